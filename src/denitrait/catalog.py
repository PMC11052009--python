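"""Enzyme catalogs: the ordered gene/KO tables that fix pattern digit positions.

A catalog is an ordered list of (position, gene symbol, KEGG Orthology id,
pathway step, complex label) records. The digit order of every binary
presence/absence pattern is defined by the catalog, so the catalog is the
single source of truth for "which digit is which gene".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["CatalogEntry", "EnzymeCatalog", "denitrification_catalog", "nitrogen_fixation_catalog"]


@dataclass(frozen=True)
class CatalogEntry:
    """One gene in an enzyme catalog.

    Attributes
    ----------
    position : int
        1-based digit position in the presence/absence pattern.
    gene_symbol : str
        Gene symbol, e.g. ``"narG"``.
    ko_id : str
        KEGG Orthology identifier, e.g. ``"K00370"``.
    step : int
        1-based pathway step this gene contributes to.
    complex_label : str
        Name of the enzyme complex the gene belongs to (e.g. ``"narGHI"``);
        singleton genes use their own symbol.
    """

    position: int
    gene_symbol: str
    ko_id: str
    step: int
    complex_label: str


class EnzymeCatalog:
    """Ordered, validated collection of :class:`CatalogEntry` records.

    Positions must run 1..n with no gaps; gene symbols and KO ids must be
    unique. Step numbers must be non-decreasing along positions and cover
    1..n_steps without gaps.
    """

    def __init__(self, entries: Iterable[CatalogEntry]):
        entries = sorted(entries, key=lambda e: e.position)
        if not entries:
            raise ValueError("catalog must contain at least one entry")
        positions = [e.position for e in entries]
        if positions != list(range(1, len(entries) + 1)):
            raise ValueError(f"positions must be 1..{len(entries)} with no gaps, got {positions}")
        symbols = [e.gene_symbol for e in entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene symbols must be unique")
        kos = [e.ko_id for e in entries]
        if len(set(kos)) != len(kos):
            raise ValueError("KO ids must be unique")
        steps = sorted({e.step for e in entries})
        if steps != list(range(1, len(steps) + 1)):
            raise ValueError(f"steps must cover 1..{len(steps)} with no gaps, got {steps}")
        self._entries = tuple(entries)
        self._by_symbol = {e.gene_symbol: e for e in entries}

    @property
    def entries(self) -> tuple[CatalogEntry, ...]:
        return self._entries

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(e.gene_symbol for e in self._entries)

    @property
    def ko_ids(self) -> tuple[str, ...]:
        return tuple(e.ko_id for e in self._entries)

    @property
    def n_steps(self) -> int:
        return max(e.step for e in self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self._entries)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self._by_symbol

    def entry(self, gene_symbol: str) -> CatalogEntry:
        try:
            return self._by_symbol[gene_symbol]
        except KeyError:
            raise KeyError(f"unknown gene symbol {gene_symbol!r}; catalog has {self.gene_symbols}") from None

    def position(self, gene_symbol: str) -> int:
        return self.entry(gene_symbol).position

    def ko_for(self, gene_symbol: str) -> str:
        return self.entry(gene_symbol).ko_id

    def symbol_for_ko(self, ko_id: str) -> str:
        for e in self._entries:
            if e.ko_id == ko_id:
                return e.gene_symbol
        raise KeyError(f"unknown KO id {ko_id!r}")

    def dataset_label(self, gene_symbol: str) -> str:
        """Two-digit position prefix label, e.g. ``"01_narG"`` or ``"12_nosZ"``."""
        e = self.entry(gene_symbol)
        return f"{e.position:02d}_{e.gene_symbol}"

    @property
    def dataset_labels(self) -> tuple[str, ...]:
        return tuple(self.dataset_label(s) for s in self.gene_symbols)


# The canonical four-step denitrification pathway: nitrate -> nitrite ->
# nitric oxide -> nitrous oxide -> N2. Digit order is fixed: narG, narH,
# narI, napA, napB, nirK, nirS, norB, norC, norV, norW, nosZ.
_DENITRIFICATION_ENTRIES = (
    CatalogEntry(1, "narG", "K00370", 1, "narGHI"),
    CatalogEntry(2, "narH", "K00371", 1, "narGHI"),
    CatalogEntry(3, "narI", "K00374", 1, "narGHI"),
    CatalogEntry(4, "napA", "K02567", 1, "napAB"),
    CatalogEntry(5, "napB", "K02568", 1, "napAB"),
    CatalogEntry(6, "nirK", "K00368", 2, "nirK"),
    CatalogEntry(7, "nirS", "K15864", 2, "nirS"),
    CatalogEntry(8, "norB", "K04561", 3, "norBC"),
    CatalogEntry(9, "norC", "K02305", 3, "norBC"),
    CatalogEntry(10, "norV", "K12264", 3, "norVW"),
    CatalogEntry(11, "norW", "K12265", 3, "norVW"),
    CatalogEntry(12, "nosZ", "K00376", 4, "nosZ"),
)

# Nitrogen fixation: structural nitrogenase components NifHDK plus the
# FeMo-cofactor biosynthesis components NifENB. Only nifH's KO is fixed by
# the downstream annotation workflow; the rest are standard KEGG entries.
_NIF_ENTRIES = (
    CatalogEntry(1, "nifH", "K02588", 1, "nifHDK"),
    CatalogEntry(2, "nifD", "K02586", 1, "nifHDK"),
    CatalogEntry(3, "nifK", "K02591", 1, "nifHDK"),
    CatalogEntry(4, "nifE", "K02587", 2, "nifENB"),
    CatalogEntry(5, "nifN", "K02592", 2, "nifENB"),
    CatalogEntry(6, "nifB", "K02585", 2, "nifENB"),
)


def denitrification_catalog() -> EnzymeCatalog:
    """The 12-gene denitrification catalog defining the 12-digit pattern."""
    return EnzymeCatalog(_DENITRIFICATION_ENTRIES)


def nitrogen_fixation_catalog() -> EnzymeCatalog:
    """The 6-gene nitrogen-fixation catalog (nifHDK + nifENB)."""
    return EnzymeCatalog(_NIF_ENTRIES)
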