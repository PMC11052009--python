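"""Readers for IMG/M-style per-KO genome lists and genome metadata tables.

Each KO export is a delimited text file (tab preferred, comma accepted)
with at least the columns Domain, Status, Genome ID and Genome Name; one
file exists per KEGG Orthology term and is labelled ``"NN_geneSymbol"``
(e.g. ``"01_narG"``, ``"12_nosZ"``) where NN is the gene's digit position
in the catalog. Merging the 12 lists yields a genome x gene presence
matrix; joining a metadata table adds GTDB-Tk lineage and GOLD ecosystem
annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import EnzymeCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "KOGenomeList",
    "read_ko_genome_list",
    "merge_ko_lists",
    "read_metadata",
    "derive_genus",
    "normalize_name",
    "join_metadata",
    "LINEAGE_COLUMNS",
    "ECOSYSTEM_COLUMNS",
    "GENOME_COLUMNS",
]

#: Table-schema column groups carried through the pipeline.
GENOME_COLUMNS = (
    "Domain",
    "Gene Count",
    "Genome ID",
    "Genome Name",
    "Genome Size",
    "Genus",
    "GOLD Sequencing Project ID",
    "Sequencing Center",
    "Sequencing Status",
    "Status",
)
ECOSYSTEM_COLUMNS = (
    "Ecosystem",
    "Ecosystem Category",
    "Ecosystem Type",
    "Ecosystem Subtype",
    "Specific Ecosystem",
)
LINEAGE_COLUMNS = (
    "GTDB-Tk Domain",
    "GTDB-Tk Family",
    "GTDB-Tk Genus",
    "GTDB-Tk Order",
    "GTDB-Tk Phylum",
    "GTDB-Tk Species",
)

_MANDATORY_KO_COLUMNS = ("Domain", "Status", "Genome ID", "Genome Name")
_LABEL_RE = re.compile(r"^(\d{2})_(\w+)$")


@dataclass(frozen=True)
class KOGenomeList:
    """One per-KO genome export: which genomes carry a given KO term."""

    dataset_label: str
    ko_id: str
    records: pd.DataFrame  # columns: Domain, Status, Genome ID, Genome Name

    @property
    def genome_ids(self) -> set[str]:
        return set(self.records["Genome ID"])

    @property
    def gene_symbol(self) -> str:
        return _LABEL_RE.match(self.dataset_label).group(2)

    def __len__(self) -> int:
        return len(self.records)


def _sniff_sep(path) -> str:
    """Tab preferred; fall back to comma when the header has no tabs."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    for col in df.columns:
        df[col] = df[col].str.strip()
    return df


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace runs; export dialects vary."""
    return re.sub(r"\s+", " ", str(name)).strip()


def read_ko_genome_list(path, dataset_label: str, ko_id: str | None = None,
                        catalog: EnzymeCatalog | None = None) -> KOGenomeList:
    """Read one per-KO genome export.

    Parameters
    ----------
    path : path-like
        Delimited text file (TSV or CSV) with a header containing at least
        Domain, Status, Genome ID, Genome Name.
    dataset_label : str
        ``"NN_geneSymbol"`` label; when ``catalog`` is given, NN must match
        the gene's catalog position.
    ko_id : str, optional
        KEGG Orthology id; when a catalog is given it defaults to the
        labelled gene's KO.

    Duplicate Genome IDs within the file collapse to one record with a
    warning — a genome carries a KO at most once in the presence model.
    """
    m = _LABEL_RE.match(dataset_label)
    if not m:
        raise ValueError(f"dataset_label must look like '01_narG', got {dataset_label!r}")
    if catalog is not None:
        symbol = m.group(2)
        expected = catalog.dataset_label(symbol)
        if dataset_label != expected:
            raise ValueError(
                f"dataset_label {dataset_label!r} does not match catalog position "
                f"for {symbol!r} (expected {expected!r})"
            )
        if ko_id is None:
            ko_id = catalog.ko_for(symbol)
    if ko_id is None:
        ko_id = ""

    df = _read_delimited(path)
    missing = [c for c in _MANDATORY_KO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}")
    df = df[list(_MANDATORY_KO_COLUMNS)].copy()
    if df.empty:
        logger.warning("%s: empty KO genome list for %s", path, dataset_label)
    if df["Genome ID"].isna().any() or (df["Genome ID"] == "").any():
        raise ValueError(f"{path}: empty Genome ID in {dataset_label}")
    n_before = len(df)
    df = df.drop_duplicates(subset="Genome ID", keep="first").reset_index(drop=True)
    if len(df) < n_before:
        logger.warning(
            "%s: %d duplicate Genome ID row(s) collapsed in %s",
            path, n_before - len(df), dataset_label,
        )
    return KOGenomeList(dataset_label=dataset_label, ko_id=ko_id, records=df)


def merge_ko_lists(lists: list[KOGenomeList], catalog: EnzymeCatalog) -> pd.DataFrame:
    """Merge the per-gene lists into a genome x gene boolean presence matrix.

    Every catalog label must appear exactly once. The result has one row per
    genome in the union of the lists (so every row has at least one present
    gene), with columns Genome ID, Genome Name, Domain, Status and one
    boolean column per gene symbol. Name/domain/status conflicts between
    lists resolve first-seen-wins (list order, then row order) with a
    logged warning.
    """
    labels = [ko.dataset_label for ko in lists]
    expected = list(catalog.dataset_labels)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate dataset label(s): {sorted(dupes)}")
    missing = [l for l in expected if l not in labels]
    extra = [l for l in labels if l not in expected]
    if missing or extra:
        raise ValueError(f"dataset labels must be exactly {expected}; missing {missing}, unexpected {extra}")

    by_label = {ko.dataset_label: ko for ko in lists}
    info: dict[str, dict] = {}
    membership: dict[str, set[str]] = {}
    for label in expected:  # catalog order so "first seen" is deterministic
        ko = by_label[label]
        symbol = ko.gene_symbol
        membership[symbol] = ko.genome_ids
        for row in ko.records.itertuples(index=False):
            gid = row[2]
            name = normalize_name(row[3])
            if gid not in info:
                info[gid] = {"Genome Name": name, "Domain": row[0], "Status": row[1]}
            elif info[gid]["Genome Name"] != name:
                logger.warning(
                    "genome %s: name conflict between lists (%r kept, %r in %s)",
                    gid, info[gid]["Genome Name"], name, label,
                )

    genome_ids = sorted(info)
    out = pd.DataFrame(
        {
            "Genome ID": genome_ids,
            "Genome Name": [info[g]["Genome Name"] for g in genome_ids],
            "Domain": [info[g]["Domain"] for g in genome_ids],
            "Status": [info[g]["Status"] for g in genome_ids],
        }
    )
    for symbol in catalog.gene_symbols:
        out[symbol] = out["Genome ID"].isin(membership[symbol])
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a genome metadata table keyed by Genome ID.

    Lineage/ecosystem/sequencing columns are optional and kept nullable
    (missing annotation is an explicit missing value, rendered as "Null"
    only in grouped summaries). Duplicate Genome ID rows are rejected.
    """
    df = _read_delimited(path)
    if "Genome ID" not in df.columns:
        raise ValueError(f"{path}: metadata table must contain a 'Genome ID' column")
    dup = df["Genome ID"][df["Genome ID"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate Genome ID(s) in metadata: {dup}")
    for col in ("Genome Size", "Gene Count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def derive_genus(genome_name: str) -> str:
    """Text before the first whitespace run of the genome name.

    This is a literal lexical rule: "Pseudomonas aeruginosa PAO1" gives
    "Pseudomonas", but "Candidatus Heimdallarchaeota ..." gives
    "Candidatus". Callers needing taxonomic genus should prefer the GTDB-Tk
    genus column.
    """
    name = normalize_name(genome_name)
    if not name:
        logger.warning("empty genome name; derived genus is empty")
        return ""
    return name.split(" ")[0]


def join_metadata(presence: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Left-join metadata onto the presence matrix by Genome ID.

    Genomes without metadata keep missing lineage/ecosystem values; metadata
    rows for unknown genomes are dropped (count logged). No genome is
    dropped or duplicated. Metadata columns already present in the matrix
    (e.g. Domain, Status from the KO exports) are not overwritten.
    """
    meta = metadata.drop(columns=[c for c in metadata.columns
                                  if c != "Genome ID" and c in presence.columns])
    unknown = ~meta["Genome ID"].isin(presence["Genome ID"])
    if unknown.any():
        logger.info("ignoring %d metadata row(s) for genomes absent from the matrix", int(unknown.sum()))
    out = presence.merge(meta, on="Genome ID", how="left", validate="one_to_one")
    return out
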