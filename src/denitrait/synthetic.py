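"""Synthetic cohort generator emitting IMG/M-dialect inputs with known truth.

The generator plants a trait distribution (4-digit code per genome), draws
each genome's 12-digit enzymes pattern uniformly from that code's preimage
under the rule map, attaches taxonomy/ecosystem annotation from small
pools, optionally duplicates genome names to create replicate strains, and
flags auxiliary-KO carriers. It writes exactly the files the ingest module
consumes — one TSV per catalog gene listing the genomes whose pattern has
a '1' at that gene's position, plus a metadata TSV — together with a truth
table recording every planted attribute, so end-to-end recovery can be
checked exactly. Same seed, same spec => byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import EnzymeCatalog
from .rules import TraitRuleSet, build_denitrification_ruleset, enumerate_rule_map, trait_name

__all__ = ["SyntheticCohortSpec", "SyntheticCohort", "generate_cohort"]

#: Small but realistic annotation pools: (genus, family, order, phylum, domain).
_DEFAULT_TAXA = (
    ("Pseudomonas", "Pseudomonadaceae", "Pseudomonadales", "Pseudomonadota", "Bacteria"),
    ("Paracoccus", "Paracoccaceae", "Rhodobacterales", "Pseudomonadota", "Bacteria"),
    ("Shewanella", "Shewanellaceae", "Alteromonadales", "Pseudomonadota", "Bacteria"),
    ("Arcobacter", "Arcobacteraceae", "Campylobacterales", "Campylobacterota", "Bacteria"),
    ("Sulfurimonas", "Sulfurimonadaceae", "Campylobacterales", "Campylobacterota", "Bacteria"),
    ("Bradyrhizobium", "Xanthobacteraceae", "Hyphomicrobiales", "Pseudomonadota", "Bacteria"),
    ("Thermus", "Thermaceae", "Thermales", "Deinococcota", "Bacteria"),
    ("Haloferax", "Haloferacaceae", "Haloferacales", "Halobacteriota", "Archaea"),
    ("Natrinema", "Natrialbaceae", "Natrialbales", "Halobacteriota", "Archaea"),
)

#: GOLD-style 5-level ecosystem tuples; None marks the missing-annotation option.
_DEFAULT_ECOSYSTEMS = (
    ("Environmental", "Aquatic", "Marine", "Coastal", "Seawater"),
    ("Environmental", "Aquatic", "Freshwater", "Lake", "Sediment"),
    ("Environmental", "Terrestrial", "Soil", "Loam", "Agricultural soil"),
    ("Host-associated", "Mollusca", "Oyster", "Gill", "Tissue"),
    ("Engineered", "Wastewater", "Activated sludge", "Nutrient removal", "Bioreactor"),
    None,
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Planted structure of a synthetic cohort.

    Attributes
    ----------
    seed : int
        Mandatory RNG seed; identical spec + seed gives byte-identical files.
    n_genomes : int
        Cohort size.
    trait_weights : dict
        4-digit code -> probability (normalized on use). Defaults to the
        uniform distribution over all 16 codes, which maximizes coverage of
        rule-engine edge cases.
    taxonomy_pool, ecosystem_pool : tuples
        Sampling pools; an ecosystem entry of ``None`` stands for missing
        annotation and is drawn with probability ``missing_ecosystem_rate``
        (the ``None`` entry need not be listed in the pool).
    replicate_rate : float
        Probability that a genome re-uses an already-emitted genome name
        under a fresh Genome ID, creating a replicate strain.
    aux_ko_rates : dict
        KO id -> carrier probability for auxiliary annotations
        (e.g. ``{"K02588": 0.1, "K01915": 0.9}``).
    """

    seed: int
    n_genomes: int = 1000
    trait_weights: dict[str, float] = field(default_factory=dict)
    taxonomy_pool: tuple = _DEFAULT_TAXA
    ecosystem_pool: tuple = _DEFAULT_ECOSYSTEMS
    missing_ecosystem_rate: float = 0.2
    replicate_rate: float = 0.05
    aux_ko_rates: dict[str, float] = field(default_factory=dict)

    def normalized_weights(self, n_steps: int = 4) -> dict[str, float]:
        if not self.trait_weights:
            codes = [format(i, f"0{n_steps}b") for i in range(2 ** n_steps)]
            return {c: 1.0 / len(codes) for c in codes}
        total = float(sum(self.trait_weights.values()))
        if total <= 0:
            raise ValueError("trait_weights must have positive total mass")
        for c, w in self.trait_weights.items():
            if not 0.0 <= w:
                raise ValueError(f"negative weight for code {c!r}")
        return {c: w / total for c, w in self.trait_weights.items()}

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "n_genomes": self.n_genomes,
            "trait_weights": dict(self.trait_weights),
            "taxonomy_pool": [list(t) for t in self.taxonomy_pool],
            "ecosystem_pool": [list(t) if t is not None else None for t in self.ecosystem_pool],
            "missing_ecosystem_rate": self.missing_ecosystem_rate,
            "replicate_rate": self.replicate_rate,
            "aux_ko_rates": dict(self.aux_ko_rates),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["taxonomy_pool"] = tuple(tuple(t) for t in data.get("taxonomy_pool", _DEFAULT_TAXA))
        data["ecosystem_pool"] = tuple(
            tuple(t) if t is not None else None for t in data.get("ecosystem_pool", _DEFAULT_ECOSYSTEMS)
        )
        return cls(**data)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: file paths plus the planted truth table."""

    spec: SyntheticCohortSpec
    ko_list_paths: dict[str, Path]  # dataset_label -> path
    aux_list_paths: dict[str, Path]  # ko_id -> path
    metadata_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _species_epithets(rng: np.random.Generator) -> str:
    # pronounceable pseudo-Latin epithets, deterministic under the rng
    syllables = ["den", "ni", "tri", "fi", "ma", "ri", "sal", "ter", "aqu", "lu", "co", "ba"]
    k = int(rng.integers(2, 4))
    return "".join(rng.choice(syllables) for _ in range(k))


def generate_cohort(
    spec: SyntheticCohortSpec,
    outdir,
    rules: TraitRuleSet | None = None,
    catalog: EnzymeCatalog | None = None,
) -> SyntheticCohort:
    """Generate IMG/M-dialect input files plus a truth table under ``outdir``.

    Patterns are drawn uniformly from each planted code's preimage; the
    all-zero pattern is never emitted (such a genome would appear in no KO
    list, so it could not be part of the dataset). Files written:
    ``ko_<label>.tsv`` per catalog gene, ``metadata.tsv``, ``truth.csv`` and
    ``cohort_spec.yaml``.
    """
    rules = rules or build_denitrification_ruleset()
    catalog = catalog or rules.catalog
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    enum = enumerate_rule_map(rules)
    zero = "0" * len(catalog)
    preimages = {
        code: [p for p in enum.preimage(code) if p != zero] for code in enum.codes
    }
    weights = spec.normalized_weights(rules.n_steps)
    for code in weights:
        if code not in preimages or not preimages[code]:
            raise ValueError(f"trait code {code!r} has no usable enzymes pattern")

    codes = list(weights)
    probs = np.array([weights[c] for c in codes])
    probs = probs / probs.sum()

    eco_pool = [e for e in spec.ecosystem_pool if e is not None]

    rows = []
    names_emitted: list[str] = []
    for i in range(spec.n_genomes):
        code = codes[int(rng.choice(len(codes), p=probs))]
        pool = preimages[code]
        pattern = pool[int(rng.integers(len(pool)))]
        genome_id = f"65{spec.seed % 1000:03d}{i:06d}"

        if names_emitted and rng.random() < spec.replicate_rate:
            name = names_emitted[int(rng.integers(len(names_emitted)))]
            taxon = next(r for r in rows if r["Genome Name"] == name)
            genus, family, order, phylum, domain = (
                taxon["Genus"], taxon["GTDB-Tk Family"], taxon["GTDB-Tk Order"],
                taxon["GTDB-Tk Phylum"], taxon["GTDB-Tk Domain"],
            )
        else:
            genus, family, order, phylum, domain = spec.taxonomy_pool[
                int(rng.integers(len(spec.taxonomy_pool)))
            ]
            name = f"{genus} {_species_epithets(rng)} S{i:05d}"
            names_emitted.append(name)

        if rng.random() < spec.missing_ecosystem_rate or not eco_pool:
            eco = (None,) * 5
        else:
            eco = eco_pool[int(rng.integers(len(eco_pool)))]

        row = {
            "Genome ID": genome_id,
            "Genome Name": name,
            "Domain": domain,
            "Status": "Permanent Draft",
            "Genus": genus,
            "GTDB-Tk Domain": domain,
            "GTDB-Tk Phylum": phylum,
            "GTDB-Tk Order": order,
            "GTDB-Tk Family": family,
            "GTDB-Tk Genus": genus,
            "GTDB-Tk Species": " ".join(name.split(" ")[:2]),
            "Ecosystem": eco[0],
            "Ecosystem Category": eco[1],
            "Ecosystem Type": eco[2],
            "Ecosystem Subtype": eco[3],
            "Specific Ecosystem": eco[4],
            "Genome Size": int(rng.integers(1_500_000, 9_000_000)),
            "Gene Count": int(rng.integers(1500, 9000)),
            "pattern": pattern,
            "code": code,
            "trait": trait_name(code) if rules.name == "denitrification" else code,
        }
        for ko_id, rate in spec.aux_ko_rates.items():
            row[f"aux_{ko_id}"] = bool(rng.random() < rate)
        rows.append(row)

    truth = pd.DataFrame(rows)

    # per-gene KO list files: exactly the genomes with '1' at that position
    ko_paths: dict[str, Path] = {}
    for entry in catalog:
        label = catalog.dataset_label(entry.gene_symbol)
        member = truth[truth["pattern"].str[entry.position - 1] == "1"]
        frame = pd.DataFrame(
            {
                "Domain": member["Domain"],
                "Status": member["Status"],
                "Genome ID": member["Genome ID"],
                "Genome Name": member["Genome Name"],
            }
        )
        path = outdir / f"ko_{label}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        ko_paths[label] = path

    # auxiliary KO lists: exactly the planted carrier genomes
    aux_paths: dict[str, Path] = {}
    for ko_id in spec.aux_ko_rates:
        carriers = truth[truth[f"aux_{ko_id}"]]
        frame = pd.DataFrame(
            {
                "Domain": carriers["Domain"],
                "Status": carriers["Status"],
                "Genome ID": carriers["Genome ID"],
                "Genome Name": carriers["Genome Name"],
            }
        )
        path = outdir / f"aux_{ko_id}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        aux_paths[ko_id] = path

    meta_cols = [
        "Genome ID", "Genome Size", "Gene Count",
        "GTDB-Tk Domain", "GTDB-Tk Phylum", "GTDB-Tk Order",
        "GTDB-Tk Family", "GTDB-Tk Genus", "GTDB-Tk Species",
        "Ecosystem", "Ecosystem Category", "Ecosystem Type",
        "Ecosystem Subtype", "Specific Ecosystem",
    ]
    metadata_path = outdir / "metadata.tsv"
    truth[meta_cols].to_csv(metadata_path, sep="\t", index=False)

    truth_path = outdir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    spec.to_yaml(outdir / "cohort_spec.yaml")

    return SyntheticCohort(
        spec=spec,
        ko_list_paths=ko_paths,
        aux_list_paths=aux_paths,
        metadata_path=metadata_path,
        truth_path=truth_path,
        truth=truth,
    )
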