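"""Assembly and analysis of the annotated denitrification-potential dataset.

The dataset is a wide table with 36 columns in four groups — genome,
ecosystem, lineage (GTDB-Tk), and the derived denitrification columns: the
12 per-enzyme binary fields E01_narG .. E12_nosZ, the 12-digit "Denitrifying
Enzymes Pattern", the 4-digit "Denitrification Pattern", and the named
"Denitrification Traits" category. Pattern columns are always typed as text
so leading zeros survive every export format.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import EnzymeCatalog, denitrification_catalog
from .ingest import (
    ECOSYSTEM_COLUMNS,
    GENOME_COLUMNS,
    LINEAGE_COLUMNS,
    KOGenomeList,
    derive_genus,
    normalize_name,
)
from .rules import TraitRuleSet, apply_trait_rules, encode_pattern, trait_name

logger = logging.getLogger(__name__)

__all__ = [
    "PATTERN_COLUMN",
    "CODE_COLUMN",
    "TRAIT_COLUMN",
    "enzyme_columns",
    "dataset_columns",
    "build_dataset",
    "detect_replicate_strains",
    "summarize",
    "count_distinct",
    "filter_dataset",
    "annotate_auxiliary_kos",
    "export_dataset",
    "read_dataset",
]

PATTERN_COLUMN = "Denitrifying Enzymes Pattern"
CODE_COLUMN = "Denitrification Pattern"
TRAIT_COLUMN = "Denitrification Traits"
NULL_LABEL = "Null"


def enzyme_columns(catalog: EnzymeCatalog) -> list[str]:
    """Per-enzyme binary column names, e.g. ``E01_narG`` .. ``E12_nosZ``."""
    return [f"E{e.position:02d}_{e.gene_symbol}" for e in catalog]


def dataset_columns(catalog: EnzymeCatalog) -> list[str]:
    """Canonical column order: genome, ecosystem, lineage, enzymes, potential."""
    return (
        list(GENOME_COLUMNS)
        + list(ECOSYSTEM_COLUMNS)
        + list(LINEAGE_COLUMNS)
        + enzyme_columns(catalog)
        + [CODE_COLUMN, TRAIT_COLUMN, PATTERN_COLUMN]
    )


def build_dataset(annotated: pd.DataFrame, rules: TraitRuleSet,
                  catalog: EnzymeCatalog | None = None) -> pd.DataFrame:
    """Build the annotated dataset from a merged + joined presence matrix.

    ``annotated`` must carry ``Genome ID``, ``Genome Name`` and one boolean
    column per catalog gene symbol (the output of
    :func:`~denitrait.ingest.merge_ko_lists` /
    :func:`~denitrait.ingest.join_metadata`); any genome/ecosystem/lineage
    columns present are carried through, the rest are filled with missing
    values. Genomes whose enzymes pattern is all zeros are excluded (the
    inclusion criterion is at least one denitrifying enzyme) with the count
    logged.
    """
    catalog = catalog or rules.catalog
    if annotated["Genome ID"].duplicated().any():
        dup = annotated["Genome ID"][annotated["Genome ID"].duplicated()].tolist()
        raise ValueError(f"duplicate Genome ID(s) in input matrix: {dup}")

    out = pd.DataFrame(index=annotated.index)
    for col in GENOME_COLUMNS + ECOSYSTEM_COLUMNS + LINEAGE_COLUMNS:
        out[col] = annotated[col] if col in annotated.columns else pd.NA
    out["Genome Name"] = annotated["Genome Name"].map(normalize_name)
    if "Genus" not in annotated.columns:
        out["Genus"] = out["Genome Name"].map(derive_genus)

    patterns = annotated.apply(
        lambda row: encode_pattern(
            {s: bool(row[s]) for s in catalog.gene_symbols}, catalog
        ),
        axis=1,
    )
    for col, entry in zip(enzyme_columns(catalog), catalog):
        out[col] = patterns.str[entry.position - 1].astype(int)
    out[PATTERN_COLUMN] = patterns
    out[CODE_COLUMN] = patterns.map(lambda p: apply_trait_rules(p, rules))
    out[TRAIT_COLUMN] = out[CODE_COLUMN].map(trait_name)

    empty = out[PATTERN_COLUMN] == "0" * len(catalog)
    if empty.any():
        logger.info("excluding %d genome(s) with no denitrifying enzymes", int(empty.sum()))
        out = out[~empty]
    return out[dataset_columns(catalog)].reset_index(drop=True)


def detect_replicate_strains(dataset: pd.DataFrame) -> pd.Series:
    """Strain names with two or more genome records.

    Strain identity is the normalized Genome Name; the result maps name ->
    genome count, restricted to counts >= 2, sorted by name.
    """
    counts = dataset["Genome Name"].map(normalize_name).value_counts()
    reps = counts[counts >= 2].sort_index()
    reps.name = "genome_count"
    return reps


def summarize(dataset: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Group the dataset and count genomes and distinct enzymes patterns.

    Missing annotation in any grouping key is rendered as the explicit
    label ``"Null"``. Rows are ordered lexicographically by key values.
    """
    keys = list(keys)
    unknown = [k for k in keys if k not in dataset.columns]
    if unknown:
        raise KeyError(f"unknown summary key(s): {unknown}")
    if dataset.empty:
        return pd.DataFrame(columns=keys + ["genome_count", "distinct_patterns"])
    work = dataset.copy()
    for k in keys:
        work[k] = work[k].astype("object").where(work[k].notna(), NULL_LABEL)
    grouped = (
        work.groupby(keys, dropna=False)
        .agg(
            genome_count=("Genome ID", "size"),
            distinct_patterns=(PATTERN_COLUMN, "nunique"),
        )
        .reset_index()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped


def count_distinct(dataset: pd.DataFrame, column: str) -> int:
    """Number of distinct non-null values in a column (names normalized)."""
    if column not in dataset.columns:
        raise KeyError(f"unknown column {column!r}")
    values = dataset[column].dropna()
    if column == "Genome Name":
        values = values.map(normalize_name)
    return int(values.nunique())


def filter_dataset(
    dataset: pd.DataFrame,
    *,
    equals: Mapping[str, object] | None = None,
    isin: Mapping[str, Sequence] | None = None,
    name_contains: str | None = None,
) -> pd.DataFrame:
    """Subset the dataset by a conjunction of predicates, preserving row order.

    Parameters
    ----------
    equals : mapping column -> value
        Exact equality per column.
    isin : mapping column -> allowed values
        Set membership per column.
    name_contains : str
        Case-insensitive substring match on Genome Name.
    """
    mask = pd.Series(True, index=dataset.index)
    for col, val in (equals or {}).items():
        if col not in dataset.columns:
            raise KeyError(f"unknown column {col!r}")
        mask &= dataset[col] == val
    for col, vals in (isin or {}).items():
        if col not in dataset.columns:
            raise KeyError(f"unknown column {col!r}")
        mask &= dataset[col].isin(list(vals))
    if name_contains is not None:
        mask &= dataset["Genome Name"].str.contains(name_contains, case=False, regex=False, na=False)
    return dataset[mask]


def annotate_auxiliary_kos(
    dataset: pd.DataFrame, aux_lists: Mapping[str, KOGenomeList]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag dataset genomes present in auxiliary KO lists (e.g. nifH, glnA).

    Adds one boolean column per auxiliary KO, named ``"<gene>_<ko>"`` (or
    the KO id when the list has no gene symbol), and returns a per-KO count
    table in the pathway-annotation layout: ko_id, gene_symbol, column,
    genome_count, example_genome. Aux genome ids absent from the dataset
    are ignored with a log entry.
    """
    out = dataset.copy()
    rows = []
    known = set(out["Genome ID"])
    for ko_id, ko_list in aux_lists.items():
        ids = ko_list.genome_ids
        orphans = ids - known
        if orphans:
            logger.info("aux KO %s: %d genome id(s) not in dataset, ignored", ko_id, len(orphans))
        try:
            symbol = ko_list.gene_symbol
        except AttributeError:
            symbol = ""
        col = f"{symbol}_{ko_id}" if symbol else ko_id
        out[col] = out["Genome ID"].isin(ids)
        hit = out.loc[out[col], "Genome Name"]
        rows.append(
            {
                "ko_id": ko_id,
                "gene_symbol": symbol,
                "column": col,
                "genome_count": int(out[col].sum()),
                "example_genome": hit.iloc[0] if not hit.empty else pd.NA,
            }
        )
    return out, pd.DataFrame(rows)


# Columns that must survive export as text (leading zeros are meaningful).
def _text_columns(columns: Sequence[str]) -> list[str]:
    return [c for c in columns if c in (PATTERN_COLUMN, CODE_COLUMN, "Genome ID", "GOLD Sequencing Project ID")]


def export_dataset(dataset: pd.DataFrame, path, format: str | None = None) -> Path:
    """Write the dataset as CSV, TSV or spreadsheet; re-import is lossless.

    ``format`` defaults from the file suffix (.csv/.tsv/.xlsx). Pattern and
    identifier columns are written as text so "0100" round-trips unchanged.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "spreadsheet":
        fmt = "xlsx"
    if fmt == "csv":
        dataset.to_csv(path, index=False)
    elif fmt == "tsv":
        dataset.to_csv(path, index=False, sep="\t")
    elif fmt == "xlsx":
        frame = dataset.copy()
        # spreadsheet numeric coercion would corrupt "0100"-style values
        for col in _text_columns(frame.columns):
            frame[col] = frame[col].map(lambda v: v if pd.isna(v) else str(v))
        frame.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use csv, tsv or xlsx)")
    return path


def read_dataset(path, format: str | None = None) -> pd.DataFrame:
    """Read back a dataset written by :func:`export_dataset`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "spreadsheet":
        fmt = "xlsx"
    text_cols = [PATTERN_COLUMN, CODE_COLUMN, "Genome ID", "GOLD Sequencing Project ID"]
    dtype = {c: str for c in text_cols}
    if fmt == "csv":
        df = pd.read_csv(path, dtype=dtype)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=dtype)
    elif fmt == "xlsx":
        df = pd.read_excel(path, dtype=dtype)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    for col in ("Genome Size", "Gene Count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df
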