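"""Scholarly-search text and genome-portal link construction.

Builds Google Scholar search strings for denitrification gene symbols —
plain ("denitrification nosZ") or negated ('("absence of nosZ"
denitrification)', useful for literature on incomplete denitrification) —
and the IMG/M per-KO genome-list URL. Everything is emitted as text; no
network access is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .catalog import EnzymeCatalog, denitrification_catalog

__all__ = [
    "NEGATION_PHRASES",
    "ScholarQuery",
    "build_scholar_query",
    "enumerate_scholar_queries",
    "build_portal_url",
]

#: Negation words that retrieve literature on incomplete denitrification.
NEGATION_PHRASES = (
    "absence",
    "lack",
    "lacking",
    "missing",
    "no",
    "not possess",
    "not with",
    "without",
)

_IMG_URL_TEMPLATE = (
    "https://img.jgi.doe.gov/cgi-bin/m/main.cgi"
    "?section=FindFunctions&page=findkogenomelist"
    "&ko_id=KO:{ko_id}&taxonChoice=allIsolates&data_type"
)

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class ScholarQuery:
    """A rendered scholarly search text for one gene symbol."""

    gene_symbol: str
    mode: str  # "plain" | "negation"
    negation_phrase: str | None
    rendered_text: str


def build_scholar_query(
    gene_symbol: str,
    mode: str = "plain",
    phrase: str | None = None,
    catalog: EnzymeCatalog | None = None,
) -> ScholarQuery:
    """Build a Scholar search text for a catalog gene symbol.

    ``plain`` renders ``denitrification <symbol>``; ``negation`` renders
    ``("<phrase> of <symbol>" denitrification)`` and requires ``phrase`` to
    be one of :data:`NEGATION_PHRASES`.
    """
    catalog = catalog or denitrification_catalog()
    if gene_symbol not in catalog:
        raise ValueError(f"unknown gene symbol {gene_symbol!r}; catalog has {catalog.gene_symbols}")
    if mode == "plain":
        if phrase is not None:
            raise ValueError("plain mode takes no negation phrase")
        text = f"denitrification {gene_symbol}"
        return ScholarQuery(gene_symbol, "plain", None, text)
    if mode == "negation":
        if phrase is None:
            raise ValueError(f"negation mode requires a phrase from {NEGATION_PHRASES}")
        if phrase not in NEGATION_PHRASES:
            raise ValueError(f"unknown negation phrase {phrase!r}; use one of {NEGATION_PHRASES}")
        text = f'("{phrase} of {gene_symbol}" denitrification)'
        return ScholarQuery(gene_symbol, "negation", phrase, text)
    raise ValueError(f"mode must be 'plain' or 'negation', got {mode!r}")


def enumerate_scholar_queries(catalog: EnzymeCatalog | None = None) -> list[ScholarQuery]:
    """Plain search texts for every gene symbol in the catalog."""
    catalog = catalog or denitrification_catalog()
    return [build_scholar_query(s, "plain", catalog=catalog) for s in catalog.gene_symbols]


def build_portal_url(ko_id: str) -> str:
    """IMG/M find-KO-genome-list URL for a KO identifier (reference only)."""
    if not _KO_RE.match(ko_id or ""):
        raise ValueError(f"malformed KO id {ko_id!r}; expected 'K' followed by 5 digits")
    return _IMG_URL_TEMPLATE.format(ko_id=ko_id)
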