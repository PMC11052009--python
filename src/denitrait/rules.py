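"""Boolean gene-complex rule engine.

A genome's enzyme complement is a binary string ("enzymes pattern") whose
digit order is fixed by an :class:`~denitrait.catalog.EnzymeCatalog`. A
:class:`TraitRuleSet` maps that string to a shorter per-step binary string
("step pattern"): each pathway step is satisfied iff at least one of its
enzyme complexes is fully present, a complex being a conjunction of gene
symbols. For denitrification the steps are nitrate, nitrite, nitric oxide
and nitrous oxide reduction, the complexes narGHI/napAB, nirK, nirS,
norBC/norVW and nosZ, and the step pattern has 4 digits — one of 16 codes,
each with a conventional trait name ("Complete Denitrification", "Nitrous
Oxide Reduction Only", ...).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import yaml

from .catalog import EnzymeCatalog, denitrification_catalog, nitrogen_fixation_catalog

__all__ = [
    "TraitStep",
    "TraitRuleSet",
    "RuleEnumeration",
    "build_denitrification_ruleset",
    "build_nif_ruleset",
    "parse_pattern",
    "encode_pattern",
    "pattern_to_presence",
    "apply_trait_rules",
    "trait_name",
    "all_trait_names",
    "enumerate_rule_map",
    "DENITRIFICATION_STEP_NAMES",
    "INCOMPLETE_TRAIT_NAME",
    "COMPLETE_TRAIT_NAME",
]

DENITRIFICATION_STEP_NAMES = ("Nitrate", "Nitrite", "Nitric Oxide", "Nitrous Oxide")
INCOMPLETE_TRAIT_NAME = "Incomplete Enzymes for Denitrification Steps"
COMPLETE_TRAIT_NAME = "Complete Denitrification"


@dataclass(frozen=True)
class TraitStep:
    """One pathway step: satisfied iff all genes of any one alternative are present."""

    step_name: str
    alternatives: tuple[frozenset[str], ...]

    def satisfied(self, present: frozenset[str] | set[str]) -> bool:
        return any(alt <= present for alt in self.alternatives)


@dataclass(frozen=True)
class TraitRuleSet:
    """Ordered pathway steps over a gene catalog.

    Parameters
    ----------
    name : str
        Ruleset name, e.g. ``"denitrification"``.
    steps : sequence of TraitStep
        One entry per pathway step, in step order.
    catalog : EnzymeCatalog
        The catalog fixing pattern digit order; every gene symbol referenced
        by a step must exist in it.
    """

    name: str
    steps: tuple[TraitStep, ...]
    catalog: EnzymeCatalog = field(repr=False)

    def __post_init__(self):
        known = set(self.catalog.gene_symbols)
        for step in self.steps:
            for alt in step.alternatives:
                unknown = alt - known
                if unknown:
                    raise ValueError(
                        f"step {step.step_name!r} references genes absent from the "
                        f"catalog: {sorted(unknown)}"
                    )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def evaluate(self, present: set[str] | frozenset[str]) -> str:
        """Step pattern for a set of present gene symbols."""
        present = frozenset(present)
        return "".join("1" if step.satisfied(present) else "0" for step in self.steps)

    # -- serialization: step name + list of gene-symbol lists, so users can
    #    define new trait rules in a config file without code changes.

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "steps": [
                {"step_name": s.step_name, "alternatives": [sorted(a) for a in s.alternatives]}
                for s in self.steps
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping, catalog: EnzymeCatalog) -> "TraitRuleSet":
        steps = tuple(
            TraitStep(s["step_name"], tuple(frozenset(a) for a in s["alternatives"]))
            for s in data["steps"]
        )
        return cls(name=data["name"], steps=steps, catalog=catalog)

    @classmethod
    def from_yaml(cls, path, catalog: EnzymeCatalog) -> "TraitRuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), catalog)


def build_denitrification_ruleset(catalog: EnzymeCatalog | None = None) -> TraitRuleSet:
    """The four-step denitrification ruleset.

    Step 1 (nitrate reduction) requires the membrane-bound narGHI complex or
    the periplasmic napAB complex; step 2 (nitrite reduction) either of the
    single-gene reductases nirK or nirS; step 3 (nitric oxide reduction) the
    norBC complex or the flavorubredoxin norVW complex; step 4 (nitrous
    oxide reduction) nosZ. A partial complex (e.g. norB without norC, or
    napB without napA) does not satisfy its step.
    """
    catalog = catalog or denitrification_catalog()
    steps = (
        TraitStep("Nitrate", (frozenset({"narG", "narH", "narI"}), frozenset({"napA", "napB"}))),
        TraitStep("Nitrite", (frozenset({"nirK"}), frozenset({"nirS"}))),
        TraitStep("Nitric Oxide", (frozenset({"norB", "norC"}), frozenset({"norV", "norW"}))),
        TraitStep("Nitrous Oxide", (frozenset({"nosZ"}),)),
    )
    return TraitRuleSet("denitrification", steps, catalog)


def build_nif_ruleset(catalog: EnzymeCatalog | None = None) -> TraitRuleSet:
    """Two-step nitrogen-fixation ruleset: structural NifHDK, biosynthetic NifENB."""
    catalog = catalog or nitrogen_fixation_catalog()
    steps = (
        TraitStep("Structural", (frozenset({"nifH", "nifD", "nifK"}),)),
        TraitStep("Biosynthetic", (frozenset({"nifE", "nifN", "nifB"}),)),
    )
    return TraitRuleSet("nitrogen_fixation", steps, catalog)


def parse_pattern(text: str, length: int = 12) -> str:
    """Validate a binary pattern string.

    Raises ``ValueError`` naming the offending position for wrong length or
    any character outside {'0','1'}.
    """
    if not isinstance(text, str):
        raise ValueError(f"pattern must be a string, got {type(text).__name__}")
    if len(text) != length:
        raise ValueError(f"pattern must have exactly {length} digits, got {len(text)}: {text!r}")
    for i, ch in enumerate(text, start=1):
        if ch not in "01":
            raise ValueError(f"invalid character {ch!r} at position {i} in pattern {text!r}")
    return text


def encode_pattern(presence: Mapping[str, bool], catalog: EnzymeCatalog) -> str:
    """Encode a gene presence map into the catalog-ordered binary pattern.

    Keys absent from ``presence`` are treated as absent genes; keys that are
    not catalog gene symbols are rejected by name.
    """
    unknown = set(presence) - set(catalog.gene_symbols)
    if unknown:
        raise ValueError(f"unknown gene symbol(s) {sorted(unknown)}; catalog has {catalog.gene_symbols}")
    return "".join("1" if presence.get(e.gene_symbol, False) else "0" for e in catalog)


def pattern_to_presence(pattern: str, catalog: EnzymeCatalog) -> dict[str, bool]:
    """Inverse of :func:`encode_pattern`: pattern string to presence map."""
    pattern = parse_pattern(pattern, len(catalog))
    return {e.gene_symbol: pattern[e.position - 1] == "1" for e in catalog}


def apply_trait_rules(pattern: str, rules: TraitRuleSet) -> str:
    """Derive the per-step pattern from an enzymes pattern.

    Pure function of the pattern: digit k of the result is '1' iff step k
    of ``rules`` has at least one fully present complex.
    """
    pattern = parse_pattern(pattern, len(rules.catalog))
    present = frozenset(
        e.gene_symbol for e in rules.catalog if pattern[e.position - 1] == "1"
    )
    return rules.evaluate(present)


def trait_name(code: str, step_names: Sequence[str] = DENITRIFICATION_STEP_NAMES) -> str:
    """Conventional trait name for a step-pattern code.

    The all-zero code names the incomplete category; the all-one code the
    complete one. Any other code lists the satisfied step names joined with
    commas and a final " and " (no Oxford comma), suffixed " Reduction Only".
    """
    code = parse_pattern(code, len(step_names))
    if set(code) == {"0"}:
        return INCOMPLETE_TRAIT_NAME
    if set(code) == {"1"}:
        return COMPLETE_TRAIT_NAME
    satisfied = [name for name, d in zip(step_names, code) if d == "1"]
    if len(satisfied) == 1:
        joined = satisfied[0]
    else:
        joined = ", ".join(satisfied[:-1]) + " and " + satisfied[-1]
    return joined + " Reduction Only"


def all_trait_names(n_steps: int = 4) -> dict[str, str]:
    """Map every possible step code to its trait name (16 codes for 4 steps)."""
    codes = ("".join(bits) for bits in product("01", repeat=n_steps))
    return {code: trait_name(code) for code in codes}


@dataclass(frozen=True)
class RuleEnumeration:
    """Exhaustive rule-map over every possible enzymes pattern.

    Attributes
    ----------
    mapping : dict
        enzymes pattern -> step code, over all 2**n_genes patterns.
    preimage_counts : dict
        step code -> number of enzymes patterns mapping to it.
    """

    mapping: dict[str, str]
    preimage_counts: dict[str, int]

    @property
    def codes(self) -> set[str]:
        return set(self.preimage_counts)

    @property
    def n_patterns(self) -> int:
        return len(self.mapping)

    def preimage(self, code: str) -> list[str]:
        return sorted(p for p, c in self.mapping.items() if c == code)


def enumerate_rule_map(rules: TraitRuleSet) -> RuleEnumeration:
    """Apply ``rules`` to every possible enzymes pattern (2**n_genes of them)."""
    n = len(rules.catalog)
    mapping: dict[str, str] = {}
    counts: Counter[str] = Counter()
    for bits in product("01", repeat=n):
        pattern = "".join(bits)
        code = apply_trait_rules(pattern, rules)
        mapping[pattern] = code
        counts[code] += 1
    return RuleEnumeration(mapping, dict(counts))
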