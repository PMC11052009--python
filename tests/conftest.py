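import pytest

from denitrait import (
    build_denitrification_ruleset,
    build_dataset,
    denitrification_catalog,
    table6_input_matrix,
)


@pytest.fixture(scope="session")
def catalog():
    return denitrification_catalog()


@pytest.fixture(scope="session")
def ruleset(catalog):
    return build_denitrification_ruleset(catalog)


@pytest.fixture(scope="session")
def table6_dataset(ruleset, catalog):
    """The 21 nirK+nirS archaeal genomes built into a full dataset."""
    return build_dataset(table6_input_matrix(), ruleset, catalog)


def brute_force_code(pattern: str) -> str:
    """Independent truth-table oracle for the denitrification rules.

    Re-evaluates every enzyme complex directly from hard-coded digit
    positions (narGHI or napAB; nirK or nirS; norBC or norVW; nosZ),
    without going through the rule engine.
    """
    nitrate = (pattern[0] == pattern[1] == pattern[2] == "1") or (pattern[3] == pattern[4] == "1")
    nitrite = pattern[5] == "1" or pattern[6] == "1"
    nitric = (pattern[7] == pattern[8] == "1") or (pattern[9] == pattern[10] == "1")
    nitrous = pattern[11] == "1"
    return "".join("1" if s else "0" for s in (nitrate, nitrite, nitric, nitrous))
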