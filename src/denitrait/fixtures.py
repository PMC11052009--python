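"""Published reference records for the archaeal denitrification analysis.

Two small printed tables and a handful of worked pattern strings from the
source study of archaeal denitrification potential are packaged here so
every pipeline stage can be exercised and cross-checked without any
download: the nine observed archaeal trait categories with one example
genome each, and the 21 archaeal genomes carrying both nitrite reductases
(nirK and nirS).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import CODE_COLUMN, PATTERN_COLUMN

__all__ = ["PaperFixtures", "load_paper_fixtures", "table6_input_matrix"]


# Nine archaeal trait categories: (code, trait name, genome count,
# example genome, example genome's 12-digit enzymes pattern).
_TABLE5 = (
    ("0000", "Incomplete Enzymes for Denitrification Steps", 278, "Aeropyrum pernix K1", "110000000000"),
    ("0001", "Nitrous Oxide Reduction Only", 58, "Haloarcula japonica DSM 6131", "110000010001"),
    ("0010", "Nitric Oxide Reduction Only", 1, "Candidatus Hydrothermarchaeota archaeon JdFR-18", "110100011100"),
    ("0100", "Nitrite Reduction Only", 366, "Haloferax volcanii DS2", "110001010000"),
    ("0101", "Nitrite and Nitrous Oxide Reduction Only", 119, "Haloferax mediterranei R-4", "110001010001"),
    ("1000", "Nitrate Reduction Only", 39, "Pyrobaculum aerophilum IM2", "111000010000"),
    ("1001", "Nitrate and Nitrous Oxide Reduction Only", 3, "Pyrobaculum calidifontis JCM 11548", "111000010001"),
    ("1011", "Nitrate, Nitric Oxide and Nitrous Oxide Reduction Only", 1, "Ferroglobus placidus AEDII12DO, DSM 10642", "111000011101"),
    ("1100", "Nitrate and Nitrite Reduction Only", 1, "Candidatus Heimdallarchaeota archaeon LC_3", "111001000000"),
)

# The 21 archaeal genomes with both nirK and nirS:
# (genome name, genome id, enzymes pattern, ecosystem category).
_TABLE6 = (
    ("Halobiforma haloterrestris DSM 13078", "2693429869", "110001110001", "Terrestrial"),
    ("Halobiforma lacisalsi AJ5, JCM 12983", "2529293100", "110001110001", "Aquatic"),
    ("Halobiforma lacisalsi AJ5, JCM 12983", "2806310686", "110001110001", "Aquatic"),
    ("Halobiforma nitratireducens JCM 10879", "2554235466", "110001100001", "Aquatic"),
    ("Halorubrum amylolyticum ZC67", "2881047951", "110001110001", "Terrestrial"),
    ("Halorubrum salipaludis WN019", "2995789858", "000001110001", "Terrestrial"),
    ("Halosolutus halophilus LT55", "8055007790", "000001110001", "Terrestrial"),
    ("Haloterrigena longa ABH32", "8065811630", "000001110001", "Aquatic"),
    ("Haloterrigena sp. LL2A", "2639762614", "000001110001", "Aquatic"),
    ("Natrinema altunense AJ2", "2585427993", "110001110001", "Aquatic"),
    ("Natrinema altunense JCM 12890", "2554235488", "110001110001", "Aquatic"),
    ("Natrinema amylolyticum LT61", "8056733939", "110001110001", "Terrestrial"),
    ("Natrinema pallidum BOL6-1", "8058325716", "110001110000", "Terrestrial"),
    ("Natrinema pellirubrum 157", "2509601048", "110001110000", "Fish"),
    ("Natrinema pellirubrum 157", "2537562080", "110001110000", "Fish"),
    ("Natrinema sp. J7-2", "2517093029", "000001110000", "Terrestrial"),
    ("Natrinema thermotolerans A29", "2582580504", "110001110000", "Food production"),
    ("Natrinema thermotolerans A29", "2914868299", "110001110000", "Food production"),
    ("Natrinema thermotolerans DSM 11552", "2534681901", "110001110000", "Aquatic"),
    ("Natronomonas sp. LN261", "3001203943", "000001100001", "Terrestrial"),
    ("Salinilacihabitans rarus AD-4", "8054413294", "110001110001", "Aquatic"),
)

# Named worked-example enzymes patterns quoted in the study's analyses.
_WORKED_EXAMPLES = {
    "Marinobacter denitrificans JB02H27": "111111111001",
    "Nisaea denitrificans DSM 18348": "000111011001",
    "Shewanella denitrificans OS217": "000111011001",
    "Arcobacter sp. LA11": "000110111001",
    "Pseudoalteromonas denitrificans DSM 6059": "000110111001",
    "Aliarcobacter cryaerophilus AZT-1": "000010111000",
    "Psychrobacter maritimus Pi2-25": "111001010010",
    "Roseibium (pattern 1)": "000000111001",
    "Roseibium (pattern 2)": "000001011001",
    "Roseibium (pattern 3)": "000110111001",
}


@dataclass(frozen=True)
class PaperFixtures:
    """Packaged printed reference data.

    Attributes
    ----------
    table5_examples : DataFrame
        Nine archaeal trait categories with example genomes and patterns.
    table6_rows : DataFrame
        21 archaeal genomes encoding both nirK and nirS.
    worked_examples : dict
        Genome name -> quoted 12-digit enzymes pattern.
    """

    table5_examples: pd.DataFrame
    table6_rows: pd.DataFrame
    worked_examples: dict[str, str]


def load_paper_fixtures() -> PaperFixtures:
    """Return the packaged printed tables and worked-example patterns."""
    table5 = pd.DataFrame(
        _TABLE5,
        columns=[CODE_COLUMN, "Denitrification Traits", "Genome Count",
                 "Example Genome", PATTERN_COLUMN],
    )
    table6 = pd.DataFrame(
        _TABLE6,
        columns=["Genome Name", "Genome ID", PATTERN_COLUMN, "Ecosystem Category"],
    )
    return PaperFixtures(
        table5_examples=table5,
        table6_rows=table6,
        worked_examples=dict(_WORKED_EXAMPLES),
    )


def table6_input_matrix() -> pd.DataFrame:
    """The 21 nirK+nirS archaeal genomes as a build-ready presence matrix.

    Expands each printed pattern into per-gene boolean columns in the form
    :func:`~denitrait.dataset.build_dataset` accepts, with the ecosystem
    category carried as annotation.
    """
    from .catalog import denitrification_catalog
    from .rules import pattern_to_presence

    catalog = denitrification_catalog()
    rows = []
    for name, gid, pattern, eco_cat in _TABLE6:
        row = {
            "Genome ID": gid,
            "Genome Name": name,
            "Domain": "Archaea",
            "Status": "Finished",
            "Ecosystem Category": eco_cat,
        }
        row.update(pattern_to_presence(pattern, catalog))
        rows.append(row)
    return pd.DataFrame(rows)
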