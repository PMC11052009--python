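"""Dataset assembly and analytics tests, mostly over the printed archaeal tables."""

import pandas as pd
import pytest

from denitrait import (
    annotate_auxiliary_kos,
    apply_trait_rules,
    build_dataset,
    count_distinct,
    dataset_columns,
    detect_replicate_strains,
    export_dataset,
    filter_dataset,
    load_paper_fixtures,
    read_dataset,
    summarize,
    table6_input_matrix,
    trait_name,
)
from denitrait.dataset import CODE_COLUMN, PATTERN_COLUMN, TRAIT_COLUMN
from denitrait.ingest import KOGenomeList


class TestBuildDataset:
    def test_table6_rows_rebuild_to_printed_patterns(self, table6_dataset):
        fx = load_paper_fixtures()
        built = table6_dataset.set_index("Genome ID")[PATTERN_COLUMN]
        printed = fx.table6_rows.set_index("Genome ID")[PATTERN_COLUMN]
        assert built.sort_index().equals(printed.sort_index())

    def test_has_36_canonical_columns(self, table6_dataset, catalog):
        cols = dataset_columns(catalog)
        assert len(cols) == 36
        assert list(table6_dataset.columns) == cols

    def test_single_gene_genome(self, ruleset, catalog):
        matrix = pd.DataFrame([{
            "Genome ID": "g1", "Genome Name": "Thermus sp. X",
            **{s: s == "nosZ" for s in catalog.gene_symbols},
        }])
        ds = build_dataset(matrix, ruleset, catalog)
        assert ds.loc[0, PATTERN_COLUMN] == "000000000001"
        assert ds.loc[0, CODE_COLUMN] == "0001"
        assert ds.loc[0, TRAIT_COLUMN] == "Nitrous Oxide Reduction Only"
        assert ds.loc[0, "Genus"] == "Thermus"

    def test_all_zero_genomes_excluded(self, ruleset, catalog):
        matrix = pd.DataFrame([
            {"Genome ID": "g1", "Genome Name": "A x", **{s: False for s in catalog.gene_symbols}},
            {"Genome ID": "g2", "Genome Name": "B x", **{s: s == "nirK" for s in catalog.gene_symbols}},
        ])
        ds = build_dataset(matrix, ruleset, catalog)
        assert list(ds["Genome ID"]) == ["g2"]

    def test_stored_code_and_trait_are_self_consistent(self, table6_dataset, ruleset, catalog):
        from denitrait.dataset import enzyme_columns

        for _, row in table6_dataset.iterrows():
            code = apply_trait_rules(row[PATTERN_COLUMN], ruleset)
            assert row[CODE_COLUMN] == code
            assert row[TRAIT_COLUMN] == trait_name(code)
            for i, col in enumerate(enzyme_columns(catalog)):
                assert str(row[col]) == row[PATTERN_COLUMN][i]

    def test_trait_partition_sums_to_dataset_size(self, table6_dataset):
        by_trait = summarize(table6_dataset, [TRAIT_COLUMN])
        assert by_trait["genome_count"].sum() == len(table6_dataset)

    def test_nosz_trait_consistency(self, table6_dataset):
        # genomes whose last pattern digit is '1' are exactly those in the
        # eight codes ending in '1'
        with_nosz = set(table6_dataset.loc[
            table6_dataset[PATTERN_COLUMN].str[-1] == "1", "Genome ID"])
        nosz_codes = {c for c in table6_dataset[CODE_COLUMN].unique() if c.endswith("1")}
        via_codes = set(table6_dataset.loc[
            table6_dataset[CODE_COLUMN].isin(nosz_codes), "Genome ID"])
        assert with_nosz == via_codes


class TestReplicates:
    def test_table6_replicate_strains(self, table6_dataset):
        reps = detect_replicate_strains(table6_dataset)
        assert reps.to_dict() == {
            "Halobiforma lacisalsi AJ5, JCM 12983": 2,
            "Natrinema pellirubrum 157": 2,
            "Natrinema thermotolerans A29": 2,
        }

    def test_unique_names_give_empty_result(self, ruleset, catalog):
        matrix = pd.DataFrame([
            {"Genome ID": f"g{i}", "Genome Name": f"Genus sp{i} X",
             **{s: s == "nosZ" for s in catalog.gene_symbols}}
            for i in range(4)
        ])
        assert detect_replicate_strains(build_dataset(matrix, ruleset, catalog)).empty

    def test_five_records_sharing_one_name(self, ruleset, catalog):
        matrix = pd.DataFrame([
            {"Genome ID": f"g{i}", "Genome Name": "Brucella melitensis bv. 1 16 M",
             **{s: s == "nosZ" for s in catalog.gene_symbols}}
            for i in range(5)
        ])
        reps = detect_replicate_strains(build_dataset(matrix, ruleset, catalog))
        assert reps.to_dict() == {"Brucella melitensis bv. 1 16 M": 5}


class TestSummaries:
    def test_table6_ecosystem_category_tally(self, table6_dataset):
        table = summarize(table6_dataset, ["Ecosystem Category"]).set_index("Ecosystem Category")
        assert table["genome_count"].to_dict() == {
            "Aquatic": 9, "Terrestrial": 8, "Fish": 2, "Food production": 2,
        }

    def test_table5_patterns_group_to_singletons(self, ruleset, catalog):
        fx = load_paper_fixtures()
        rows = []
        for _, r in fx.table5_examples.iterrows():
            from denitrait import pattern_to_presence
            row = {"Genome ID": r["Example Genome"], "Genome Name": r["Example Genome"]}
            row.update(pattern_to_presence(r[PATTERN_COLUMN], catalog))
            rows.append(row)
        ds = build_dataset(pd.DataFrame(rows), ruleset, catalog)
        table = summarize(ds, [CODE_COLUMN])
        assert len(table) == 9
        assert (table["genome_count"] == 1).all()

    def test_missing_annotation_rendered_as_null(self, ruleset, catalog):
        matrix = pd.DataFrame([
            {"Genome ID": "g1", "Genome Name": "A x", "Ecosystem Category": "Aquatic",
             **{s: s == "nosZ" for s in catalog.gene_symbols}},
            {"Genome ID": "g2", "Genome Name": "B x",
             **{s: s == "nosZ" for s in catalog.gene_symbols}},
        ])
        ds = build_dataset(matrix, ruleset, catalog)
        table = summarize(ds, ["Ecosystem Category"]).set_index("Ecosystem Category")
        assert table.loc["Null", "genome_count"] == 1

    def test_empty_dataset_gives_empty_summary(self, table6_dataset):
        assert summarize(table6_dataset.iloc[:0], [TRAIT_COLUMN]).empty

    def test_unknown_key_rejected(self, table6_dataset):
        with pytest.raises(KeyError, match="No Such"):
            summarize(table6_dataset, ["No Such Column"])


class TestCountDistinct:
    def test_table6_distinct_genera(self, table6_dataset):
        assert count_distinct(table6_dataset, "Genus") == 7

    def test_table6_distinct_strains(self, table6_dataset):
        assert count_distinct(table6_dataset, "Genome Name") == 18

    def test_single_row(self, table6_dataset):
        assert count_distinct(table6_dataset.iloc[:1], PATTERN_COLUMN) == 1


class TestFilter:
    def test_nirk_and_nirs_filter_keeps_all_21(self, table6_dataset):
        subset = filter_dataset(table6_dataset, equals={"E06_nirK": 1, "E07_nirS": 1})
        assert len(subset) == 21

    def test_name_contains_is_case_insensitive(self, table6_dataset):
        subset = filter_dataset(table6_dataset, name_contains="natrinema")
        assert len(subset) == 10

    def test_conjunction_of_predicates(self, table6_dataset):
        subset = filter_dataset(
            table6_dataset,
            equals={"Ecosystem Category": "Aquatic"},
            name_contains="Natrinema",
        )
        assert set(subset["Genome Name"]) == {
            "Natrinema altunense AJ2",
            "Natrinema altunense JCM 12890",
            "Natrinema thermotolerans DSM 11552",
        }

    def test_empty_predicates_is_identity(self, table6_dataset):
        pd.testing.assert_frame_equal(filter_dataset(table6_dataset), table6_dataset)

    def test_isin_predicate(self, table6_dataset):
        subset = filter_dataset(table6_dataset, isin={"Ecosystem Category": ["Fish", "Food production"]})
        assert len(subset) == 4


class TestAuxAnnotation:
    def _aux_list(self, ko_id, symbol, ids):
        frame = pd.DataFrame(
            [("Archaea", "Finished", gid, f"Genome {gid}") for gid in ids],
            columns=["Domain", "Status", "Genome ID", "Genome Name"],
        )
        return KOGenomeList(f"00_{symbol}", ko_id, frame)

    def test_counts_planted_carriers(self, table6_dataset):
        carriers = list(table6_dataset["Genome ID"][:5])
        annotated, counts = annotate_auxiliary_kos(
            table6_dataset, {"K01915": self._aux_list("K01915", "glnA", carriers)}
        )
        assert counts.loc[0, "genome_count"] == 5
        assert set(annotated.loc[annotated["glnA_K01915"], "Genome ID"]) == set(carriers)

    def test_empty_list_gives_zero_count(self, table6_dataset):
        annotated, counts = annotate_auxiliary_kos(
            table6_dataset, {"K02588": self._aux_list("K02588", "nifH", [])}
        )
        assert counts.loc[0, "genome_count"] == 0
        assert not annotated["nifH_K02588"].any()

    def test_unknown_genome_ids_ignored(self, table6_dataset):
        annotated, counts = annotate_auxiliary_kos(
            table6_dataset, {"K01601": self._aux_list("K01601", "cbbL", ["nope1", "nope2"])}
        )
        assert counts.loc[0, "genome_count"] == 0


def _normalize_missing(df):
    return df.astype(object).where(df.notna(), None)


class TestExport:
    @pytest.mark.parametrize("fmt", ["csv", "tsv", "xlsx"])
    def test_round_trip(self, table6_dataset, tmp_path, fmt):
        path = export_dataset(table6_dataset, tmp_path / f"ds.{fmt}", fmt)
        back = read_dataset(path, fmt)
        assert list(back.columns) == list(table6_dataset.columns)
        a = _normalize_missing(back)
        b = _normalize_missing(table6_dataset)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    @pytest.mark.parametrize("fmt", ["csv", "tsv", "xlsx"])
    def test_leading_zeros_preserved(self, table6_dataset, tmp_path, fmt):
        path = export_dataset(table6_dataset, tmp_path / f"ds.{fmt}", fmt)
        back = read_dataset(path, fmt)
        assert (back[CODE_COLUMN].str.len() == 4).all()
        assert (back[PATTERN_COLUMN].str.len() == 12).all()
        assert set(back[CODE_COLUMN]) == set(table6_dataset[CODE_COLUMN])

    def test_csv_and_tsv_reimport_equal(self, table6_dataset, tmp_path):
        a = read_dataset(export_dataset(table6_dataset, tmp_path / "a.csv", "csv"))
        b = read_dataset(export_dataset(table6_dataset, tmp_path / "b.tsv", "tsv"))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_format_rejected(self, table6_dataset, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            export_dataset(table6_dataset, tmp_path / "x.parquet", "parquet")
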