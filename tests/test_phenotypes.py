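import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclust.phenotypes import (
    ALL_TRAITS,
    BIN_LABELS,
    CATEGORICAL_TRAITS,
    DEFAULT_ORDINAL_MAP,
    ConversionError,
    SchemaError,
    ValidationError,
    bin_continuous,
    classify_global_phenotypes,
    default_schema,
    filter_complete,
    read_phenotype_table,
    to_ordinal,
)

from conftest import make_record, make_table


class TestReadWrite:
    def test_round_trip_preserves_table(self, toy_table, tmp_path):
        path = tmp_path / "table.csv"
        toy_table.to_csv(path)
        back = read_phenotype_table(str(path))
        pd.testing.assert_frame_equal(
            back.data, toy_table.data, check_dtype=False, check_exact=False
        )
        assert back.complete_mask.all()

    def test_blank_cell_marks_record_incomplete(self, tmp_path):
        table = make_table([make_record("a"), make_record("b")])
        table.data.loc[1, "ascospore_number"] = np.nan
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = read_phenotype_table(str(path))
        assert list(back.complete_mask) == [True, False]

    def test_bad_label_names_gene_trait_and_label(self, tmp_path):
        table = make_table([make_record("NCU999")])
        path = tmp_path / "t.csv"
        table.to_csv(path)
        text = path.read_text().replace("Normal,Normal", "Norml,Normal", 1)
        with pytest.raises(ValidationError, match="NCU999.*conidia_number.*Norml"):
            read_phenotype_table(io.StringIO(text))

    def test_missing_column_is_schema_error(self):
        csv = "gene_id,growth_rate\nA,80\n"
        with pytest.raises(SchemaError, match="aerial_height|conidia"):
            read_phenotype_table(io.StringIO(csv))

    def test_duplicate_gene_id_names_the_id(self):
        with pytest.raises(ValidationError, match="dup1"):
            make_table([make_record("dup1"), make_record("dup1")])

    def test_column_map_renames_traits(self, tmp_path):
        table = make_table([make_record("A")])
        df = table.data.rename(columns={"growth_rate": "basal.growth"})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        back = read_phenotype_table(str(path), column_map={"growth_rate": "basal.growth"})
        assert back.data.loc[0, "growth_rate"] == 80.0


class TestFilterComplete:
    def test_counting_matches_planted_missingness(self, rng):
        # 1286 records, exactly 118 made incomplete: the retained count is
        # the complement, independently countable from the planted indices.
        rows = [make_record(f"G{i:05d}") for i in range(1286)]
        table = make_table(rows)
        incomplete = rng.choice(1286, size=118, replace=False)
        for i in incomplete:
            trait = ALL_TRAITS[int(rng.integers(len(ALL_TRAITS)))]
            table.data.loc[int(i), trait] = np.nan
        kept = filter_complete(table)
        assert len(kept) == 1286 - 118 == 1168
        assert not set(kept.gene_ids) & {f"G{int(i):05d}" for i in incomplete}

    def test_all_complete_is_identity(self, toy_table):
        kept = filter_complete(toy_table)
        pd.testing.assert_frame_equal(kept.data, toy_table.data)

    def test_all_incomplete_yields_empty_table(self):
        table = make_table([make_record("A"), make_record("B")])
        table.data.loc[:, "growth_rate"] = np.nan
        assert len(filter_complete(table)) == 0


class TestBinContinuous:
    @pytest.mark.parametrize(
        "value,trait,expected",
        [
            (80.0, "growth", "Normal Average"),
            (39.0, "growth", "Severely Reduced"),
            (75.0, "growth", "Normal Low"),
            (77.6, "growth", "Normal Average"),
            (82.6, "growth", "Normal High"),
            (85.0, "growth", "Normal High"),
            (85.1, "growth", "Increased"),
            (64.9, "growth", "Reduced"),
            (74.95, "growth", "Normal Low"),  # rounds to 75.0
            (46.0, "aerial", "Increased"),
            (37.0, "aerial", "Normal Average"),
            (30.0, "aerial", "Normal Low"),
            (29.5, "aerial", "Normal Low"),  # unprinted gap goes up
            (29.0, "aerial", "Slightly Reduced"),
            (14.9, "aerial", "Severely Reduced"),
        ],
    )
    def test_reference_range_bins(self, value, trait, expected):
        assert bin_continuous(value, trait) == expected

    @given(
        value=st.floats(min_value=0, max_value=500, allow_nan=False),
        trait=st.sampled_from(["growth", "aerial"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_binning_is_total_on_nonnegatives(self, value, trait):
        assert bin_continuous(value, trait) in BIN_LABELS

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            bin_continuous(-1.0, "growth")


class TestToOrdinal:
    def test_severity_scale_endpoints(self):
        table = make_table(
            [
                make_record("A", conidia_number="Not Formed"),
                make_record("B", conidia_number="Normal"),
                make_record("C", conidia_number="Increased"),
            ]
        )
        X = to_ordinal(table)
        assert list(X["conidia_number"]) == [0.0, 1.0, 1.5]

    def test_all_normal_abundances_convert_to_ones(self):
        table = make_table([make_record("A"), make_record("B", growth_rate=60.0)])
        X = to_ordinal(table)
        for trait in ("conidia_number", "protoperithecia_number", "perithecia_number", "ascospore_number"):
            assert (X[trait] == 1.0).all()
        # morphology traits are excluded; continuous traits are z-scored
        assert set(X.columns) == {
            "growth_rate", "aerial_height",
            "conidia_number", "protoperithecia_number",
            "perithecia_number", "ascospore_number",
        }
        assert abs(X["growth_rate"].mean()) < 1e-12
        assert abs(X["growth_rate"].std(ddof=1) - 1.0) < 1e-12

    def test_uncovered_label_raises_naming_trait(self):
        table = make_table([make_record("A", conidia_number="Increased")])
        partial = {k: v for k, v in DEFAULT_ORDINAL_MAP.items() if k != "Increased"}
        with pytest.raises(ConversionError, match="conidia_number.*Increased"):
            to_ordinal(table, partial)


class TestGlobalClassification:
    def test_planted_defect_classes_are_counted(self):
        rows = [make_record(f"g{i}", growth_rate=50.0) for i in range(7)]  # growth only
        rows += [make_record(f"a{i}", conidia_number="Reduced") for i in range(2)]  # asexual only
        rows += [make_record("gs0", growth_rate=90.0, ascospore_number="Not Formed")]  # growth+sexual
        rows += [make_record(f"wt{i}") for i in range(3)]  # no phenotype
        summary = classify_global_phenotypes(make_table(rows))
        assert summary.class_counts == {"growth": 8, "asexual": 2, "sexual": 1}
        assert summary.total_global_phenotypes == 11
        assert summary.n_with_phenotype == 10
        assert summary.n_no_phenotype == 3
        assert summary.venn["growth+sexual"] == 1
        assert summary.venn["growth_only"] == 7

    def test_increased_growth_counts_as_growth_defect_only(self):
        summary = classify_global_phenotypes(make_table([make_record("A", growth_rate=90.0)]))
        row = summary.flags.iloc[0]
        assert row["growth_defect"] and not row["asexual_defect"] and not row["sexual_defect"]

    def test_class_counts_bounded_by_any_defect(self, rng):
        from phenoclust.simulate import collection_like_config, simulate_phenotypes

        table, _ = simulate_phenotypes(collection_like_config(seed=3))
        summary = classify_global_phenotypes(table)
        total = summary.total_global_phenotypes
        assert summary.n_with_phenotype <= total <= 3 * summary.n_with_phenotype

    def test_incomplete_table_rejected(self):
        table = make_table([make_record("A")])
        table.data.loc[0, "growth_rate"] = np.nan
        with pytest.raises(ValidationError):
            classify_global_phenotypes(table)
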