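import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenoclust.cluster import ClusterAssignment, pam
from phenoclust.dissimilarity import PRESETS, gower_matrix
from phenoclust.phenotypes import CATEGORICAL_TRAITS, CONTINUOUS_TRAITS
from phenoclust.quality import (
    QualityReport,
    cluster_summary,
    guideline_check,
    percent_consensus,
    relative_sd,
    run_quality,
    weight_scan,
)
from phenoclust.simulate import (
    PhenotypeSimConfig,
    random_archetypes,
    simulate_phenotypes,
)

from conftest import make_record, make_table


def truth_assignment(table, truth, method="truth"):
    return ClusterAssignment(
        ids=table.gene_ids,
        labels=np.asarray(truth),
        k=int(np.max(truth)),
        method=method,
        total_cost=float("nan"),
    )


class TestRelativeSd:
    def test_constant_sample_has_zero_rsd(self):
        assert relative_sd([80, 80, 80]) == 0.0

    def test_two_point_hand_computation(self):
        # SD = 7.0711 (n-1), mean = 15 -> 47.14%
        assert relative_sd([10, 20]) == pytest.approx(47.14, abs=0.01)

    def test_singleton_convention_is_zero(self):
        assert relative_sd([42]) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_sd([1e-12, -1e-12])
        with pytest.raises(ValueError):
            relative_sd([])


class TestPercentConsensus:
    def test_six_of_ten_shared_labels_is_sixty_percent(self):
        labels = ["Reduced"] * 6 + ["Normal"] * 3 + ["Increased"]
        cons = percent_consensus(labels)
        assert cons.percent == 60.0
        assert cons.majority == "Reduced"
        assert not cons.tie

    def test_unanimous_cluster_is_hundred_percent(self):
        assert percent_consensus(["Normal"] * 5).percent == 100.0

    def test_tie_broken_by_vocabulary_order_and_flagged(self):
        cons = percent_consensus(["B", "B", "A", "A"], vocabulary=("B", "A"))
        assert cons.percent == 50.0
        assert cons.majority == "B"
        assert cons.tie


class TestRunQuality:
    def test_pure_planted_clusters_score_perfectly(self):
        arch = random_archetypes(3, np.random.default_rng(0), consensus=1.0, cont_sd_frac=0.0)
        cfg = PhenotypeSimConfig(sizes=(5, 5, 5), archetypes=arch, seed=0)
        table, truth = simulate_phenotypes(cfg)
        report = run_quality(truth_assignment(table, truth), table)
        assert report.composite_consensus == 100.0
        assert report.composite_rsd == pytest.approx(0.0, abs=1e-9)

    def test_single_cluster_equals_whole_table_statistics(self):
        arch = random_archetypes(2, np.random.default_rng(1))
        cfg = PhenotypeSimConfig(sizes=(10, 10), archetypes=arch, seed=1)
        table, _ = simulate_phenotypes(cfg)
        report = run_quality(truth_assignment(table, np.ones(20, dtype=int)), table)
        # direct whole-table recomputation
        for trait in CONTINUOUS_TRAITS:
            x = table.data[trait].astype(float)
            expected = 100 * x.std(ddof=1) / x.mean()
            assert report.per_trait_average[trait] == pytest.approx(expected)
        for trait in CATEGORICAL_TRAITS:
            share = 100 * table.data[trait].value_counts().max() / 20
            assert report.per_trait_average[trait] == pytest.approx(share)

    def test_consensus_tracks_planted_mixing_rate(self):
        p = 0.80
        arch = random_archetypes(4, np.random.default_rng(2), consensus=p)
        cfg = PhenotypeSimConfig(sizes=(60,) * 4, archetypes=arch, seed=2)
        table, truth = simulate_phenotypes(cfg)
        report = run_quality(truth_assignment(table, truth), table)
        assert report.composite_consensus == pytest.approx(100 * p, abs=3.0)

    def test_composites_recompute_from_per_trait_averages(self):
        arch = random_archetypes(3, np.random.default_rng(3))
        cfg = PhenotypeSimConfig(sizes=(8, 8, 8), archetypes=arch, seed=3)
        table, truth = simulate_phenotypes(cfg)
        report = run_quality(truth_assignment(table, truth), table)
        assert report.composite_rsd == pytest.approx(
            np.mean([report.per_trait_average[t] for t in CONTINUOUS_TRAITS])
        )
        assert report.composite_consensus == pytest.approx(
            np.mean([report.per_trait_average[t] for t in CATEGORICAL_TRAITS])
        )

    def test_row_permutation_leaves_statistics_unchanged(self):
        arch = random_archetypes(3, np.random.default_rng(4))
        cfg = PhenotypeSimConfig(sizes=(7, 7, 7), archetypes=arch, seed=4)
        table, truth = simulate_phenotypes(cfg)
        report1 = run_quality(truth_assignment(table, truth), table)
        perm = np.random.default_rng(0).permutation(len(table))
        shuffled = table.data.iloc[perm].reset_index(drop=True)
        from phenoclust.phenotypes import PhenotypeTable

        table2 = PhenotypeTable(schema=table.schema, data=shuffled)
        report2 = run_quality(
            truth_assignment(table2, np.asarray(truth)[perm]), table2
        )
        assert report1.composite_consensus == pytest.approx(report2.composite_consensus)
        assert report1.composite_rsd == pytest.approx(report2.composite_rsd)

    def test_merging_two_pure_clusters_lowers_consensus(self):
        arch = random_archetypes(2, np.random.default_rng(5), consensus=1.0, cont_sd_frac=0.01)
        cfg = PhenotypeSimConfig(sizes=(6, 6), archetypes=arch, seed=5)
        table, truth = simulate_phenotypes(cfg)
        pure = run_quality(truth_assignment(table, truth), table)
        merged = run_quality(truth_assignment(table, np.ones(12, dtype=int)), table)
        assert merged.composite_consensus < pure.composite_consensus

    def test_gene_missing_from_table_rejected(self, toy_table):
        assignment = ClusterAssignment(
            ids=("NCU00001", "ghost"), labels=np.array([1, 1]), k=1,
            method="x", total_cost=0.0,
        )
        with pytest.raises(ValueError, match="ghost"):
            run_quality(assignment, toy_table)


class TestGuidelines:
    def _report(self, sizes, rsd, consensus):
        per_cluster = pd.DataFrame({"cluster": range(1, len(sizes) + 1), "size": sizes})
        return QualityReport(
            per_cluster=per_cluster,
            per_trait_average=pd.Series(dtype=float),
            composite_rsd=rsd,
            composite_consensus=consensus,
        )

    def test_two_gene_cluster_fails_min_size(self):
        verdict = guideline_check(self._report([2, 10], 10.0, 96.0))
        assert not verdict.min_size_ok and not verdict.passed

    def test_compliant_run_passes_all_guidelines(self):
        verdict = guideline_check(self._report([5] * 40, 10.98, 96.0))
        assert verdict.passed

    def test_forty_one_clusters_fail_max_k(self):
        verdict = guideline_check(self._report([5] * 41, 10.0, 96.0))
        assert not verdict.max_clusters_ok

    def test_boundary_semantics(self):
        assert not guideline_check(self._report([5] * 10, 15.0, 96.0)).rsd_ok
        assert guideline_check(self._report([5] * 10, 14.99, 95.0)).consensus_ok


@pytest.fixture(scope="module")
def continuous_signal_table():
    # clusters separated mainly by the continuous traits: categorical
    # consensus is weak (p=0.5), continuous spread tight
    arch = random_archetypes(
        5, np.random.default_rng(7), consensus=0.5, cont_sd_frac=0.02
    )
    cfg = PhenotypeSimConfig(sizes=(25,) * 5, archetypes=arch, seed=7)
    return simulate_phenotypes(cfg)


class TestWeightScan:
    def test_scan_shape_and_finiteness(self, continuous_signal_table):
        table, _ = continuous_signal_table
        scan = weight_scan(table, [PRESETS["NoWeight"], PRESETS["W6"]], [4, 5])
        assert len(scan) == 4
        assert scan["composite_consensus"].notna().all()
        assert scan["composite_rsd"].notna().all()
        assert scan["best"].sum() == 1

    def test_continuous_upweighting_sharpens_continuous_recovery(self, continuous_signal_table):
        table, _ = continuous_signal_table
        scan = weight_scan(table, [PRESETS["NoWeight"], PRESETS["W6"]], [5])
        by = scan.set_index("weights")
        assert (
            by.loc["W6", "composite_rsd"] < by.loc["NoWeight", "composite_rsd"]
        )

    def test_single_cell_scan_matches_run_quality(self, continuous_signal_table):
        table, _ = continuous_signal_table
        scan = weight_scan(table, [PRESETS["W6"]], [5])
        D = gower_matrix(table, PRESETS["W6"])
        report = run_quality(pam(D, 5), table)
        assert scan.loc[0, "composite_consensus"] == pytest.approx(report.composite_consensus)
        assert scan.loc[0, "composite_rsd"] == pytest.approx(report.composite_rsd)

    def test_planted_k_recovered_and_consensus_rises_to_it(self):
        # below the planted k, clusters are forcibly merged and consensus
        # drops; at the planted k recovery is essentially exact
        arch = random_archetypes(8, np.random.default_rng(42), consensus=0.97, cont_sd_frac=0.03)
        cfg = PhenotypeSimConfig(sizes=(20,) * 8, archetypes=arch, seed=42)
        table, truth = simulate_phenotypes(cfg)
        D = gower_matrix(table, PRESETS["W6"])
        consensus = {}
        for k in (6, 7, 8):
            a = pam(D, k)
            consensus[k] = run_quality(a, table).composite_consensus
            if k == 8:
                assert adjusted_rand_score(truth, a.labels) >= 0.9
        assert consensus[6] < consensus[7] < consensus[8]

    def test_empty_scan_arguments_rejected(self, continuous_signal_table):
        table, _ = continuous_signal_table
        with pytest.raises(ValueError):
            weight_scan(table, [], [5])


class TestClusterSummary:
    def test_majority_growth_bin_formatting(self):
        rows = [make_record(f"g{i}", growth_rate=80.0) for i in range(6)]
        rows += [make_record(f"h{i}", growth_rate=50.0) for i in range(2)]
        table = make_table(rows)
        summary = cluster_summary(truth_assignment(table, [1] * 8), table)
        assert summary.loc[0, "growth_rate"] == "75% Normal Average"

    def test_no_majority_over_half_reads_varied(self):
        rows = [make_record(f"a{i}", conidia_number="Reduced") for i in range(4)]
        rows += [make_record(f"b{i}", conidia_number="Not Formed") for i in range(3)]
        rows += [make_record(f"c{i}", conidia_number="Increased") for i in range(3)]
        table = make_table(rows)
        summary = cluster_summary(truth_assignment(table, [1] * 10), table)
        assert summary.loc[0, "conidia_number"] == "Varied"

    def test_pure_cluster_reads_hundred_percent_everywhere(self):
        table = make_table([make_record(f"g{i}") for i in range(4)])
        summary = cluster_summary(truth_assignment(table, [1] * 4), table)
        for trait in CATEGORICAL_TRAITS:
            assert summary.loc[0, trait] == "100% Normal"
        assert summary.loc[0, "growth_rate"] == "100% Normal Average"
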