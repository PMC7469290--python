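"""Annotation filtering, functional profiles and taxon attribution."""

import numpy as np
import pandas as pd
import pytest

from magcentric import attribution, reference
from magcentric.attribution import AnnotationHit, DAContext, TOTAL_GROUP


def hit(protein="p1", mag="m1", target="K00001", identity=90.0, coverage=0.9,
        e_value=1e-30):
    return AnnotationHit(protein, mag, target, identity, coverage, e_value)


class TestHitFilters:
    @pytest.mark.parametrize(
        "identity,e_value,kept",
        [(50.0, 1e-6, True), (49.9, 1e-30, False), (80.0, 1e-5, False),
         (100.0, 0.0, True)],
    )
    def test_ko_thresholds(self, identity, e_value, kept):
        hits = attribution.filter_ko_hits([hit(identity=identity, e_value=e_value)])
        assert bool(hits) is kept

    @pytest.mark.parametrize(
        "coverage,e_value,kept",
        [(0.35, 1e-19, True), (0.349, 1e-30, False), (0.9, 1e-18, False)],
    )
    def test_cazy_thresholds(self, coverage, e_value, kept):
        hits = attribution.filter_cazy_hits([hit(coverage=coverage, e_value=e_value)])
        assert bool(hits) is kept

    def test_invalid_hit_rejected(self):
        with pytest.raises(ValueError):
            hit(identity=120.0)
        with pytest.raises(ValueError):
            hit(coverage=1.5)
        with pytest.raises(ValueError):
            hit(e_value=-1.0)


class TestAnnotationMatrix:
    def test_counts_per_mag_and_target(self):
        hits = [hit(protein=f"p{i}") for i in range(3)]
        mat = attribution.build_annotation_matrix(hits, ["m1", "m2"])
        assert mat.loc["m1", "K00001"] == 3
        assert mat.loc["m2", "K00001"] == 0

    def test_empty_hits_keep_declared_rows(self):
        mat = attribution.build_annotation_matrix([], ["m1", "m2"])
        assert list(mat.index) == ["m1", "m2"]
        assert mat.shape[1] == 0

    def test_protein_counts_once_per_distinct_target(self):
        hits = [
            hit(protein="p", target="K1", e_value=1e-40),
            hit(protein="p", target="K1", e_value=1e-20),  # worse duplicate
            hit(protein="p", target="K2"),
        ]
        mat = attribution.build_annotation_matrix(hits, ["m1"])
        assert mat.loc["m1", "K1"] == 1
        assert mat.loc["m1", "K2"] == 1

    def test_unknown_mag_rejected(self):
        with pytest.raises(ValueError, match="unknown MAG"):
            attribution.build_annotation_matrix([hit(mag="ghost")], ["m1"])


class TestCazySummaries:
    def test_published_module_counts(self):
        out = attribution.cazy_module_percentages(
            reference.CAZY_MODULE_COUNTS["african_mags"]
        )
        assert out["count"].sum() == 69628
        assert out.loc["GH", "percent"] == 56.82
        assert out.loc["GT", "percent"] == 25.09

    def test_single_module_is_100(self):
        mat = pd.DataFrame({"GH13": [3, 2]}, index=["m1", "m2"])
        out = attribution.cazy_module_percentages(mat, {"GH13": "GH"})
        assert out.loc["GH", "percent"] == 100.0

    def test_missing_module_assignment_rejected(self):
        mat = pd.DataFrame({"GH13": [1]}, index=["m1"])
        with pytest.raises(ValueError, match="module"):
            attribution.cazy_module_percentages(mat, {})

    def test_phylum_rows_sum_to_100(self):
        mat = pd.DataFrame(
            {"GH2": [10, 0], "GT2": [5, 3], "PL1": [0, 7]}, index=["m1", "m2"]
        )
        taxonomy = pd.DataFrame(
            {"genome_id": ["m1", "m2"], "phylum": ["A", "B"]}
        )
        out = attribution.phylum_cazy_proportions(
            mat, taxonomy, {"GH2": "GH", "GT2": "GT", "PL1": "PL"}
        )
        np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=0.01)
        assert out.loc["A", "GH"] == pytest.approx(100 * 10 / 15, abs=0.01)

    def test_planted_mixture_recovered_exactly(self):
        mat = pd.DataFrame({"GH2": [30, 30], "GT2": [10, 10]}, index=["m1", "m2"])
        taxonomy = pd.DataFrame({"genome_id": ["m1", "m2"], "phylum": ["X", "X"]})
        out = attribution.phylum_cazy_proportions(
            mat, taxonomy, {"GH2": "GH", "GT2": "GT"}
        )
        assert out.loc["X", "GH"] == 75.0 and out.loc["X", "GT"] == 25.0


class TestHeatmapInput:
    def _toy(self):
        mags = [f"m{i}" for i in range(6)]
        taxonomy = pd.DataFrame(
            {"genome_id": mags,
             "phylum": ["P1"] * 3 + ["P2"] * 3,
             "genus": ["g1", "g1", "g2", "g3", "g3", "g4"]}
        )
        mat = pd.DataFrame(
            {"famA": [9, 8, 9, 0, 1, 0], "famB": [9, 9, 8, 0, 0, 1],
             "famC": [0, 1, 0, 9, 8, 9], "famD": [5, 5, 5, 5, 5, 5]},
            index=mags,
        )
        return mat, taxonomy

    def test_correlated_columns_adjacent_constant_last(self):
        mat, taxonomy = self._toy()
        log_mat, order = attribution.cazy_family_heatmap_input(mat, taxonomy)
        assert order[-1] == "famD"  # constant across groups
        assert abs(order.index("famA") - order.index("famB")) == 1

    def test_log_transform_of_zero(self):
        mat, taxonomy = self._toy()
        log_mat, _ = attribution.cazy_family_heatmap_input(mat, taxonomy)
        assert log_mat.loc["m3", "famA"] == 0.0
        assert log_mat.loc["m0", "famA"] == pytest.approx(np.log(10))

    def test_rows_in_taxonomy_order(self):
        mat, taxonomy = self._toy()
        log_mat, _ = attribution.cazy_family_heatmap_input(mat, taxonomy)
        phyla = taxonomy.set_index("genome_id").loc[log_mat.index, "phylum"]
        assert list(phyla) == sorted(phyla)


class TestKoPerSample:
    def test_hand_example(self):
        ko = pd.DataFrame({"K1": [2, 1], "K2": [0, 3]}, index=["m1", "m2"])
        ab = pd.DataFrame({"S": [10.0, 1.0]}, index=["m1", "m2"])
        out = attribution.ko_per_sample(ko, ab)
        assert out.loc["K1", "S"] == 21
        assert out.loc["K2", "S"] == 3

    def test_identity_abundance_copies_columns(self):
        ko = pd.DataFrame({"K1": [4], "K2": [7]}, index=["m1"])
        ab = pd.DataFrame({"S": [1.0]}, index=["m1"])
        out = attribution.ko_per_sample(ko, ab)
        assert out["S"].tolist() == [4, 7]

    def test_zero_abundance_contributes_nothing(self):
        ko = pd.DataFrame({"K1": [5, 9]}, index=["m1", "m2"])
        ab = pd.DataFrame({"S": [2.0, 0.0]}, index=["m1", "m2"])
        assert attribution.ko_per_sample(ko, ab).loc["K1", "S"] == 10

    def test_linear_in_abundance(self, rng):
        ko = pd.DataFrame(rng.integers(0, 5, size=(4, 3)), index=list("abcd"))
        ab = pd.DataFrame(rng.uniform(1, 10, size=(4, 2)), index=list("abcd"))
        one = attribution.ko_per_sample(ko, ab)
        two = attribution.ko_per_sample(ko, 2 * ab)
        np.testing.assert_allclose(two, 2 * one, atol=1)  # rounding slack

    def test_mismatched_mag_sets_rejected(self):
        ko = pd.DataFrame({"K1": [1]}, index=["m1"])
        ab = pd.DataFrame({"S": [1.0]}, index=["m2"])
        with pytest.raises(ValueError, match="MAG sets"):
            attribution.ko_per_sample(ko, ab)


class TestPathways:
    def test_member_sums_and_multimapping(self):
        ks = pd.DataFrame({"S": [3, 4, 5]}, index=["K1", "K2", "K3"])
        pmap = pd.DataFrame(
            {"ko": ["K1", "K2", "K3", "K3"], "pathway": ["p1", "p1", "p1", "p2"]}
        )
        out = attribution.aggregate_pathways(ks, pmap)
        assert out.loc["p1", "S"] == 12
        assert out.loc["p2", "S"] == 5
        assert out["S"].sum() >= ks["S"].sum()

    def test_empty_pathway_row_retained(self):
        ks = pd.DataFrame({"S": [1]}, index=["K1"])
        pmap = pd.DataFrame({"ko": ["K1", "K9"], "pathway": ["p1", "p_empty"]})
        out = attribution.aggregate_pathways(ks, pmap)
        assert out.loc["p_empty", "S"] == 0

    def test_unmapped_bucket(self):
        ks = pd.DataFrame({"S": [2, 3]}, index=["K1", "K2"])
        pmap = pd.DataFrame({"ko": ["K1"], "pathway": ["p1"]})
        out = attribution.aggregate_pathways(ks, pmap)
        assert out.loc["unassigned", "S"] == 3


def small_attribution_setup():
    mags = ["da1", "da2", "bg1"]
    taxonomy = pd.DataFrame(
        {"genome_id": mags, "phylum": ["P"] * 3,
         "genus": ["Prevotella", "Ruminococcus", "Other"]}
    )
    metadata = pd.DataFrame(
        {"sample_id": ["a", "b", "c", "d"],
         "animal": ["1", "2", "1", "2"],
         "period": [2, 2, 3, 3],
         "diet": [40, 40, 80, 80]}
    )
    ko = pd.DataFrame({"K1": [1, 1, 1]}, index=mags)
    pmap = pd.DataFrame({"ko": ["K1"], "pathway": ["path"]})
    return mags, taxonomy, metadata, ko, pmap


class TestTaxonContribution:
    def test_worked_lfc_example(self):
        """Aggregated counts 8 vs 2 with pseudocount 1 give log2(9/3)."""
        mags, taxonomy, metadata, ko, pmap = small_attribution_setup()
        ab = pd.DataFrame(
            {"a": [4.0, 0, 0], "b": [4.0, 0, 0], "c": [1.0, 0, 0], "d": [1.0, 0, 0]},
            index=mags,
        )
        ctx = DAContext(da_mags={"da1"})
        out = attribution.taxon_contribution(ctx, ko, ab, taxonomy, metadata, pmap)
        total = out[(out["taxon_group"] == TOTAL_GROUP) & (out["contrast"] == "40vs80")]
        assert total["count_low"].iloc[0] == 8
        assert total["count_high"].iloc[0] == 2
        assert total["lfc"].iloc[0] == pytest.approx(np.log2(3), abs=1e-9)

    def test_equal_counts_zero_lfc(self):
        mags, taxonomy, metadata, ko, pmap = small_attribution_setup()
        ab = pd.DataFrame(1.0, index=mags, columns=metadata["sample_id"])
        ctx = DAContext(da_mags={"da1"})
        out = attribution.taxon_contribution(ctx, ko, ab, taxonomy, metadata, pmap)
        total = out[(out["taxon_group"] == TOTAL_GROUP) & (out["contrast"] == "40vs80")]
        assert total["lfc"].iloc[0] == 0.0

    def test_groups_conserve_total_counts(self):
        mags, taxonomy, metadata, ko, pmap = small_attribution_setup()
        ab = pd.DataFrame(
            np.arange(12, dtype=float).reshape(3, 4) + 1.0, index=mags,
            columns=metadata["sample_id"],
        )
        ctx = DAContext(da_mags={"da1", "da2"})
        out = attribution.taxon_contribution(ctx, ko, ab, taxonomy, metadata, pmap)
        for contrast in ("40vs80",):
            sub = out[out["contrast"] == contrast]
            total = sub[sub["taxon_group"] == TOTAL_GROUP]
            parts = sub[sub["taxon_group"] != TOTAL_GROUP]
            assert parts["count_low"].sum() == pytest.approx(total["count_low"].iloc[0])
            assert parts["count_high"].sum() == pytest.approx(total["count_high"].iloc[0])

    def test_empty_da_set_rejected(self):
        mags, taxonomy, metadata, ko, pmap = small_attribution_setup()
        ab = pd.DataFrame(1.0, index=mags, columns=metadata["sample_id"])
        with pytest.raises(ValueError, match="empty"):
            attribution.taxon_contribution(
                DAContext(da_mags=set()), ko, ab, taxonomy, metadata, pmap
            )


class TestScenarios:
    def _classify(self, overall_lfc, attributable, n_sig):
        overall = pd.DataFrame(
            [{"pathway": "p", "contrast": "40vs80",
              "n_significant_kos": n_sig, "overall_lfc": overall_lfc}]
        )
        contrib = pd.DataFrame(
            [{"taxon_group": TOTAL_GROUP, "pathway": "p", "contrast": "40vs80",
              "count_low": 1.0, "count_high": 1.0, "lfc": attributable}]
        )
        return attribution.classify_scenarios(overall, contrib)["scenario"].iloc[0]

    def test_matching_substantial_shifts_agree(self):
        assert self._classify(0.72, 1.67, 5) == "agreement"

    def test_small_overall_large_attributable_disconnect(self):
        assert self._classify(-0.13, 1.34, 3) == "disconnect"

    def test_opposite_signs_disconnect(self):
        assert self._classify(-1.2, 1.1, 3) == "disconnect"

    def test_no_significant_ko_attribution_only(self):
        assert self._classify(np.nan, 1.07, 0) == "attribution-only"

    def test_nothing_substantial_is_none(self):
        assert self._classify(0.1, 0.2, 2) == "none"
        assert self._classify(np.nan, 0.3, 0) == "none"


class TestPhylumCorrelation:
    def test_published_catalogues_highly_correlated(self):
        counts = reference.PHYLUM_GENOME_COUNTS
        r, rho = attribution.phylum_proportion_correlation(
            counts["winning_mags"], counts["scottish_rugs"]
        )
        assert round(r, 2) == 0.99
        assert round(rho, 2) == pytest.approx(0.79, abs=0.011)

    def test_identical_vectors(self):
        v = pd.Series([3, 2, 1], index=list("abc"))
        r, rho = attribution.phylum_proportion_correlation(v, v)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_three_point_hand_example(self):
        a = pd.Series([1, 2, 3], index=list("abc"))
        b = pd.Series([2, 4, 5], index=list("abc"))
        r, _ = attribution.phylum_proportion_correlation(a, b)
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_too_few_phyla_rejected(self):
        a = pd.Series([1, 2], index=list("ab"))
        with pytest.raises(ValueError, match="3 phyla"):
            attribution.phylum_proportion_correlation(a, a)
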