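"""Bias correction, MAG aggregation, Hellinger transform, batch removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from magcentric import abundance, simulate


def toy_contigs(n, length=1000):
    return pd.DataFrame(
        {"mag_id": [f"m{i % 5}" for i in range(n)],
         "length": length,
         "gc": np.linspace(0.3, 0.7, n)},
        index=[f"c{i}" for i in range(n)],
    )


class TestCorrectBias:
    def test_identical_strata_is_a_no_op(self):
        contigs = toy_contigs(100)
        vals = np.tile(np.arange(1.0, 11.0), 10)  # identical multiset per decile
        counts = pd.DataFrame({"s1": vals, "s2": vals[::-1]}, index=contigs.index)
        out = abundance.correct_bias(counts, contigs)
        assert np.max(np.abs(out.to_numpy() / counts.to_numpy() - 1.0)) < 1e-6

    def test_removes_planted_monotone_gc_bias(self, filtered_metadata):
        effects = simulate.EffectSpec(
            gc_bias=lambda gc: np.exp(2.0 * (gc - 0.5)), contigs_per_mag=10,
            dispersion=0.1,
        )
        mags = [f"m{i}" for i in range(200)]
        counts, cmap, _ = simulate.simulate_counts(filtered_metadata, mags, effects, seed=3)
        rates = counts.div(cmap["length"] / 1000.0, axis=0)
        rho_before = np.mean(
            [stats.spearmanr(rates[c], cmap["gc"]).statistic for c in counts.columns]
        )
        corrected = abundance.correct_bias(counts, cmap)
        rho_after = [
            stats.spearmanr(corrected[c], cmap["gc"]).statistic for c in counts.columns
        ]
        assert rho_before > 0.5
        assert np.max(np.abs(rho_after)) < 0.05

    def test_length_scaling_leaves_coverage_density_invariant(self):
        """Doubling a contig's length at fixed per-kb density must not
        change its corrected (density-scale) value."""
        contigs = toy_contigs(100)
        counts = pd.DataFrame(
            {"s1": np.tile(np.arange(1.0, 11.0), 10) * contigs["length"] / 1000.0},
            index=contigs.index,
        )
        doubled = contigs.copy()
        doubled.loc["c7", "length"] *= 2
        counts2 = counts.copy()
        counts2.loc["c7", "s1"] *= 2  # same density on twice the length
        out1 = abundance.correct_bias(counts, contigs)
        out2 = abundance.correct_bias(counts2, doubled)
        # totals differ, so compare on the density scale up to the rescale
        r1 = out1["s1"] / out1["s1"].sum()
        r2 = out2["s1"] / out2["s1"].sum()
        assert r1.loc["c7"] == pytest.approx(r2.loc["c7"], rel=1e-6)

    def test_unknown_contig_rejected(self):
        contigs = toy_contigs(4)
        counts = pd.DataFrame({"s": [1.0]}, index=["nope"])
        with pytest.raises(ValueError, match="absent"):
            abundance.correct_bias(counts, contigs)


class TestAggregate:
    def test_mag_count_is_contig_sum(self):
        contigs = pd.DataFrame(
            {"mag_id": ["m1", "m1"], "length": 1000, "gc": 0.5},
            index=["c1", "c2"],
        )
        counts = pd.DataFrame({"s": [3.0, 4.0]}, index=["c1", "c2"])
        out = abundance.aggregate_to_mag(counts, contigs)
        assert out.values.loc["m1", "s"] == 7.0

    def test_column_sums_preserved(self, filtered_metadata):
        effects = simulate.EffectSpec(contigs_per_mag=3)
        counts, cmap, _ = simulate.simulate_counts(
            filtered_metadata, [f"m{i}" for i in range(20)], effects, seed=1
        )
        out = abundance.aggregate_to_mag(counts, cmap)
        np.testing.assert_allclose(out.values.sum(axis=0), counts.sum(axis=0))

    def test_every_mag_present_in_every_sample(self, filtered_metadata):
        """With positive baselines every genome keeps supporting reads in
        every animal and diet."""
        effects = simulate.EffectSpec(contigs_per_mag=3, dispersion=0.2)
        counts, cmap, _ = simulate.simulate_counts(
            filtered_metadata, [f"m{i}" for i in range(100)], effects, seed=2
        )
        out = abundance.aggregate_to_mag(counts, cmap)
        assert (out.values.to_numpy() >= 1).all()


class TestHellinger:
    def test_worked_example(self):
        out = abundance.hellinger(pd.DataFrame({"s": [1.0, 3.0]}, index=["a", "b"]))
        np.testing.assert_allclose(out.values["s"], [0.5, 0.8660254], atol=1e-7)

    def test_unit_sum_of_squares(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 50, size=(30, 5)) + 0.1)
        out = abundance.hellinger(mat)
        np.testing.assert_allclose((out.values ** 2).sum(axis=0), 1.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=1e4))
    def test_scale_invariance(self, factor):
        mat = pd.DataFrame({"s": [1.0, 2.0, 5.0]})
        a = abundance.hellinger(mat).values
        b = abundance.hellinger(mat * factor).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            abundance.hellinger(pd.DataFrame({"s": [0.0, 0.0]}))

    def test_flags_are_monotone(self):
        mat = abundance.AbundanceMatrix(
            values=pd.DataFrame({"s": [1.0, 1.0]}), bias_corrected=True
        )
        out = abundance.hellinger(mat)
        assert out.bias_corrected and out.transformed


class TestRemoveBatch:
    def _matrix(self, filtered_metadata, animal_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        md = filtered_metadata.set_index("sample_id")
        base = rng.normal(0.0, 1.0, size=(40, len(md)))
        offsets = {a: rng.normal(0.0, animal_sd) for a in md["animal"].unique()}
        shifted = base + np.array([offsets[a] for a in md["animal"]])[None, :]
        return pd.DataFrame(shifted, columns=md.index)

    def test_no_batch_effects_identity(self, filtered_metadata):
        mat = self._matrix(filtered_metadata, animal_sd=0.0, seed=1)
        out = abundance.remove_batch(mat, filtered_metadata)
        # the fit removes the (noise-level) batch component only; refit is 0
        refit = abundance.remove_batch(out.values, filtered_metadata)
        np.testing.assert_allclose(refit.values.to_numpy(), out.values.to_numpy(),
                                   atol=1e-10)

    def test_planted_animal_offsets_removed(self, filtered_metadata):
        mat = self._matrix(filtered_metadata, animal_sd=5.0, seed=2)
        out = abundance.remove_batch(mat, filtered_metadata)
        md = filtered_metadata.set_index("sample_id")
        before = mat.T.groupby(md["animal"]).mean().var().mean()
        after = out.values.T.groupby(md["animal"]).mean().var().mean()
        assert after < 0.05 * before
        # the defining property: refitting batch coefficients yields ~0
        refit = abundance.remove_batch(out.values, filtered_metadata)
        np.testing.assert_allclose(
            refit.values.to_numpy(), out.values.to_numpy(), atol=1e-8
        )

    def test_aliased_batch_rejected(self):
        md = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "animal": ["1", "1", "2", "2"],
                "period": [2, 3, 2, 3],
                "diet": [40, 40, 80, 80],  # diet aliased with animal
            }
        )
        mat = pd.DataFrame(np.eye(4), columns=md["sample_id"])
        with pytest.raises(ValueError, match="aliased"):
            abundance.remove_batch(mat, md, batch_vars=("animal",), keep_vars=("diet",))


class TestPhylumSummary:
    def test_single_phylum_is_100_everywhere(self, filtered_metadata):
        mat = pd.DataFrame(
            np.ones((3, 14)), index=["g1", "g2", "g3"],
            columns=filtered_metadata["sample_id"],
        )
        taxonomy = pd.DataFrame(
            {"genome_id": ["g1", "g2", "g3"], "phylum": ["Bacteroidetes"] * 3}
        )
        out = abundance.phylum_relative_abundance(mat, taxonomy, filtered_metadata)
        np.testing.assert_allclose(out.to_numpy(), 100.0)

    def test_diet_columns_sum_to_100(self, filtered_metadata, rng):
        mags = [f"g{i}" for i in range(20)]
        mat = pd.DataFrame(
            rng.uniform(1, 100, size=(20, 14)), index=mags,
            columns=filtered_metadata["sample_id"],
        )
        taxonomy = pd.DataFrame(
            {"genome_id": mags, "phylum": [f"P{i % 4}" for i in range(20)]}
        )
        out = abundance.phylum_relative_abundance(mat, taxonomy, filtered_metadata)
        np.testing.assert_allclose(out.sum(axis=0), 100.0, atol=1e-9)

    def test_planted_mixture_recovered(self, filtered_metadata):
        mags = ["a", "b"]
        # fixed 3:1 mixture in every sample
        mat = pd.DataFrame(
            np.array([[75.0] * 14, [25.0] * 14]), index=mags,
            columns=filtered_metadata["sample_id"],
        )
        taxonomy = pd.DataFrame({"genome_id": mags, "phylum": ["X", "Y"]})
        out = abundance.phylum_relative_abundance(mat, taxonomy, filtered_metadata)
        np.testing.assert_allclose(out.loc["X"], 75.0)

    def test_missing_taxonomy_rejected(self, filtered_metadata):
        mat = pd.DataFrame(np.ones((1, 14)), index=["g"],
                           columns=filtered_metadata["sample_id"])
        with pytest.raises(ValueError, match="missing taxonomy"):
            abundance.phylum_relative_abundance(
                mat, pd.DataFrame({"genome_id": ["other"], "phylum": ["P"]}),
                filtered_metadata,
            )
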