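import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from msnpls.expression import (
    aggregate_expression,
    assign_samples_to_regions,
    differential_stability,
    differential_stability_table,
    filter_probes_intensity,
    prepare_expression_matrix,
    robust_sigmoid_normalize,
    select_probe_per_gene,
)
from msnpls.simulate import SimulationParams, simulate_donor_samples, simulate_expression_matrix


def make_samples(flags_by_probe):
    """A minimal long sample table with one donor and one sample per flag."""
    rows = []
    for probe, flags in flags_by_probe.items():
        for i, flag in enumerate(flags):
            rows.append(
                {
                    "donor_id": "d1",
                    "sample_id": f"s{i}",
                    "x": 0.0,
                    "y": 0.0,
                    "z": 0.0,
                    "probe_id": probe,
                    "intensity": 1.0,
                    "above_background": flag,
                }
            )
    return pd.DataFrame(rows)


class TestIntensityFilter:
    def test_always_above_retained_never_above_dropped(self):
        samples = make_samples({"pA": [True] * 4, "pB": [False] * 4})
        kept = filter_probes_intensity(samples)
        assert list(kept) == ["pA"]

    def test_boundary_fraction_is_inclusive(self):
        samples = make_samples({"pA": [True, True, False, False]})
        assert list(filter_probes_intensity(samples, min_fraction=0.5)) == ["pA"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_probes_intensity(make_samples({}).reindex(columns=[
                "donor_id", "sample_id", "x", "y", "z", "probe_id", "intensity", "above_background"
            ]))


class TestDifferentialStability:
    def test_identical_profiles(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]])
        assert differential_stability(prof) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert differential_stability(prof) == pytest.approx(-1.0)

    def test_matches_pairwise_spearman_oracle(self, rng):
        prof = pd.DataFrame(rng.standard_normal((3, 12)))
        pairs = [(0, 1), (0, 2), (1, 2)]
        oracle = np.mean(
            [spearmanr(prof.iloc[a], prof.iloc[b]).statistic for a, b in pairs]
        )
        assert differential_stability(prof) == pytest.approx(oracle, abs=1e-12)

    def test_constant_profile_pair_skipped(self):
        prof = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [4.0, 2.0, 3.0, 1.0]]
        )
        # the constant donor contributes no pairs; the remaining pair decides
        expected = spearmanr([1, 2, 3, 4], [4, 2, 3, 1]).statistic
        assert differential_stability(prof) == pytest.approx(expected, abs=1e-12)

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            differential_stability(pd.DataFrame([[1.0, 2.0, 3.0]]))

    def test_all_pairs_skipped_is_an_error(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        with pytest.raises(ValueError, match="all donor pairs"):
            differential_stability(prof)


class TestProbeSelection:
    def test_max_ds_wins_and_ties_break_lexicographically(self):
        ds = pd.Series({"p1": 0.9, "p2": 0.2, "p3": 0.7, "p4": 0.7, "p5": 0.5})
        probe_map = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4", "p5"],
                "gene_id": ["gA", "gA", "gB", "gB", "gC"],
            }
        )
        chosen = select_probe_per_gene(ds, probe_map)
        assert chosen["gA"] == "p1"
        assert chosen["gB"] == "p3"  # tie at 0.7 -> smaller probe id
        assert chosen["gC"] == "p5"

    def test_gene_without_scored_probe_dropped(self):
        ds = pd.Series({"p1": 0.9})
        probe_map = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["gA", "gB"]})
        chosen = select_probe_per_gene(ds, probe_map)
        assert list(chosen.index) == ["gA"]


class TestSampleAssignment:
    def _centroids(self):
        return pd.DataFrame(
            {"roi": ["r1", "r2"], "x": [0.0, 20.0], "y": [0.0, 0.0], "z": [0.0, 0.0]}
        )

    def _samples(self, coords_values):
        rows = []
        for i, (coords, value) in enumerate(coords_values):
            rows.append(
                {
                    "donor_id": "d1",
                    "sample_id": f"s{i}",
                    "x": coords[0],
                    "y": coords[1],
                    "z": coords[2],
                    "probe_id": "p1",
                    "intensity": value,
                    "above_background": True,
                }
            )
        return pd.DataFrame(rows)

    def test_sample_at_centroid_assigned(self):
        samples = self._samples([((0.0, 0.0, 0.0), 2.0), ((20.0, 0.0, 0.0), 5.0)])
        assignment, means = assign_samples_to_regions(samples, self._centroids())
        direct = assignment[~assignment["fallback"]]
        assert set(zip(direct["sample_id"], direct["roi"])) == {("s0", "r1"), ("s1", "r2")}

    def test_out_of_radius_sample_becomes_fallback(self):
        # 3 mm from r1, far from r2: both regions are empty after the radius
        # pass and get the nearest sample as fallback.
        samples = self._samples([((3.0, 0.0, 0.0), 7.0)])
        assignment, means = assign_samples_to_regions(samples, self._centroids())
        assert assignment["fallback"].all()
        assert set(assignment["roi"]) == {"r1", "r2"}
        np.testing.assert_allclose(means["intensity"], 7.0)

    def test_region_mean_over_assigned_samples(self):
        samples = self._samples([((0.5, 0.0, 0.0), 2.0), ((0.0, 0.5, 0.0), 4.0)])
        _, means = assign_samples_to_regions(samples, self._centroids())
        r1 = means[(means["roi"] == "r1")]["intensity"].iloc[0]
        assert r1 == pytest.approx(3.0)


class TestRobustSigmoid:
    def test_median_maps_to_half_before_rescale(self, rng):
        x = rng.standard_normal(35)
        x[0] = np.median(x[1:])  # force a value at the median
        s = robust_sigmoid_normalize(x, rescale=False)
        med_pos = np.argwhere(x == np.median(x))
        if med_pos.size:
            assert s[med_pos[0, 0]] == pytest.approx(0.5)

    def test_strictly_monotone_and_unit_range(self, rng):
        x = np.sort(rng.standard_normal(20))
        out = robust_sigmoid_normalize(x)
        assert np.all(np.diff(out) > 0)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(30)
        base = robust_sigmoid_normalize(x)
        np.testing.assert_allclose(
            robust_sigmoid_normalize(3.7 * x + 11.0), base, atol=1e-10
        )

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="IQR"):
            robust_sigmoid_normalize(np.ones(10))


class TestAggregate:
    def test_single_donor_identity(self, rng):
        block = pd.DataFrame(rng.uniform(size=(4, 3)))
        out = aggregate_expression({"d1": block})
        np.testing.assert_allclose(out.to_numpy(), block.to_numpy())

    def test_mean_of_two_donors(self):
        b1 = pd.DataFrame([[0.2]], columns=["g"], index=["r"])
        b2 = pd.DataFrame([[0.6]], columns=["g"], index=["r"])
        out = aggregate_expression({"d1": b1, "d2": b2})
        assert out.iloc[0, 0] == pytest.approx(0.4)

    def test_matches_loop_oracle_with_missing_donors(self, rng):
        blocks = {f"d{i}": pd.DataFrame(rng.uniform(size=(5, 4))) for i in range(3)}
        blocks["d0"].iloc[:, 1] = np.nan  # gene dropped for one donor
        out = aggregate_expression(blocks)
        for i in range(5):
            for j in range(4):
                vals = [
                    blocks[d].iloc[i, j]
                    for d in blocks
                    if np.isfinite(blocks[d].iloc[i, j])
                ]
                assert out.iloc[i, j] == pytest.approx(np.mean(vals), abs=1e-15)

    def test_uncovered_cell_is_an_error(self, rng):
        blocks = {"d1": pd.DataFrame(rng.uniform(size=(3, 2)))}
        blocks["d1"].iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="no donor coverage"):
            aggregate_expression(blocks)


class TestEndToEnd:
    def test_recovers_planted_regional_gradient(self, rng):
        """The donor pipeline reproduces a planted ground-truth matrix with
        high per-gene rank correlation at the generator's default noise."""
        params = SimulationParams(seed=5, n_genes=40, n_signal=10)
        pattern = rng.standard_normal(34)
        truth, _ = simulate_expression_matrix(params, pattern, rng=rng)
        samples, probes, centroids = simulate_donor_samples(params, truth, rng=rng)
        recovered = prepare_expression_matrix(samples, probes, centroids)
        assert recovered.shape[0] == 34
        assert ((recovered.values >= 0) & (recovered.values <= 1)).all()
        assert np.isfinite(recovered.values).all()
        cors = [
            spearmanr(truth[g], recovered[g]).statistic for g in recovered.columns
        ]
        assert np.mean(cors) >= 0.8

    def test_ds_table_scores_good_probe_higher(self, rng):
        params = SimulationParams(seed=6, n_genes=10, n_signal=2)
        pattern = rng.standard_normal(34)
        truth, _ = simulate_expression_matrix(params, pattern, rng=rng)
        samples, probes, centroids = simulate_donor_samples(params, truth, rng=rng)
        _, region_means = assign_samples_to_regions(samples, centroids)
        ds = differential_stability_table(region_means)
        good = ds[[p for p in ds.index if p.endswith("_p0")]]
        bad = ds[[p for p in ds.index if p.endswith("_p1")]]
        assert good.mean() > bad.mean()
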