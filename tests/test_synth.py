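"""Generator correctness: planted structure must be recoverable by independent
estimators, and every generator must be deterministic under a fixed seed."""

import numpy as np
import pytest
from scipy import stats

from connmvpa.containers import CANONICAL_NETWORKS
from connmvpa.synth import (
    ScrSimConfig,
    SimConfig,
    default_edge_effects,
    make_behavioral_table,
    make_node_timeseries,
    make_scr_trace,
    make_spatial_maps,
    make_voxel_data,
    plant_from_z,
    planted_covariance,
)


def residual_partial_corr(x, i, j):
    """Oracle: regress all other columns out of i and j, correlate residuals."""
    others = np.delete(np.arange(x.shape[1]), [i, j])
    A = np.column_stack([np.ones(len(x)), x[:, others]])
    proj = A @ np.linalg.lstsq(A, x[:, [i, j]], rcond=None)[0]
    ri, rj = (x[:, [i, j]] - proj).T
    return np.corrcoef(ri, rj)[0, 1]


class TestSpatialMaps:
    def test_disjoint_supports_have_zero_correlation(self):
        cfg = SimConfig(overlap=0.0, seed=5)
        maps, _ = make_spatial_maps(cfg)
        assert maps.maps.shape == (25, 2000)
        corr = np.corrcoef(maps.maps)
        off = corr[~np.eye(25, dtype=bool)]
        assert np.abs(off).max() < 1e-12
        norms = np.linalg.norm(maps.maps, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_determinism(self):
        cfg = SimConfig(seed=7)
        a, _ = make_spatial_maps(cfg)
        b, _ = make_spatial_maps(cfg)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_overlap_raises_mean_pairwise_correlation(self):
        cfg = SimConfig(overlap=0.2, seed=5)
        maps, _ = make_spatial_maps(cfg)
        # brute-force Pearson over voxels
        corr = np.corrcoef(maps.maps)
        n = maps.n_components
        adjacent = np.array([corr[i, i + 1] for i in range(n - 1)])
        # adjacent components share ~20% of their support with identical values
        assert 0.05 < adjacent.mean() < 0.45
        nonadjacent = corr[np.triu_indices(n, k=2)]
        assert np.abs(nonadjacent).max() < np.abs(adjacent).mean()

    def test_ground_truth_records_network_vs_artifact(self):
        maps, gt = make_spatial_maps(SimConfig(seed=1))
        assert gt.true_maps.kept_flags.sum() == 17
        assert (~gt.true_maps.kept_flags).sum() == 8

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="n_voxels"):
            make_spatial_maps(SimConfig(n_voxels=80, seed=0))


class TestNodeTimeseries:
    def test_planted_partial_correlation_recovered(self):
        cfg = SimConfig(
            n_nodes_kept=6, n_nodes_artifact=2, n_timepoints=10000,
            n_voxels=200, edge_effects=[(0, 1, 0.5, 0.5)], seed=42,
        )
        ts, gt = make_node_timeseries(cfg, "view")
        kept = ts.kept().data
        est = residual_partial_corr(kept, 0, 1)
        assert abs(est - 0.5) < 0.03

    def test_null_edges_near_zero(self):
        cfg = SimConfig(
            n_nodes_kept=6, n_nodes_artifact=2, n_timepoints=10000,
            n_voxels=200, edge_effects=[], seed=9,
        )
        ts, _ = make_node_timeseries(cfg, "view")
        kept = ts.kept().data
        vals = [
            residual_partial_corr(kept, i, j)
            for i in range(6) for j in range(i + 1, 6)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_reference_edge_magnitudes_plant_successfully(self):
        # the fifteen reported edges at T = 284 imply a PD precision matrix
        cfg = SimConfig(seed=3)
        ts, gt = make_node_timeseries(cfg, "reappraise")
        assert ts.data.shape == (284, 25)
        assert gt.shrink_factor == 1.0
        assert np.allclose(gt.true_partial_corr, gt.true_partial_corr.T)
        eff = default_edge_effects(284)
        i, j, _, rr = eff[1]  # second reference edge, reappraise condition
        assert gt.true_partial_corr[i, j] == pytest.approx(rr)

    def test_zstat_to_partial_r_conversion(self):
        # z of 4.1 at T=284 must map inside (-1,1), raw atanh would not
        r = plant_from_z(-4.098, 284)
        assert -0.25 < r < -0.23

    def test_covariance_is_positive_definite(self, small_cfg):
        cov, _, _ = planted_covariance(small_cfg, "view")
        np.linalg.cholesky(cov)  # raises if not PD

    def test_infeasible_planting_errors_or_shrinks(self):
        effects = [(0, 1, 0.9, 0.9), (1, 2, 0.9, 0.9), (0, 2, 0.9, 0.9)]
        bad = SimConfig(
            n_nodes_kept=3, n_nodes_artifact=1, n_timepoints=50,
            n_voxels=100, edge_effects=effects, seed=0,
        )
        with pytest.raises(ValueError, match="positive definite"):
            make_node_timeseries(bad, "view")
        shrunk = SimConfig(
            n_nodes_kept=3, n_nodes_artifact=1, n_timepoints=50,
            n_voxels=100, edge_effects=effects, seed=0, on_not_pd="shrink",
        )
        with pytest.warns(UserWarning, match="shrunk"):
            _, gt = make_node_timeseries(shrunk, "view")
        assert gt.shrink_factor < 1.0

    def test_determinism_and_condition_dependence(self, small_cfg):
        a, _ = make_node_timeseries(small_cfg, "view")
        b, _ = make_node_timeseries(small_cfg, "view")
        c, _ = make_node_timeseries(small_cfg, "reappraise")
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestVoxelData:
    def test_noiseless_construction_is_exact(self, small_cfg):
        maps, _ = make_spatial_maps(small_cfg)
        ts, _ = make_node_timeseries(small_cfg, "view")
        data = make_voxel_data(maps, ts, noise_sd=0.0)
        np.testing.assert_allclose(data, maps.maps.T @ ts.data.T, atol=1e-12)

    def test_zero_timeseries_gives_zero_data(self, small_cfg):
        maps, _ = make_spatial_maps(small_cfg)
        ts, _ = make_node_timeseries(small_cfg, "view")
        ts.data[:] = 0.0
        assert np.all(make_voxel_data(maps, ts, 0.0) == 0)

    def test_dimension_mismatch_names_shapes(self, small_cfg):
        maps, _ = make_spatial_maps(small_cfg)
        other = SimConfig(
            n_nodes_kept=3, n_nodes_artifact=1, n_timepoints=60,
            n_voxels=100, edge_effects=[], seed=0,
        )
        ts, _ = make_node_timeseries(other, "view")
        with pytest.raises(ValueError, match="components"):
            make_voxel_data(maps, ts, 0.0)

    def test_noisy_recovery_against_least_squares_oracle(self):
        cfg = SimConfig(seed=8)  # default scale: 25 components, 2000 voxels
        maps, _ = make_spatial_maps(cfg)
        ts, _ = make_node_timeseries(cfg, "view")
        noise_sd = 0.5
        data = make_voxel_data(maps, ts, noise_sd=noise_sd, seed=4)
        M = maps.maps
        # normal-equations oracle
        recovered = (np.linalg.solve(M @ M.T, M @ data)).T
        for c in range(ts.n_nodes):
            r = np.corrcoef(recovered[:, c], ts.data[:, c])[0, 1]
            # unit-norm orthogonal maps: recovered = truth + N(0, noise_sd),
            # so corr is predicted in closed form from the node variance
            var_c = ts.data[:, c].var(ddof=1)
            predicted = np.sqrt(var_c / (var_c + noise_sd**2))
            assert abs(r - predicted) < 0.06
            assert r > 0.8


class TestScrTrace:
    def test_zero_amplitude_zero_noise_is_pure_drift(self):
        cfg = ScrSimConfig(
            trial_onsets=[10.0, 20.0], amplitudes=[0.0, 0.0],
            drift_amplitude=0.0, rf_noise_sd=0.0, seed=0,
        )
        trace, amps = make_scr_trace(cfg)
        assert np.all(trace == 0)
        assert np.all(amps == 0)

    def test_bump_peak_matches_requested_amplitude(self):
        cfg = ScrSimConfig(trial_onsets=[10.0], amplitudes=[0.5], seed=0)
        trace, _ = make_scr_trace(cfg)
        assert trace.max() == pytest.approx(0.5, rel=1e-3)
        assert trace[: 10 * cfg.fs_hz].max() == 0  # nothing before onset

    def test_determinism(self):
        cfg = ScrSimConfig(
            trial_onsets=[10.0], amplitudes=[0.3], rf_noise_sd=0.05, seed=12
        )
        a, _ = make_scr_trace(cfg)
        b, _ = make_scr_trace(cfg)
        np.testing.assert_array_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="inter-onset"):
            ScrSimConfig(trial_onsets=[10.0, 15.0], amplitudes=[0.1, 0.1])
        with pytest.raises(ValueError, match="post-onset"):
            ScrSimConfig(trial_onsets=[10.0], amplitudes=[0.1], duration_s=12.0)
        with pytest.raises(ValueError, match="non-negative"):
            ScrSimConfig(trial_onsets=[10.0], amplitudes=[-0.1])


class TestBehavioralTable:
    def test_shape_and_completeness(self):
        table, info = make_behavioral_table(31, seed=0)
        assert len(table) == 62  # 31 subjects x 2 conditions
        assert table["subject"].nunique() == 31
        assert not table.isna().any().any()
        assert table["neg_rating"].between(1, 7).all()
        assert table["hit_rate"].between(0, 100).all()

    def test_null_effect_p_values_uniform(self):
        # zero planted difference: paired t-test p over replicates of the
        # generated tables should be uniform (scipy.ttest_rel as the oracle)
        table_p = []
        for r in range(400):
            table, _ = make_behavioral_table(
                12, planted_mean_diffs={"neg_rating": 0.0}, seed=1000 + r
            )
            piv = table.pivot(index="subject", columns="condition", values="neg_rating")
            _, p = stats.ttest_rel(piv["view"], piv["reappraise"])
            table_p.append(p)
        assert stats.kstest(table_p, "uniform").pvalue > 0.01

    def test_power_matches_noncentral_t(self):
        # planted d = 0.30 at n = 31: empirical power of the paired t-test
        # vs the closed-form noncentral-t power
        n, d, alpha, reps = 31, 0.30, 0.05, 5000
        rng = np.random.default_rng(5)
        diffs = d + rng.standard_normal((reps, n))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), n - 1)
        empirical = np.mean(p < alpha)
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        nc = d * np.sqrt(n)
        analytic = stats.nct.sf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        assert abs(empirical - analytic) < 0.03

    def test_clipping_reported(self):
        _, info = make_behavioral_table(20, seed=2)
        assert set(info["clip_rate"]) == {"neg_rating", "pos_rating", "hit_rate", "source_acc"}
        assert all(0 <= v <= 1 for v in info["clip_rate"].values())
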