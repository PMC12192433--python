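"""Netmats estimation: normalization, aggressive cleanup, unregularized
partial correlation (vs. residual-regression oracle), Fisher transform,
edge flattening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmvpa.containers import NodeTimeseries
from connmvpa.netmats import (
    NetMat,
    aggressive_cleanup,
    fisher_transform,
    flatten_edges,
    netmat_from_timeseries,
    partial_correlation,
    unflatten_edges,
    variance_normalize,
)
from connmvpa.synth import SimConfig, make_node_timeseries


def residual_partial_corr_matrix(x):
    """Oracle: partial corr of (i, j) via regression on all other columns."""
    n = x.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            others = np.delete(np.arange(n), [i, j])
            A = np.column_stack([np.ones(len(x)), x[:, others]])
            proj = A @ np.linalg.lstsq(A, x[:, [i, j]], rcond=None)[0]
            ri, rj = (x[:, [i, j]] - proj).T
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def make_ts(data, n_artifact=0):
    n = data.shape[1]
    labels = [f"N{i}" for i in range(n - n_artifact)] + [
        f"A{i}" for i in range(n_artifact)
    ]
    flags = np.array([False] * (n - n_artifact) + [True] * n_artifact)
    return NodeTimeseries(data, labels, flags)


class TestVarianceNormalize:
    def test_unit_variance_and_oracle(self, rng):
        x = 2 + 3 * rng.standard_normal((100, 4))
        ts = variance_normalize(make_ts(x))
        np.testing.assert_allclose(ts.data.std(axis=0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(ts.data.mean(axis=0), 0.0, atol=1e-12)
        oracle = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        np.testing.assert_allclose(ts.data, oracle, atol=1e-12)

    def test_idempotent_on_normalized_input(self, rng):
        x = rng.standard_normal((200, 3))
        once = variance_normalize(make_ts(x))
        twice = variance_normalize(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_zero_variance_names_node(self, rng):
        x = rng.standard_normal((50, 3))
        x[:, 1] = 7.0
        with pytest.raises(ValueError, match="N1"):
            variance_normalize(make_ts(x))


class TestAggressiveCleanup:
    def test_orthogonal_artifact_leaves_kept_nodes(self, rng):
        T = 400
        kept = rng.standard_normal((T, 3))
        art = rng.standard_normal((T, 1))
        # orthogonalize artifact against kept nodes and the intercept
        A = np.column_stack([np.ones(T), kept])
        art = art - A @ np.linalg.lstsq(A, art, rcond=None)[0]
        ts = make_ts(np.column_stack([kept, art]), n_artifact=1)
        out = aggressive_cleanup(ts)
        assert out.n_nodes == 3
        # kept nodes demeaned at most (regression includes intercept)
        np.testing.assert_allclose(out.data, kept - kept.mean(axis=0), atol=1e-10)

    def test_kept_equal_to_artifact_becomes_zero(self, rng):
        a = rng.standard_normal(100)
        ts = make_ts(np.column_stack([a, rng.standard_normal(100), a]), n_artifact=1)
        out = aggressive_cleanup(ts)
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_projection_oracle_recovers_signal(self, rng):
        T = 284
        signal = rng.standard_normal(T)
        art = rng.standard_normal((T, 2))
        kept = signal + 0.7 * art[:, 0]
        data = np.column_stack([kept, rng.standard_normal(T), art])
        ts = make_ts(data, n_artifact=2)
        out = aggressive_cleanup(ts)
        # explicit projection oracle I - A (A^T A)^-1 A^T with intercept
        A = np.column_stack([np.ones(T), art])
        P = np.eye(T) - A @ np.linalg.inv(A.T @ A) @ A.T
        np.testing.assert_allclose(out.data[:, 0], P @ kept, atol=1e-8)
        assert np.corrcoef(out.data[:, 0], P @ signal)[0, 1] > 0.999

    def test_idempotence_with_same_artifact_set(self, rng):
        data = rng.standard_normal((200, 6))
        ts = make_ts(data, n_artifact=2)
        once = aggressive_cleanup(ts)
        again = aggressive_cleanup(
            NodeTimeseries(
                np.column_stack([once.data, data[:, 4:]]),
                once.node_labels + ["A0", "A1"],
                np.array([False] * 4 + [True] * 2),
            )
        )
        np.testing.assert_allclose(again.data, once.data, atol=1e-10)

    def test_dependent_artifacts_dropped_with_warning(self, rng):
        art = rng.standard_normal((100, 1))
        data = np.column_stack([rng.standard_normal((100, 2)), art, 2 * art])
        ts = make_ts(data, n_artifact=2)
        with pytest.warns(UserWarning, match="A1"):
            out = aggressive_cleanup(ts)
        assert out.n_nodes == 2


class TestPartialCorrelation:
    def test_two_nodes_equals_pearson(self, rng):
        x = rng.standard_normal((100, 2))
        x[:, 1] += 0.5 * x[:, 0]
        r = partial_correlation(make_ts(x))
        assert r[0, 1] == pytest.approx(np.corrcoef(x.T)[0, 1], abs=1e-10)

    def test_chain_conditional_independence(self, rng):
        # x -> y -> z: marginal corr(x,z) large, partial ~ 0
        T = 20000
        x = rng.standard_normal(T)
        y = 0.8 * x + rng.standard_normal(T)
        z = 0.8 * y + rng.standard_normal(T)
        data = np.column_stack([x, y, z])
        r = partial_correlation(make_ts(data))
        assert abs(np.corrcoef(x, z)[0, 1]) > 0.3
        assert abs(r[0, 2]) < 0.03

    def test_matches_residual_regression_oracle(self, rng):
        for n in (5, 8, 10):
            x = rng.standard_normal((400, n)) @ rng.standard_normal((n, n))
            r = partial_correlation(make_ts(x))
            oracle = residual_partial_corr_matrix(x)
            np.testing.assert_allclose(r, oracle, atol=1e-8)

    def test_identity_covariance_zero_offdiagonal(self):
        # whiten so the sample covariance is exactly the identity
        x = np.random.default_rng(0).standard_normal((50, 4))
        x -= x.mean(axis=0)
        L = np.linalg.cholesky(np.cov(x, rowvar=False, ddof=1))
        white = x @ np.linalg.inv(L).T
        r = partial_correlation(make_ts(white))
        assert np.abs(r[~np.eye(4, dtype=bool)]).max() < 1e-8

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError, match="timepoints"):
            partial_correlation(make_ts(rng.standard_normal((5, 5))))

    def test_singular_covariance_is_an_error(self, rng):
        x = rng.standard_normal((50, 3))
        data = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(np.linalg.LinAlgError):
            partial_correlation(make_ts(data))

    def test_planted_recovery_through_full_chain(self):
        cfg = SimConfig(
            n_nodes_kept=6, n_nodes_artifact=2, n_timepoints=10000,
            n_voxels=200, edge_effects=[(0, 1, 0.4, 0.4), (2, 5, -0.25, -0.25)],
            seed=21,
        )
        ts, gt = make_node_timeseries(cfg, "view")
        nm = netmat_from_timeseries(ts, scaling="raw_atanh")
        est = np.tanh(nm.z)
        assert np.abs(est - gt.true_partial_corr).max() < 0.03


class TestFisherTransform:
    def test_closed_form_values(self):
        r = np.array([[0.0, 0.5], [0.5, 0.0]])
        raw = fisher_transform(r, 284, scaling="raw_atanh")
        assert raw.z[0, 1] == pytest.approx(np.log(3) / 2, abs=1e-10)
        zst = fisher_transform(r, 284, scaling="zstat_scaled")
        assert zst.z[0, 1] == pytest.approx(0.5493061 * np.sqrt(281), abs=1e-4)
        assert zst.z[0, 1] == pytest.approx(9.208, abs=1e-3)
        assert raw.z[0, 0] == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        r1=st.floats(-0.99, 0.99),
        r2=st.floats(-0.99, 0.99),
        scaling=st.sampled_from(["raw_atanh", "zstat_scaled"]),
    )
    def test_strictly_monotone(self, r1, r2, scaling):
        lo, hi = min(r1, r2), max(r1, r2)
        if lo == hi:
            return
        m = fisher_transform(
            np.array([[0, lo], [lo, 0.0]]), 100, scaling
        ).z[0, 1]
        M = fisher_transform(
            np.array([[0, hi], [hi, 0.0]]), 100, scaling
        ).z[0, 1]
        assert m < M

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            fisher_transform(np.array([[0.0, 1.0], [1.0, 0.0]]), 100)


class TestEdgeFlattening:
    def test_17_nodes_gives_136_edges(self):
        nm = NetMat(np.zeros((17, 17)), [f"n{i}" for i in range(17)], 284, "raw_atanh")
        assert nm.n_edges == 136
        assert flatten_edges(nm).shape == (136,)

    def test_three_node_order(self):
        a, b, c = 1.0, 2.0, 3.0
        m = np.array([[0, a, b], [a, 0, c], [b, c, 0]])
        np.testing.assert_array_equal(flatten_edges(m), [a, b, c])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_flatten_unflatten_bijection(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal(n * (n - 1) // 2)
        np.testing.assert_array_equal(flatten_edges(unflatten_edges(vals, n)), vals)


class TestSamplingBehavior:
    def test_null_zstat_scale_is_approximately_standard_normal(self):
        # planted r = 0: atanh(r_hat) * sqrt(T-3) ~ N(0,1), so mean |z|
        # should be near sqrt(2/pi)
        rng = np.random.default_rng(123)
        T = 120
        zs = []
        for _ in range(1000):
            x = rng.standard_normal((T, 2))
            r = partial_correlation(make_ts(x))[0, 1]
            zs.append(np.arctanh(r) * np.sqrt(T - 3))
        mean_abs = np.abs(zs).mean()
        assert abs(mean_abs - np.sqrt(2 / np.pi)) < 0.1

    def test_netmat_symmetry_and_finiteness_on_cohort(self, small_cfg):
        ts, _ = make_node_timeseries(small_cfg, "view")
        nm = netmat_from_timeseries(ts)
        assert np.allclose(nm.z, nm.z.T, atol=1e-10)
        assert np.all(np.isfinite(nm.z))
        assert nm.scaling == "zstat_scaled"
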