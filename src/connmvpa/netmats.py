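"""Network-matrix estimation: cleanup, unregularized partial correlation, Fisher z.

The netmats stage turns each subject's stage-1 dual-regression timeseries
into a node x node connectivity matrix:

1. variance-normalize every timeseries (zero mean, unit variance);
2. "aggressive cleanup" — regress the artifact-component timeseries out of
   every retained network's timeseries, then discard the artifact columns;
3. unregularized partial correlation between every pair of retained nodes,
   r_ij = -Theta_ij / sqrt(Theta_ii Theta_jj) with Theta the inverse sample
   covariance;
4. Fisher r-to-z transform, by default scaled by sqrt(T - 3) so entries are
   approximate z-statistics (17 nodes at T = 284 give the working regime).

A 17-node matrix flattens to a 136-edge vector (row-major upper triangle),
the feature vector used by the edge-wise GLM and the connectome MVPA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import NodeTimeseries, edge_index, edge_labels

__all__ = [
    "NetMat",
    "variance_normalize",
    "aggressive_cleanup",
    "partial_correlation",
    "fisher_transform",
    "flatten_edges",
    "unflatten_edges",
    "netmat_from_timeseries",
]


@dataclass
class NetMat:
    """Symmetric node x node matrix of Fisher-transformed partial correlations.

    ``scaling`` records whether entries are raw atanh values ("raw_atanh")
    or scaled by sqrt(T-3) to approximate z-statistics ("zstat_scaled").
    The diagonal is 0 by convention (never NaN) so flattening and I/O are
    total.
    """

    z: np.ndarray
    node_labels: list[str]
    n_timepoints_effective: int
    scaling: str

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("z must be square")
        if len(self.node_labels) != n:
            raise ValueError("one label per node required")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z must be symmetric to 1e-10")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("all entries must be finite")
        if self.scaling not in ("raw_atanh", "zstat_scaled"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def edge_labels(self) -> list[str]:
        return edge_labels(self.node_labels)


def variance_normalize(ts: NodeTimeseries) -> NodeTimeseries:
    """Demean and scale each node's timeseries to unit sample variance."""
    x = ts.data
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [ts.node_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance node timeseries: {bad}")
    out = (x - x.mean(axis=0)) / sd
    return NodeTimeseries(out, list(ts.node_labels), ts.artifact_flags.copy(), ts.tr_seconds)


def aggressive_cleanup(ts: NodeTimeseries) -> NodeTimeseries:
    """Regress all artifact timeseries jointly out of every kept node, then drop them.

    The regression design is the artifact columns plus an intercept; each
    kept column is replaced by its least-squares residual. Linearly
    dependent artifact columns are dropped with a warning naming them.
    """
    keep = ~ts.artifact_flags
    if not np.any(keep):
        raise ValueError("no kept (non-artifact) nodes to clean")
    if not np.any(~keep):
        return ts.kept()
    Y = ts.data[:, keep]
    A = ts.data[:, ~keep]
    art_labels = [l for l, k in zip(ts.node_labels, keep) if not k]
    design = np.column_stack([np.ones(ts.n_timepoints), A])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        kept_cols, names, cols = [], [], [np.ones(ts.n_timepoints)]
        for j in range(A.shape[1]):
            trial = np.column_stack(cols + [A[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(A[:, j])
                kept_cols.append(j)
            else:
                names.append(art_labels[j])
        warnings.warn(f"dropping linearly dependent artifact column(s): {names}")
        design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    labels = [l for l, k in zip(ts.node_labels, keep) if k]
    return NodeTimeseries(resid, labels, np.zeros(len(labels), dtype=bool), ts.tr_seconds)


def partial_correlation(ts: NodeTimeseries | np.ndarray) -> np.ndarray:
    """Unregularized partial correlation between every pair of nodes.

    r_ij = -Theta_ij / sqrt(Theta_ii Theta_jj), Theta = inv(sample cov).
    No regularization is applied: a singular covariance is an error, not
    something to shrink away silently. Diagonal is set to 0.
    """
    x = ts.data if isinstance(ts, NodeTimeseries) else np.asarray(ts, dtype=float)
    T, n = x.shape
    if T <= n + 1:
        raise ValueError(f"need more timepoints ({T}) than nodes + 1 ({n + 1})")
    cov = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            "sample covariance is singular or near-singular; cannot invert "
            "(no silent regularization is applied)"
        )
    theta = np.linalg.inv(cov)
    d = np.sqrt(np.diag(theta))
    r = -theta / np.outer(d, d)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    return r


def fisher_transform(
    r_matrix: np.ndarray,
    n_timepoints: int,
    scaling: str = "zstat_scaled",
    node_labels: list[str] | None = None,
) -> NetMat:
    """Fisher r-to-z transform of a (partial) correlation matrix.

    ``raw_atanh``: z = atanh(r). ``zstat_scaled`` (default): z = atanh(r)
    * sqrt(T - 3), an approximate z-statistic under the null.
    """
    r = np.asarray(r_matrix, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1):
        raise ValueError("|r| >= 1 encountered; Fisher transform undefined")
    z = np.arctanh(np.where(off, r, 0.0))
    if scaling == "zstat_scaled":
        if n_timepoints <= 3:
            raise ValueError("zstat scaling needs n_timepoints > 3")
        z = z * np.sqrt(n_timepoints - 3)
    elif scaling != "raw_atanh":
        raise ValueError(f"unknown scaling {scaling!r}")
    labels = node_labels or [f"node{i}" for i in range(r.shape[0])]
    return NetMat(z, list(labels), n_timepoints, scaling)


def flatten_edges(netmat: NetMat | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle edge vector (length n(n-1)/2)."""
    z = netmat.z if isinstance(netmat, NetMat) else np.asarray(netmat)
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu].copy()


def unflatten_edges(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`flatten_edges`: symmetric matrix with zero diagonal."""
    values = np.asarray(values, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if values.size != expected:
        raise ValueError(f"expected {expected} edges for {n_nodes} nodes, got {values.size}")
    out = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = values
    return out + out.T


def netmat_from_timeseries(
    ts: NodeTimeseries,
    scaling: str = "zstat_scaled",
    normalize_first: bool = True,
) -> NetMat:
    """Full netmats chain: variance-normalize, aggressive cleanup, partial
    correlation, Fisher transform.

    ``normalize_first`` controls whether normalization precedes cleanup
    (default, matching the narrative order) or follows it — a sensitivity
    flag, since upstream tooling does not pin this down.
    """
    if normalize_first:
        ts = variance_normalize(ts)
        clean = aggressive_cleanup(ts)
    else:
        clean = variance_normalize(aggressive_cleanup(ts))
    r = partial_correlation(clean)
    return fisher_transform(r, clean.n_timepoints, scaling, clean.node_labels)


def edge_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Edge (i, j) ordering used by :func:`flatten_edges`."""
    return edge_index(n_nodes)
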