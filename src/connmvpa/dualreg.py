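"""Network selection by spatial cross-correlation, and two-stage dual regression.

Given a set of group-level component maps, :func:`match_networks` identifies
which components correspond to canonical intrinsic networks by spatial
Pearson correlation against reference maps (components matching any
reference at r >= 0.3 are retained; the rest are flagged artifactual).

Dual regression then produces subject-specific versions of the group maps:
stage 1 regresses the group spatial maps against each subject's
voxel-by-time data to obtain one timeseries per component (the pseudoinverse
of the spatial-map matrix applied to the data); stage 2 regresses those
timeseries back into the data to obtain subject-specific spatial maps.
Stage-1 output deliberately includes the artifact components — they are
needed downstream for cleanup before network-matrix estimation.

Both regression stages are plain least squares with no intercept; inputs are
demeaned along the regression dimension first (maps over voxels in stage 1,
timeseries over time in stage 2), mirroring common practice for this step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import NodeTimeseries, SpatialMapSet

__all__ = [
    "match_networks",
    "dual_regression_stage1",
    "dual_regression_stage2",
    "dual_regress",
    "DualRegressionResult",
]

logger = logging.getLogger(__name__)


@dataclass
class DualRegressionResult:
    """Subject-specific timeseries (time x component) and maps (component x voxel)."""

    stage1_timeseries: NodeTimeseries
    stage2_maps: np.ndarray


def _check_variance(maps: np.ndarray, ids) -> None:
    sd = maps.std(axis=1)
    if np.any(sd == 0):
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance spatial map(s): {bad}")


def match_networks(
    candidates: SpatialMapSet,
    references: SpatialMapSet,
    r_threshold: float = 0.3,
    absolute: bool = False,
) -> SpatialMapSet:
    """Label candidate components by their best-matching reference network.

    For each candidate, the spatial Pearson correlation against every
    reference map is computed over all voxels; ``match_r`` is the maximum
    (of signed r by default — sign-flipped components fail to match; pass
    ``absolute=True`` to match on |r| since ICA sign is arbitrary). A
    candidate is kept iff ``match_r >= r_threshold`` and is assigned the
    argmax reference's label, ties broken by lowest reference index.
    """
    if candidates.n_voxels != references.n_voxels:
        raise ValueError(
            f"candidates ({candidates.n_voxels} voxels) and references "
            f"({references.n_voxels} voxels) do not share a grid"
        )
    _check_variance(candidates.maps, candidates.component_ids)
    _check_variance(references.maps, references.component_ids)

    def std(m):
        c = m - m.mean(axis=1, keepdims=True)
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    corr = std(candidates.maps) @ std(references.maps).T  # cand x ref
    score = np.abs(corr) if absolute else corr
    best = np.argmax(score, axis=1)  # argmax returns lowest index on ties
    match_r = score[np.arange(len(best)), best]
    kept = match_r >= r_threshold
    labels = [references.component_ids[b] if k else None for b, k in zip(best, kept)]
    n_tied = int(np.sum(np.sum(score == match_r[:, None], axis=1) > 1))
    if n_tied:
        logger.info("match_networks: %d candidate(s) had tied best references", n_tied)
    return SpatialMapSet(
        candidates.maps.copy(),
        list(candidates.component_ids),
        kept_flags=kept,
        match_r=match_r,
        match_label=labels,
        grid_shape=candidates.grid_shape,
    )


def _dependent_components(M: np.ndarray, ids) -> list:
    """Names of columns that are linear combinations of earlier ones."""
    bad, cols = [], []
    for k in range(M.shape[1]):
        trial = cols + [M[:, k]]
        if np.linalg.matrix_rank(np.column_stack(trial)) < len(trial):
            bad.append(ids[k])
        else:
            cols.append(M[:, k])
    return bad


def dual_regression_stage1(
    group_maps: SpatialMapSet, subject_data: np.ndarray, demean: bool = True
) -> NodeTimeseries:
    """Spatial regression: subject timeseries = pinv(maps^T) . data.

    ``subject_data`` is voxel x time. Returns a time x component matrix with
    one column per group component (kept and artifact alike).
    """
    M = group_maps.maps  # C x V
    data = np.asarray(subject_data, dtype=float)
    if data.ndim != 2 or data.shape[0] != group_maps.n_voxels:
        raise ValueError(
            f"subject data shape {data.shape} does not match {group_maps.n_voxels} voxels"
        )
    if np.linalg.matrix_rank(M) < M.shape[0]:
        bad = _dependent_components(M.T, group_maps.component_ids)
        raise ValueError(f"rank-deficient spatial map matrix; dependent: {bad}")
    if demean:
        logger.debug("stage 1: demeaning maps over voxels and data per timepoint")
        M = M - M.mean(axis=1, keepdims=True)
        data = data - data.mean(axis=0, keepdims=True)
    ts = (np.linalg.pinv(M.T) @ data).T  # T x C
    flags = ~group_maps.kept_flags
    return NodeTimeseries(ts, list(group_maps.component_ids), flags)


def dual_regression_stage2(
    stage1_ts: NodeTimeseries | np.ndarray,
    subject_data: np.ndarray,
    demean: bool = True,
) -> np.ndarray:
    """Temporal regression: subject maps = pinv(ts) . data^T.

    Returns a component x voxel matrix of subject-specific spatial maps.
    """
    ts = stage1_ts.data if isinstance(stage1_ts, NodeTimeseries) else np.asarray(stage1_ts, float)
    ids = (
        stage1_ts.node_labels
        if isinstance(stage1_ts, NodeTimeseries)
        else [str(i) for i in range(ts.shape[1])]
    )
    data = np.asarray(subject_data, dtype=float)
    if data.ndim != 2 or data.shape[1] != ts.shape[0]:
        raise ValueError(
            f"subject data shape {data.shape} does not match {ts.shape[0]} timepoints"
        )
    if np.linalg.matrix_rank(ts) < ts.shape[1]:
        bad = _dependent_components(ts, ids)
        raise ValueError(f"rank-deficient timeseries matrix; dependent: {bad}")
    if demean:
        ts = ts - ts.mean(axis=0, keepdims=True)
        data = data - data.mean(axis=1, keepdims=True)
    return np.linalg.pinv(ts) @ data.T  # C x V


def dual_regress(
    group_maps: SpatialMapSet, subject_data: np.ndarray, demean: bool = True
) -> DualRegressionResult:
    """Run both stages for one subject."""
    ts = dual_regression_stage1(group_maps, subject_data, demean=demean)
    maps = dual_regression_stage2(ts, subject_data, demean=demean)
    return DualRegressionResult(stage1_timeseries=ts, stage2_maps=maps)
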