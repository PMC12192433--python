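"""Synthetic-data generators for the connectivity pipeline.

Everything the pipeline consumes can be generated here from explicit
parameters and a single root seed: group spatial maps, node timeseries with
planted condition-dependent partial correlations, voxel-by-time data via the
forward model, electrodermal traces with response bumps of known amplitude,
and behavioral rating/memory tables with planted paired effects.

The default configuration emulates the study conditions the pipeline is
built for: 31 subjects, two conditions (passive viewing vs. reappraisal of
negative scenes), one 284-timepoint run per condition at TR = 1 s, 25 group
components of which 17 are canonical networks and 8 are artifacts, and
condition-dependent inter-network coupling at the magnitudes of the
consistently meaningful edges (converted from z-statistics to partial
correlations; see ``plant_from_z``).

Node timeseries are i.i.d. multivariate Gaussian draws whose precision
matrix encodes the planted partial correlations; no hemodynamic or temporal
autocorrelation structure is simulated (covariance-level claims only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import CANONICAL_NETWORKS, NodeTimeseries, SpatialMapSet

__all__ = [
    "SimConfig",
    "ScrSimConfig",
    "GroundTruth",
    "TABLE_EDGE_EFFECTS",
    "default_edge_effects",
    "plant_from_z",
    "make_spatial_maps",
    "make_node_timeseries",
    "make_voxel_data",
    "make_scr_trace",
    "make_behavioral_table",
]

#: Condition-dependent inter-network coupling targets, as
#: (node_a, node_b, mean_z_view, mean_z_reappraise) with z on the
#: sqrt(T-3)-scaled Fisher scale. These are the fifteen edges reported as
#: consistently meaningful for distinguishing reappraisal from viewing.
TABLE_EDGE_EFFECTS = (
    ("SN", "SSN1", 0.364, 1.118),
    ("DMN2", "ACN2", -2.751, -1.067),
    ("DMN1", "ACN1", -4.098, -2.857),
    ("CBG", "HVIS", -0.667, -0.359),
    ("DMN1", "SSN2", -0.835, -0.647),
    ("CBG", "SSN2", -2.867, -2.236),
    ("DMN3", "LIMB", 1.114, 0.928),
    ("DMN1", "LFP", 1.555, 0.424),
    ("ACN2", "REW2", -1.490, -2.106),
    ("DMN2", "HVIS", -3.220, -3.558),
    ("ACN1", "SSN2", -1.253, -1.713),
    ("RFP", "SML", -0.958, -1.360),
    ("LIMB", "SSN1", -1.191, -1.623),
    ("LFP", "SML", -0.087, -0.620),
    ("ACN2", "SN", -0.253, -1.108),
)


def plant_from_z(z: float, n_timepoints: int) -> float:
    """Convert a sqrt(T-3)-scaled Fisher z-statistic to a partial correlation.

    The planted value is ``tanh(z / sqrt(T - 3))``: connectivity tables
    report z-statistics of this form, and magnitudes above ~4 would be
    impossible as raw atanh values of a partial correlation.
    """
    return float(np.tanh(z / np.sqrt(n_timepoints - 3)))


def default_edge_effects(n_timepoints: int = 284) -> list[tuple[int, int, float, float]]:
    """The fifteen reference edges as (i, j, r_view, r_reappraise) index tuples."""
    idx = {name: k for k, name in enumerate(CANONICAL_NETWORKS)}
    out = []
    for a, b, zv, zr in TABLE_EDGE_EFFECTS:
        i, j = sorted((idx[a], idx[b]))
        out.append((i, j, plant_from_z(zv, n_timepoints), plant_from_z(zr, n_timepoints)))
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic fMRI cohort.

    ``edge_effects`` lists planted inter-network partial correlations as
    (node_i, node_j, r_view, r_reappraise); nodes not mentioned are
    conditionally independent. ``on_not_pd`` controls what happens if the
    implied precision matrix is not positive definite: ``"error"`` raises,
    ``"shrink"`` scales all planted values toward 0 by the smallest factor
    (in steps of 0.05) that restores definiteness and records it.
    """

    n_subjects: int = 31
    n_nodes_kept: int = 17
    n_nodes_artifact: int = 8
    n_timepoints: int = 284
    tr_seconds: float = 1.0
    n_voxels: int = 2000
    edge_effects: list = None
    noise_sd: float = 0.2
    artifact_leakage: float = 0.0
    overlap: float = 0.0
    seed: int = 0
    on_not_pd: str = "error"

    def __post_init__(self):
        if self.edge_effects is None:
            # the reference edge table addresses the 17 canonical networks;
            # smaller node sets default to no planted coupling
            if self.n_nodes_kept == len(CANONICAL_NETWORKS):
                self.edge_effects = default_edge_effects(self.n_timepoints)
            else:
                self.edge_effects = []
        if self.n_timepoints < self.n_nodes_kept + self.n_nodes_artifact + 3:
            raise ValueError(
                "n_timepoints must be at least n_nodes_kept + n_nodes_artifact + 3 "
                "for partial correlations to be estimable"
            )
        for i, j, rv, rr in self.edge_effects:
            if not (0 <= i < self.n_nodes_kept and 0 <= j < self.n_nodes_kept and i != j):
                raise ValueError(f"edge ({i},{j}) outside kept-node range")
            for r in (rv, rr):
                if not -1.0 < r < 1.0:
                    raise ValueError(f"planted partial r {r} not strictly inside (-1, 1)")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if not 0.0 <= self.artifact_leakage < 1.0:
            raise ValueError("artifact_leakage must be in [0, 1)")
        if self.on_not_pd not in ("error", "shrink"):
            raise ValueError("on_not_pd must be 'error' or 'shrink'")

    @property
    def n_components(self) -> int:
        return self.n_nodes_kept + self.n_nodes_artifact

    def node_labels(self) -> list[str]:
        if self.n_nodes_kept == len(CANONICAL_NETWORKS):
            kept = list(CANONICAL_NETWORKS)
        else:
            kept = [f"NET{k + 1}" for k in range(self.n_nodes_kept)]
        return kept + [f"ART{k + 1}" for k in range(self.n_nodes_artifact)]


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery checks."""

    true_maps: SpatialMapSet = None
    true_timeseries: np.ndarray = None
    true_partial_corr: np.ndarray = None
    true_edge_diffs: np.ndarray = None
    shrink_factor: float = 1.0


def _planted_partial_corr(cfg: SimConfig, condition: str) -> np.ndarray:
    which = {"view": 2, "reappraise": 3}
    try:
        col = which[condition]
    except KeyError:
        raise ValueError(f"condition must be 'view' or 'reappraise', got {condition!r}")
    n = cfg.n_nodes_kept
    R = np.zeros((n, n))
    for eff in cfg.edge_effects:
        i, j = eff[0], eff[1]
        R[i, j] = R[j, i] = eff[col]
    return R


def _precision_from_partial(R: np.ndarray) -> np.ndarray:
    # unit-diagonal precision: Theta_ij = -r_ij * sqrt(Theta_ii * Theta_jj)
    return np.eye(R.shape[0]) - R + np.diag(np.diag(R))


def _is_pd(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return True
    except np.linalg.LinAlgError:
        return False


def planted_covariance(cfg: SimConfig, condition: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Covariance of kept nodes implied by the planted partial correlations.

    Returns (covariance, realized partial-correlation matrix, shrink factor).
    """
    R = _planted_partial_corr(cfg, condition)
    factor = 1.0
    Theta = _precision_from_partial(R * factor)
    while not _is_pd(Theta):
        if cfg.on_not_pd == "error":
            raise ValueError(
                "implied precision matrix is not positive definite; "
                "reduce planted partial correlations or set on_not_pd='shrink'"
            )
        factor -= 0.05
        if factor <= 0:
            raise ValueError("could not restore positive definiteness by shrinking")
        Theta = _precision_from_partial(R * factor)
    if factor < 1.0:
        warnings.warn(f"planted partial correlations shrunk by factor {factor:.2f}")
    cov = np.linalg.inv(Theta)
    return cov, R * factor, factor


def make_spatial_maps(cfg: SimConfig) -> tuple[SpatialMapSet, GroundTruth]:
    """Generate group component maps with controllable support overlap.

    Each component occupies a contiguous voxel block; with ``overlap`` > 0
    adjacent components share that fraction of their support, with the shared
    voxels carrying the same underlying values (so spatially overlapping
    components are positively correlated, as mixed ICA maps would be). Values
    are zero-mean within each map and each map has unit norm, so maps with
    disjoint supports have exactly zero Pearson correlation.
    """
    n_comp, n_vox = cfg.n_components, cfg.n_voxels
    if n_vox < 4 * n_comp:
        raise ValueError(
            f"need n_voxels >= 4 x components ({4 * n_comp}), got {n_vox}"
        )
    support = n_vox // n_comp
    shared = int(round(cfg.overlap * support))
    if shared >= support:
        raise ValueError(
            f"overlap {cfg.overlap} leaves no private support (support={support})"
        )
    rng = substream(cfg.seed, "maps")
    values = rng.standard_normal(n_vox)  # one field; overlaps share values
    stride = support - shared
    maps = np.zeros((n_comp, n_vox))
    for c in range(n_comp):
        start = c * stride
        stop = start + support
        if stop > n_vox:
            raise ValueError("infeasible overlap/support layout: supports exceed grid")
        seg = values[start:stop]
        maps[c, start:stop] = seg - seg.mean()
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate component support (zero norm)")
    maps /= norms[:, None]
    labels = cfg.node_labels()
    kept = np.array([not l.startswith("ART") for l in labels])
    mapset = SpatialMapSet(maps, labels, kept_flags=kept)
    return mapset, GroundTruth(true_maps=mapset)


def make_node_timeseries(cfg: SimConfig, condition: str) -> tuple[NodeTimeseries, GroundTruth]:
    """Sample one subjectless run of node timeseries for a condition.

    Kept nodes are T i.i.d. draws from N(0, Sigma) where the precision
    matrix of Sigma encodes the condition's planted partial correlations.
    Artifact nodes are independent unit-variance noise, optionally leaked
    onto by the kept nodes via ``artifact_leakage`` (for testing cleanup).
    """
    cov, R, factor = planted_covariance(cfg, condition)
    rng = substream(cfg.seed, f"timeseries-{condition}")
    L = np.linalg.cholesky(cov)
    kept = rng.standard_normal((cfg.n_timepoints, cfg.n_nodes_kept)) @ L.T
    art = rng.standard_normal((cfg.n_timepoints, cfg.n_nodes_artifact))
    lam = cfg.artifact_leakage
    if lam > 0 and cfg.n_nodes_artifact > 0:
        mix = rng.standard_normal((cfg.n_nodes_kept, cfg.n_nodes_artifact))
        mix /= np.linalg.norm(mix, axis=0, keepdims=True)
        art = np.sqrt(1 - lam**2) * art + lam * (kept @ mix) / np.std(kept @ mix, axis=0)
    data = np.column_stack([kept, art])
    labels = cfg.node_labels()
    flags = np.array([l.startswith("ART") for l in labels])
    ts = NodeTimeseries(data, labels, flags, cfg.tr_seconds)
    gt = GroundTruth(
        true_timeseries=data,
        true_partial_corr=R,
        true_edge_diffs=planted_edge_diffs(cfg),
        shrink_factor=factor,
    )
    return ts, gt


def planted_edge_diffs(cfg: SimConfig) -> np.ndarray:
    """Planted (reappraise - view) partial-correlation difference per edge."""
    Rv = _planted_partial_corr(cfg, "view")
    Rr = _planted_partial_corr(cfg, "reappraise")
    iu = np.triu_indices(cfg.n_nodes_kept, k=1)
    return (Rr - Rv)[iu]


def make_voxel_data(
    maps: SpatialMapSet, ts: NodeTimeseries, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Forward model: voxel x time data = maps^T . ts^T + Gaussian noise."""
    if maps.n_components != ts.n_nodes:
        raise ValueError(
            f"maps have {maps.n_components} components but timeseries has "
            f"{ts.n_nodes} nodes"
        )
    data = maps.maps.T @ ts.data.T
    if noise_sd > 0:
        rng = substream(seed, "voxelnoise")
        data = data + noise_sd * rng.standard_normal(data.shape)
    return data


# ---------------------------------------------------------------------------
# Electrodermal traces

#: Rise and decay time constants (s) of the response bump. The bump is a
#: difference of exponentials h(t) = exp(-t/decay) - exp(-t/rise), which
#: peaks at t* = ln(decay/rise) * rise*decay/(decay-rise) ~ 2.15 s after
#: onset — inside the 2-6 s window typical of stimulus-evoked responses.
SCR_RISE_TAU = 1.0
SCR_DECAY_TAU = 6.0


@dataclass
class ScrSimConfig:
    """Parameters of a synthetic electrodermal recording."""

    fs_hz: int = 1000
    trial_onsets: list = field(default_factory=lambda: [10.0])
    amplitudes: list = field(default_factory=lambda: [0.5])
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.005
    rf_noise_sd: float = 0.0
    duration_s: float = None
    seed: int = 0

    def __post_init__(self):
        onsets = np.asarray(self.trial_onsets, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if onsets.size != amps.size:
            raise ValueError("one amplitude per trial onset required")
        if np.any(np.diff(onsets) < 9.0):
            raise ValueError("inter-onset intervals must be at least 9 s")
        if onsets.size and onsets[0] < 1.0:
            raise ValueError("first onset must allow a 1 s pre-stimulus baseline")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.duration_s is None:
            self.duration_s = float(onsets[-1] + 15.0) if onsets.size else 30.0
        if onsets.size and onsets[-1] + 9.0 > self.duration_s:
            raise ValueError("onsets leave less than 9 s of post-onset recording")


def _bump(t: np.ndarray, amplitude: float) -> np.ndarray:
    h = np.where(
        t >= 0, np.exp(-np.maximum(t, 0) / SCR_DECAY_TAU) - np.exp(-np.maximum(t, 0) / SCR_RISE_TAU), 0.0
    )
    tstar = (
        np.log(SCR_DECAY_TAU / SCR_RISE_TAU)
        * SCR_RISE_TAU
        * SCR_DECAY_TAU
        / (SCR_DECAY_TAU - SCR_RISE_TAU)
    )
    peak = np.exp(-tstar / SCR_DECAY_TAU) - np.exp(-tstar / SCR_RISE_TAU)
    return amplitude * h / peak


def make_scr_trace(cfg: ScrSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a raw electrodermal trace (uS at fs_hz).

    The trace is slow sinusoidal drift + white high-frequency noise + one
    response bump per trial with the requested trough-to-peak amplitude.
    Returns (samples, true_amplitudes).
    """
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    rng = substream(cfg.seed, "scr")
    trace = cfg.drift_amplitude * np.sin(2 * np.pi * cfg.drift_freq_hz * t)
    if cfg.rf_noise_sd > 0:
        trace = trace + cfg.rf_noise_sd * rng.standard_normal(n)
    for onset, amp in zip(cfg.trial_onsets, cfg.amplitudes):
        trace = trace + _bump(t - onset, amp)
    return trace, np.asarray(cfg.amplitudes, dtype=float)


# ---------------------------------------------------------------------------
# Behavioral tables

#: Default planted condition means per measure, (view, reappraise, sd of the
#: paired difference). Ratings are on the 1-7 Likert scale, accuracies in
#: percent; values match the magnitudes reported for this task.
DEFAULT_BEHAV_EFFECTS = {
    "neg_rating": (4.516, 4.258, 0.636),
    "pos_rating": (2.726, 3.006, 0.700),
    "hit_rate": (93.35, 96.98, 6.60),
    "source_acc": (79.18, 76.46, 37.0),
}


def make_behavioral_table(
    n_subjects: int = 31,
    planted_mean_diffs: dict | None = None,
    planted_sds: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a subject x condition behavioral table with planted effects.

    Per-subject condition means are drawn as measure mean + subject offset +
    within-condition noise, so the paired difference across conditions has
    the planted mean and standard deviation. Ratings are clipped to [1, 7]
    and accuracies to [0, 100]; the clipping rate per measure is returned.

    Returns (table, info) where table has one row per subject x condition
    with columns subject, condition, neg_rating, pos_rating, hit_rate,
    source_acc; info records planted parameters and clipping rates.
    """
    effects = dict(DEFAULT_BEHAV_EFFECTS)
    if planted_mean_diffs:
        for k, diff in planted_mean_diffs.items():
            base = effects[k]
            effects[k] = (base[0], base[0] + diff, base[2])
    if planted_sds:
        for k, sd in planted_sds.items():
            base = effects[k]
            effects[k] = (base[0], base[1], sd)
    rng = substream(seed, "behavior")
    rows = {"subject": [], "condition": []}
    clip_info = {}
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    for cond in ("view", "reappraise"):
        rows["subject"].extend(subjects)
        rows["condition"].extend([cond] * n_subjects)
    for measure, (m_view, m_reapp, sd_diff) in effects.items():
        between_sd = sd_diff  # subject-level spread, comparable scale
        offset = between_sd * rng.standard_normal(n_subjects)
        within = (sd_diff / np.sqrt(2)) * rng.standard_normal((2, n_subjects))
        vals_view = m_view + offset + within[0]
        vals_reapp = m_reapp + offset + within[1]
        vals = np.concatenate([vals_view, vals_reapp])
        lo, hi = (1.0, 7.0) if measure.endswith("rating") else (0.0, 100.0)
        clipped = np.clip(vals, lo, hi)
        clip_info[measure] = float(np.mean(clipped != vals))
        rows[measure] = clipped
    table = pd.DataFrame(rows)
    info = {"planted": effects, "clip_rate": clip_info, "n_subjects": n_subjects}
    return table, info
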