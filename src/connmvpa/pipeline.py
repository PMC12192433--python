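"""End-to-end orchestration of the synthetic connectivity study.

``run_pipeline`` executes the requested stages in dependency order on a
synthetic cohort: simulate group maps and subject data, match networks,
dual-regress each subject, build netmats and edge vectors, then run the
edge-wise permutation GLM, the connectome MVPA with consistency selection,
the SCR scoring chain and the behavioral statistics. Every stage draws its
randomness from a named substream of one root seed, so reruns with the same
configuration are byte-identical and stages can be regenerated in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .behav import PairedSample, paired_test
from .containers import edge_labels
from .dualreg import dual_regression_stage1, match_networks
from .edgestats import PairedEdgeContrast
from .mvpa import ConnectomeMvpa, MvpaDataset, consistency_selection, refit_selected
from .netmats import flatten_edges, netmat_from_timeseries
from .scr import ScrRecording, condition_contrast, score_recording, subject_summary
from .synth import (
    ScrSimConfig,
    SimConfig,
    make_behavioral_table,
    make_node_timeseries,
    make_scr_trace,
    make_voxel_data,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("view", "reappraise")

#: Planted per-condition mean (and between-subject SD) of the sqrt-amplitude
#: SCR score, in sqrt(uS): passive viewing responds more strongly than
#: reappraisal.
SCR_PLANTED = {"view": (0.27, 0.21), "reappraise": (0.20, 0.15)}

#: Correlation of a subject's responsiveness across conditions.
#: Electrodermal reactivity is a stable individual trait, so the paired
#: design gains power from the shared component.
SCR_TRAIT_CORRELATION = 0.8


@dataclass
class RunConfig:
    """One declarative configuration for the whole pipeline.

    Defaults are the analysis constants of the study the pipeline
    implements: matching threshold r >= 0.3, 5000 permutations, SVM C = 1.0,
    top-10% consistency selection with an 11-fold threshold, 0.15 Hz
    low-pass / 0.01 Hz high-pass SCR filters, 10 Hz downsampling, 17 kept
    networks (136 edges).
    """

    seed: int = 0
    out_dir: str = "pipeline-out"
    stages: tuple = ("simulate", "dualreg", "netmat", "edgestats", "mvpa", "scr", "behav")
    # simulation
    n_subjects: int = 31
    n_nodes_kept: int = 17
    n_nodes_artifact: int = 8
    n_timepoints: int = 284
    n_voxels: int = 2000
    noise_sd: float = 0.2
    n_trials_per_condition: int = 16
    # analysis constants
    match_threshold: float = 0.3
    fisher_scaling: str = "zstat_scaled"
    n_perm: int = 5000
    n_perm_mvpa: int = None  # defaults to n_perm; the MVPA permutations
    # rerun the full LOSO fit and are the only expensive stage
    svm_C: float = 1.0
    top_fraction: float = 0.10
    consistency_threshold: int = 11
    fdr_q: float = 0.05
    scr_lowpass_hz: float = 0.15
    scr_highpass_hz: float = 0.01
    scr_downsample_hz: float = 10.0

    def parameter_hash(self) -> str:
        # identifies the analysis parameters; seed and paths are provenance,
        # not parameters, and are reported separately
        payload = dataclasses.asdict(self)
        payload.pop("seed")
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _subject_seed(root_seed: int, subject: int) -> int:
    return int(substream(root_seed, f"subject-{subject}").integers(2**31))


def simulate_cohort(config: RunConfig):
    """Generate group maps and per-subject/condition edge vectors.

    Returns (matched_maps, edge_arrays, netmats) where ``edge_arrays`` maps
    condition -> subject x edge matrix of Fisher-z partial correlations.
    """
    base = SimConfig(
        n_subjects=config.n_subjects,
        n_nodes_kept=config.n_nodes_kept,
        n_nodes_artifact=config.n_nodes_artifact,
        n_timepoints=config.n_timepoints,
        n_voxels=config.n_voxels,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    from .synth import make_spatial_maps

    maps, _ = make_spatial_maps(base)
    references = _kept_subset(maps)
    matched = match_networks(maps, references, r_threshold=config.match_threshold)
    n_kept = int(matched.kept_flags.sum())
    logger.info("matched %d/%d components as networks", n_kept, maps.n_components)

    edge_arrays = {c: [] for c in CONDITIONS}
    netmats = {c: [] for c in CONDITIONS}
    for s in range(config.n_subjects):
        sub_cfg = dataclasses.replace(base, seed=_subject_seed(config.seed, s))
        for k, cond in enumerate(CONDITIONS):
            ts_true, _ = make_node_timeseries(sub_cfg, cond)
            data = make_voxel_data(maps, ts_true, config.noise_sd, seed=sub_cfg.seed + k)
            stage1 = dual_regression_stage1(matched, data)
            nm = netmat_from_timeseries(stage1, scaling=config.fisher_scaling)
            netmats[cond].append(nm)
            edge_arrays[cond].append(flatten_edges(nm))
    edge_arrays = {c: np.array(v) for c, v in edge_arrays.items()}
    return matched, edge_arrays, netmats


def _kept_subset(mapset):
    from .containers import SpatialMapSet

    keep = mapset.kept_flags
    return SpatialMapSet(
        mapset.maps[keep],
        [l for l, k in zip(mapset.component_ids, keep) if k],
    )


def simulate_scr_cohort(config: RunConfig):
    """Per-subject electrodermal traces with planted condition effects.

    Each subject gets one recording per condition with
    ``n_trials_per_condition`` trials; the planted trial amplitudes are the
    square of a subject-level sqrt-amplitude drawn from the planted
    condition mean/SD (floored at zero, which also produces occasional
    non-responders at realistic rates).
    """
    rng = substream(config.seed, "scr-cohort")
    rho = SCR_TRAIT_CORRELATION
    summaries = []
    for s in range(config.n_subjects):
        scores = {}
        trait = rng.standard_normal()
        for cond in CONDITIONS:
            m, sd = SCR_PLANTED[cond]
            unique = rng.standard_normal()
            sqrt_amp = max(0.0, m + sd * (rho * trait + np.sqrt(1 - rho**2) * unique))
            jitter = 0.2 * sqrt_amp * rng.standard_normal(config.n_trials_per_condition)
            amps = np.maximum(sqrt_amp + jitter, 0.0) ** 2
            amps[amps < 0.0004] = 0.0  # sub-threshold squares score as zero anyway
            onsets = 10.0 + 18.0 * np.arange(config.n_trials_per_condition)
            scr_cfg = ScrSimConfig(
                trial_onsets=list(onsets),
                amplitudes=list(amps),
                drift_amplitude=0.3,
                rf_noise_sd=0.01,
                seed=_subject_seed(config.seed, s) + (0 if cond == "view" else 1),
            )
            trace, _ = make_scr_trace(scr_cfg)
            events = pd.DataFrame(
                {"onset": onsets, "duration": 8.0, "condition": cond}
            )
            rec = ScrRecording(trace, scr_cfg.fs_hz, events)
            scores[cond] = score_recording(
                rec,
                lowpass_hz=config.scr_lowpass_hz,
                highpass_hz=config.scr_highpass_hz,
                target_hz=config.scr_downsample_hz,
            )
        summaries.append(subject_summary(scores))
    return summaries


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs under ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``. Raises if a requested stage's prerequisite stage is
    not part of the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    for stage, needs in (
        ("dualreg", "simulate"),
        ("netmat", "dualreg"),
        ("edgestats", "netmat"),
        ("mvpa", "netmat"),
    ):
        if stage in stages and needs not in stages:
            raise ValueError(f"stage '{stage}' requires stage '{needs}' to run first")

    summary: dict = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "parameter_hash": config.parameter_hash(),
        }
    }
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )

    labels = None
    if {"simulate", "dualreg", "netmat"} <= set(stages):
        matched, edges, netmats_by_cond = simulate_cohort(config)
        kept_labels = [
            matched.match_label[i]
            for i in np.flatnonzero(matched.kept_flags)
        ]
        labels = edge_labels(kept_labels)
        for cond in CONDITIONS:
            df = pd.DataFrame(edges[cond], columns=labels)
            df.insert(0, "subject", [f"sub-{i + 1:02d}" for i in range(config.n_subjects)])
            df.to_csv(out / f"edges_{cond}.tsv", sep="\t", index=False)
        summary["simulate"] = {
            "n_components": matched.n_components,
            "n_matched_networks": int(matched.kept_flags.sum()),
            "n_edges": len(labels),
        }

    if "edgestats" in stages:
        model = PairedEdgeContrast(edges["view"], edges["reappraise"], labels)
        res = model.fit(n_perm=config.n_perm, seed=config.seed, q=config.fdr_q)
        res.to_tsv(out / "edgestats.tsv")
        summary["edgestats"] = {
            "n_edges": len(res.edge_labels),
            "n_significant_fdr": len(res.significant_edges),
            "significant_edges": res.significant_edges,
            "min_p_fdr": float(np.min(res.p_fdr)),
        }

    if "mvpa" in stages:
        dataset = MvpaDataset.from_edge_vectors(
            edges["view"], edges["reappraise"], edge_labels=labels
        )
        n_perm_mvpa = config.n_perm_mvpa or config.n_perm
        full = ConnectomeMvpa(dataset, C=config.svm_C).fit(
            n_perm=n_perm_mvpa, seed=config.seed
        )
        sel = consistency_selection(
            full,
            top_fraction=config.top_fraction,
            count_threshold=config.consistency_threshold,
        )
        sel.summary().to_csv(out / "mvpa_selection.tsv", sep="\t", index=False)
        pd.DataFrame(full.fold_coefficients, columns=labels).to_csv(
            out / "mvpa_coefficients.tsv", sep="\t", index=False
        )
        summary["mvpa"] = {
            "accuracy": full.accuracy,
            "n_correct": full.n_correct,
            "n_samples": len(dataset.y),
            "n_permutations": n_perm_mvpa,
            "p_value": full.p_value,
            "p_value_k_over_n": full.p_value_k_over_n,
            "top_k_per_fold": sel.top_k,
            "selection_prob": sel.selection_prob,
            "binomial_tail_p": sel.binomial_tail_p,
            "selected_edges": sel.selected_labels,
        }
        if len(sel.selected_edges):
            refit = refit_selected(
                dataset, sel.selected_edges, C=config.svm_C,
                n_perm=n_perm_mvpa, seed=config.seed,
            )
            summary["mvpa"]["refit"] = {
                "accuracy": refit.accuracy,
                "p_value": refit.p_value,
                "p_value_k_over_n": refit.p_value_k_over_n,
                "selection_is_circular": refit.selection_is_circular,
            }

    if "scr" in stages:
        summaries = simulate_scr_cohort(config)
        result, n_included, excluded = condition_contrast(summaries)
        rows = [
            {"subject": f"sub-{i + 1:02d}", "non_responder": s["non_responder"],
             **{f"mean_sqrt_{c}": s["condition_means"][c] for c in CONDITIONS}}
            for i, s in enumerate(summaries)
        ]
        pd.DataFrame(rows).to_csv(out / "scr_subjects.tsv", sep="\t", index=False)
        included = [s for s in summaries if not s["non_responder"]]
        summary["scr"] = {
            "n_included": n_included,
            "n_non_responders": len(excluded),
            "mean_view": float(np.mean([s["condition_means"]["view"] for s in included])),
            "mean_reappraise": float(
                np.mean([s["condition_means"]["reappraise"] for s in included])
            ),
            "t": result.t,
            "df": result.df,
            "p": result.p_two_tailed,
            "d": result.d_effect,
        }

    if "behav" in stages:
        table, info = make_behavioral_table(config.n_subjects, seed=config.seed)
        table.to_csv(out / "behavioral.csv", index=False)
        behav_stats = {}
        for measure in ("neg_rating", "pos_rating", "hit_rate", "source_acc"):
            piv = table.pivot(index="subject", columns="condition", values=measure)
            res = paired_test(
                PairedSample(piv["view"].to_numpy(), piv["reappraise"].to_numpy())
            )
            behav_stats[measure] = {
                "t": res.t, "df": res.df, "p": res.p_two_tailed, "d": res.d_effect,
                "mean_view": float(piv["view"].mean()),
                "mean_reappraise": float(piv["reappraise"].mean()),
            }
        summary["behav"] = behav_stats
        summary["behav_clip_rate"] = info["clip_rate"]

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
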