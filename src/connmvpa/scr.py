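"""Skin-conductance response scoring: filter, downsample, trough-to-peak.

The scoring chain for event-related electrodermal activity recorded at
1000 Hz:

1. 0.15 Hz low-pass Butterworth (removes scanner radiofrequency noise),
   then 0.01 Hz high-pass Butterworth (removes slow-wave drift); both
   2nd order by default, applied forward-backward so peak latencies are
   not shifted;
2. downsample to 10 Hz (the low-pass stage already band-limits the signal);
3. per trial: subtract the 1 s pre-onset baseline mean, take the minimum in
   [onset, onset+1 s) as the trough and the maximum in [onset+1 s,
   onset+8 s] as the peak; amplitude = peak - trough, set to zero when it
   does not reach 0.02 uS (negative differences included), then square-root
   transformed;
4. subjects with no non-zero amplitude on any trial are flagged
   non-responders and excluded from the condition contrast (reported, never
   silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .behav import PairedSample, paired_test

__all__ = [
    "ScrRecording",
    "ScrTrialScore",
    "filter_trace",
    "downsample",
    "score_trial",
    "score_recording",
    "subject_summary",
    "condition_contrast",
]

#: Amplitude floor in uS: a trough-to-peak difference below this is scored 0.
SCR_THRESHOLD_US = 0.02


@dataclass
class ScrRecording:
    """Single-channel electrodermal trace with trial events.

    ``events`` is a DataFrame with columns ``onset`` (seconds from recording
    start, 0-based), ``duration`` and optionally ``condition``.
    """

    samples: np.ndarray
    fs_hz: float
    events: pd.DataFrame = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.events is not None:
            onsets = np.asarray(self.events["onset"], dtype=float)
            span = len(self.samples) / self.fs_hz
            if np.any(onsets < 0) or np.any(onsets > span):
                raise ValueError("event onset outside recording span")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class ScrTrialScore:
    """Trough-to-peak score for one trial (all values in uS)."""

    onset: float
    trough: float
    peak: float
    amplitude: float
    amplitude_sqrt: float
    condition: str = None


def _butter_sos(cutoff_hz: float, fs_hz: float, btype: str, order: int):
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({fs_hz / 2} Hz)")
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs_hz, output="sos")


def filter_trace(
    rec: ScrRecording,
    lowpass_hz: float = 0.15,
    highpass_hz: float = 0.01,
    order: int = 2,
    zero_phase: bool = True,
) -> ScrRecording:
    """Low-pass then high-pass Butterworth filtering, sample count preserved."""
    x = rec.samples
    for cutoff, btype in ((lowpass_hz, "lowpass"), (highpass_hz, "highpass")):
        sos = _butter_sos(cutoff, rec.fs_hz, btype, order)
        x = signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)
    return replace(rec, samples=x)


def downsample(rec: ScrRecording, target_hz: float = 10.0) -> ScrRecording:
    """Decimate by an integer factor (run after the low-pass stage)."""
    factor = rec.fs_hz / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {rec.fs_hz} Hz not divisible by target {target_hz} Hz")
    return ScrRecording(rec.samples[:: int(round(factor))], target_hz, rec.events)


def score_trial(rec: ScrRecording, onset: float, condition: str = None) -> ScrTrialScore:
    """Score one trial on the (filtered, downsampled) recording.

    Baseline = mean over [onset-1 s, onset); windows are half-open
    [start, stop) in samples except the peak window, which includes its
    8 s endpoint.
    """
    fs = rec.fs_hz
    i_on = int(round(onset * fs))
    i_base = i_on - int(round(fs))
    i_trough_end = i_on + int(round(fs))
    i_peak_end = i_on + int(round(8 * fs))
    if i_base < 0 or i_peak_end >= len(rec.samples):
        raise ValueError(
            f"trial at {onset} s needs 1 s before and 8 s after onset within the recording"
        )
    baseline = rec.samples[i_base:i_on].mean()
    seg = rec.samples - baseline
    trough = float(seg[i_on:i_trough_end].min())
    peak = float(seg[i_trough_end : i_peak_end + 1].max())
    amplitude = peak - trough
    if amplitude < SCR_THRESHOLD_US:
        amplitude = 0.0
    return ScrTrialScore(
        onset=onset,
        trough=trough,
        peak=peak,
        amplitude=amplitude,
        amplitude_sqrt=float(np.sqrt(amplitude)),
        condition=condition,
    )


def score_recording(
    rec: ScrRecording,
    lowpass_hz: float = 0.15,
    highpass_hz: float = 0.01,
    order: int = 2,
    target_hz: float = 10.0,
) -> list[ScrTrialScore]:
    """Full chain on a raw recording: filter, downsample, score every event."""
    if rec.events is None:
        raise ValueError("recording has no events to score")
    prepared = downsample(
        filter_trace(rec, lowpass_hz=lowpass_hz, highpass_hz=highpass_hz, order=order),
        target_hz,
    )
    out = []
    for _, ev in rec.events.iterrows():
        cond = ev["condition"] if "condition" in rec.events.columns else None
        out.append(score_trial(prepared, float(ev["onset"]), cond))
    return out


def subject_summary(scores_by_condition: dict) -> dict:
    """Per-condition mean sqrt-amplitude and the non-responder flag.

    ``scores_by_condition`` maps condition name to that subject's list of
    :class:`ScrTrialScore`. A subject is a non-responder iff every trial
    amplitude is zero across all conditions.
    """
    all_amps = [s.amplitude for scores in scores_by_condition.values() for s in scores]
    if not all_amps:
        raise ValueError("no trials to summarize")
    means = {
        cond: float(np.mean([s.amplitude_sqrt for s in scores]))
        for cond, scores in scores_by_condition.items()
    }
    return {"condition_means": means, "non_responder": all(a == 0 for a in all_amps)}


def condition_contrast(
    summaries: list[dict], condition_a: str = "view", condition_b: str = "reappraise"
):
    """Paired condition contrast over subjects, excluding non-responders.

    Returns (TestResult, n_included, excluded_indices); excluded subjects
    are reported by index, never silently dropped.
    """
    excluded = [i for i, s in enumerate(summaries) if s["non_responder"]]
    included = [s for s in summaries if not s["non_responder"]]
    if len(included) < 3:
        raise ValueError("fewer than 3 responding subjects")
    a = np.array([s["condition_means"][condition_a] for s in included])
    b = np.array([s["condition_means"][condition_b] for s in included])
    result = paired_test(PairedSample(a, b, labels=(condition_a, condition_b)))
    return result, len(included), excluded
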