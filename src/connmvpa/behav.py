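"""Behavioral statistics: paired t-tests, two-tailed p, and effect sizes.

The effect size d' is the absolute mean difference divided by the
root-mean-square of the two condition standard deviations,
d' = |m_a - m_b| / sqrt((sd_a^2 + sd_b^2) / 2) — the formula consistent with
the reported values for this task battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "TestResult",
    "paired_t",
    "p_from_t",
    "cohens_d",
    "paired_test",
    "memory_summary",
]


@dataclass
class PairedSample:
    """Per-subject condition means for a paired comparison."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple = ("a", "b")

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("values_a and values_b must be 1-D and equal length")
        if len(self.values_a) < 3:
            raise ValueError("need at least 3 subjects")

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass
class TestResult:
    """t, degrees of freedom, two-tailed p and effect size d'."""

    t: float
    df: int
    p_two_tailed: float = None
    d_effect: float = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"t": self.t, "df": self.df, "p": self.p_two_tailed, "d": self.d_effect}]
        )


def paired_t(sample: PairedSample) -> TestResult:
    """Paired t statistic: t = mean(a-b) / (sd(a-b)/sqrt(n)), df = n-1."""
    d = sample.values_a - sample.values_b
    n = sample.n
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
    return TestResult(t=t, df=n - 1)


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p from the t distribution: p = 2 P(T_df > |t|)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2 * stats.t.sf(abs(t), df))


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Effect size d' = |mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2)/2)."""
    denom = np.sqrt((sd_a**2 + sd_b**2) / 2)
    if denom == 0:
        return 0.0 if mean_a == mean_b else float(np.inf)
    return float(abs(mean_a - mean_b) / denom)


def paired_test(sample: PairedSample) -> TestResult:
    """Full paired comparison: t, df, two-tailed p, and d' from the condition
    means and SDs."""
    res = paired_t(sample)
    res.p_two_tailed = p_from_t(res.t, res.df) if np.isfinite(res.t) else 0.0
    res.d_effect = cohens_d(
        float(sample.values_a.mean()),
        float(sample.values_a.std(ddof=1)),
        float(sample.values_b.mean()),
        float(sample.values_b.std(ddof=1)),
    )
    return res


def memory_summary(table: pd.DataFrame) -> dict:
    """Summarize an item-level recognition-memory table.

    ``table`` needs columns ``subject``, ``condition`` (view / reappraise /
    new), ``old_response`` ("old"/"new") and, for old items only,
    ``source_response`` (view / reappraise). Returns per-subject old/new
    accuracy, per-condition hit rates, source-decision accuracy over old
    items, and their simple means across subjects (rates in percent).
    """
    required = {"subject", "condition", "old_response"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_subject = []
    for sub, g in table.groupby("subject"):
        old = g[g["condition"].isin(["view", "reappraise"])]
        new = g[g["condition"] == "new"]
        if len(old) == 0 or len(new) == 0:
            raise ValueError(f"subject {sub!r} has an empty old or new condition cell")
        row = {"subject": sub}
        correct = np.where(
            g["condition"] == "new", g["old_response"] == "new", g["old_response"] == "old"
        )
        row["overall_acc"] = 100 * float(np.mean(correct))
        row["old_acc"] = 100 * float((old["old_response"] == "old").mean())
        row["new_acc"] = 100 * float((new["old_response"] == "new").mean())
        for cond in ("view", "reappraise"):
            sel = old[old["condition"] == cond]
            if len(sel) == 0:
                raise ValueError(f"subject {sub!r} has no {cond!r} items")
            row[f"hit_rate_{cond}"] = 100 * float((sel["old_response"] == "old").mean())
            if "source_response" in old.columns:
                row[f"source_acc_{cond}"] = 100 * float(
                    (sel["source_response"] == cond).mean()
                )
        per_subject.append(row)
    df = pd.DataFrame(per_subject)
    means = df.drop(columns="subject").mean().to_dict()
    return {"per_subject": df, "means": means}
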