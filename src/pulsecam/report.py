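"""Standardized accuracy report: agreement between rPPG and a reference.

Given per-video heart-rate estimates paired with a reference measurement
(typically contact pulse oximetry), the report computes Spearman rank
correlations, mean +/- SD of the absolute (rectified) difference per
condition cell, Bland-Altman bias and limits of agreement, and the
distinctiveness (ROC AUC) of heart-rate distributions between conditions,
expressed also as a separability percentage 100*(2*AUC - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkRecord",
    "spearman_corr",
    "abs_diff_stats",
    "bland_altman",
    "auc_separability",
    "corr_vs_length",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One video's estimate vs reference, with condition labels."""

    video_id: str
    hr_rppg: float
    hr_reference: float
    conditions: dict | None = None

    def __post_init__(self) -> None:
        for name in ("hr_rppg", "hr_reference"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def _records_frame(records: Sequence[BenchmarkRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        row = {"video_id": r.video_id, "hr_rppg": r.hr_rppg, "hr_reference": r.hr_reference}
        row.update(r.conditions or {})
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties; needs n >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError(
            f"correlations require a minimum of three data points, got {len(x)}"
        )
    return float(stats.spearmanr(x, y).statistic)


def abs_diff_stats(
    records: Sequence[BenchmarkRecord] | pd.DataFrame,
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean +/- sample SD of |hr_rppg - hr_reference| per condition cell."""
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records to summarise")
    df = df.assign(abs_diff=(df["hr_rppg"] - df["hr_reference"]).abs())
    if not group_by:
        g = df["abs_diff"]
        return pd.DataFrame(
            {"n": [len(g)], "abs_diff_mean": [g.mean()], "abs_diff_sd": [g.std(ddof=1)]}
        )
    out = (
        df.groupby(list(group_by), dropna=False)["abs_diff"]
        .agg(n="count", abs_diff_mean="mean", abs_diff_sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def bland_altman(
    records: Sequence[BenchmarkRecord] | pd.DataFrame,
) -> tuple[float, float, float, pd.DataFrame]:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    diffs = rPPG - reference; bias = mean(diffs); limits = bias +/- 1.96 *
    SD(diffs) (sample SD).  Returns (bias, loa_low, loa_high, frame) where
    the frame holds per-pair means and diffs for plotting.
    """
    df = _records_frame(records)
    if len(df) < 3:
        raise ValueError(f"Bland-Altman needs n >= 3 pairs, got {len(df)}")
    diffs = (df["hr_rppg"] - df["hr_reference"]).to_numpy(float)
    means = ((df["hr_rppg"] + df["hr_reference"]) / 2.0).to_numpy(float)
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    pairs = pd.DataFrame({"mean": means, "diff": diffs})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, pairs


def auc_separability(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Distinctiveness of two rate distributions.

    auc = P(B > A) + 0.5 * P(B = A) over all pairs (the rank-sum / ROC-AUC
    statistic, midrank tie convention); separability_pct = 100 * (2*auc - 1),
    clipped below at 0.  Returns (auc, separability_pct).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    auc = float(u) / (a.size * b.size)
    sep = max(0.0, 100.0 * (2.0 * auc - 1.0))
    return auc, sep


def corr_vs_length(
    inputs: Sequence,
    reference: Sequence[float],
    lengths_s: Sequence[float],
    estimate: Callable[[object], float],
    truncate: Callable[[object, float], object],
) -> pd.DataFrame:
    """Spearman correlation with the reference as a function of analyzed
    record length.

    For each length, every input is truncated to that many seconds,
    re-estimated from scratch with ``estimate`` and correlated against the
    reference.  Inputs whose estimation fails at a given length are
    dropped for that length; lengths retaining fewer than three data
    points are omitted.  Raises if no length yields a correlation.
    """
    if len(inputs) != len(reference):
        raise ValueError("one reference rate per input is required")
    if len(inputs) < 3:
        raise ValueError("correlations require a minimum of three data points")
    rows = []
    for L in lengths_s:
        est, ref = [], []
        for item, r in zip(inputs, reference):
            try:
                est.append(estimate(truncate(item, L)))
                ref.append(r)
            except Exception:  # noqa: BLE001 - per-item failure tolerated
                continue
        if len(est) >= 3:
            rows.append({"length_s": L, "n": len(est), "rho": spearman_corr(est, ref)})
    if not rows:
        raise ValueError("no analyzed length retained the minimum of three data points")
    return pd.DataFrame(rows)
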