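"""Scoring of fitted dispersal models against the full plots survey.

All criteria compare model predictions with the *raw* full-plots actual
CP rates: RMSE and Pearson r on the raw CP scale, relative error as the
per-plot ratio |pred - obs| / obs over plots with obs > 0. Bootstrap
summaries use the percentile bootstrap confidence interval (PBCI): the
order statistics at ranks ceil(0.025 B) and ceil(0.975 B) of the sorted
replicate values, so endpoints are always members of the input — no
interpolation, bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "ReplicateMetrics",
    "BoxStats",
    "rmse",
    "pearson_r",
    "relative_error",
    "pbci",
    "ci_coverage",
    "iqr_summary",
]


@dataclass(frozen=True)
class ReplicateMetrics:
    """Per-bootstrap-replicate scores for one scheme.

    ``mean_pred_cp`` is the field-average predicted CP with its
    within-replicate 95% CI ``(ci_low, ci_high)``; a failed fit leaves all
    metric fields NaN and sets ``failed``.
    """

    scheme_name: str
    replicate_index: int
    rmse: float = math.nan
    r: float = math.nan
    rel_err_mean: float = math.nan
    rel_err_sd: float = math.nan
    mean_pred_cp: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_sample: int = 0
    failed: bool = False
    failure: str = ""


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot summary (quartiles by the PBCI rank convention)."""

    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple = dc_field(default_factory=tuple)


def rmse(predicted, observed) -> float:
    """Root mean squared error between predictions and observations."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be equal-length and nonempty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pearson_r(predicted, observed) -> float:
    """Sample Pearson correlation; NaN (missing) if either side is constant."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be equal-length and nonempty")
    if pred.size < 2 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return math.nan
    return float(np.corrcoef(pred, obs)[0, 1])


def relative_error(predicted, observed) -> tuple[float, float]:
    """Mean and sample SD of |pred - obs| / obs over plots with obs > 0.

    Zero-CP plots carry no denominator and are excluded (their count is
    the difference between input length and qualifying plots). Returns
    (NaN, NaN) if no plot qualifies; the SD of a single qualifying plot
    is reported as 0.
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be equal-length and nonempty")
    mask = obs > 0
    if not mask.any():
        return math.nan, math.nan
    e = np.abs(pred[mask] - obs[mask]) / obs[mask]
    if e.size == 1:
        return float(e[0]), 0.0
    return float(e.mean()), float(e.std(ddof=1))


def _rank(q: float, n: int) -> int:
    """1-based order-statistic rank ceil(q*n), clamped to [1, n].

    A small epsilon guards against binary rounding of the level (e.g.
    1 - 0.95 = 0.050000000000000044) inflating the rank by one.
    """
    return min(max(int(math.ceil(q * n - 1e-9)), 1), n)


def pbci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI: order statistics at ranks ceil(a/2*B), ceil((1-a/2)*B).

    For B = 1000 at the 95% level these are the 25th and 975th sorted
    values; endpoints are always members of the input.
    """
    vals = np.sort(np.asarray(values, float))
    if vals.size < 2:
        raise ValueError("pbci needs at least 2 values")
    alpha = 1.0 - level
    lo = vals[_rank(alpha / 2.0, vals.size) - 1]
    hi = vals[_rank(1.0 - alpha / 2.0, vals.size) - 1]
    return float(lo), float(hi)


def ci_coverage(replicates, truth: float) -> float:
    """Percentage of replicate CIs containing the raw-field truth.

    ``replicates`` is an iterable of ReplicateMetrics or any objects/rows
    with ``ci_low``/``ci_high``; replicates with NaN bounds (failed fits)
    count as non-covering.
    """

    def _bounds(rep):
        if hasattr(rep, "ci_low"):
            return rep.ci_low, rep.ci_high
        return rep["ci_low"], rep["ci_high"]

    bounds = [_bounds(rep) for rep in replicates]
    if not bounds:
        raise ValueError("no replicates supplied")
    hits = sum(1 for lo, hi in bounds if lo <= truth <= hi)
    return 100.0 * hits / len(bounds)


def iqr_summary(values) -> BoxStats:
    """Tukey box-plot statistics with whiskers at 1.5 * IQR.

    Quartiles use the same order-statistic rank convention as ``pbci``;
    whiskers extend to the most extreme values inside the fences, and
    values beyond them are outliers.
    """
    vals = np.sort(np.asarray(values, float))
    if vals.size == 0:
        raise ValueError("iqr_summary needs at least 1 value")
    n = vals.size
    q1 = float(vals[_rank(0.25, n) - 1])
    med = float(vals[_rank(0.50, n) - 1])
    q3 = float(vals[_rank(0.75, n) - 1])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return BoxStats(
        q1=q1, median=med, q3=q3, iqr=iqr,
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )
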