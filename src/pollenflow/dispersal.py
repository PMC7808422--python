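"""Actual CP rates and the field-border pollen dispersal model.

The actual cross-pollination rate of a plot is the purple-grain fraction

    actual_cp = purple_grains / (n_ears * avk),

and the dispersal model relating CP to the isolation (border) width FB
and the distance D from the pollen-source edge is

    CP = p0 * 10**(a*FB + b*D).

Fitting happens on the log10 scale by default (ordinary least squares),
optionally on the raw CP scale (nonlinear least squares) or on the count
scale (Poisson GLM with a log link and a log-kernel offset). Plots whose
observed CP sits below the detection limit of one kernel are handled by a
configurable zero policy: drop them (default) or substitute a small floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DispersalFit",
    "compute_actual_cp",
    "estimate_p0",
    "fit_dispersal",
    "predict_cp",
    "predict_field",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class DispersalFit:
    """Fitted dispersal model.

    ``p0`` is the rate used in predictions (the fitted intercept when
    ``p0_mode="free"``, the first-sampled-row average CP when
    ``p0_mode="fixed"``); ``p0_first_row`` always carries the latter
    data summary. ``a_fixed`` flags that FB had no variation in the data
    (or ``fix_a`` was supplied), so the border coefficient was pinned.
    """

    p0: float
    a: float
    b: float
    n_plots_used: int
    fit_floor: float
    a_fixed: bool
    p0_mode: str = "free"
    method: str = "log_ols"
    zero_policy: str = "drop"
    p0_first_row: float = float("nan")
    n_zero_cp: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DispersalFit":
        return cls(**json.loads(text))


def compute_actual_cp(purple_grains: float, n_ears: int, avk: int) -> float:
    """Purple-grain fraction of a plot: grains / (n_ears * avk)."""
    if n_ears < 1 or avk < 1:
        raise ValueError("n_ears and avk must be >= 1")
    cap = n_ears * avk
    if not 0 <= purple_grains <= cap:
        raise ValueError(f"purple_grains={purple_grains} outside [0, n_ears*avk={cap}]")
    return purple_grains / cap


def _as_frame(plots) -> pd.DataFrame:
    if isinstance(plots, pd.DataFrame):
        return plots
    if hasattr(plots, "plots"):  # FieldGrid
        return plots.plots
    return pd.DataFrame([asdict(p) if hasattr(p, "__dataclass_fields__") else dict(p) for p in plots])


def estimate_p0(plots) -> float:
    """Average actual CP over the first sampled plot row.

    The qualifying plots are those in the minimum sampled row index
    (row 0 for a full survey). For samples that skip row 0 this is the
    closest available analogue of the first-row average: the plots at the
    minimum sampled distance from the source side.
    """
    df = _as_frame(plots)
    if len(df) == 0:
        raise ValueError("no plots supplied")
    first = df[df["row"] == df["row"].min()]
    if len(first) == 0:
        raise ValueError("no qualifying first-row plots")
    return float(first["actual_cp"].mean())


def _design(df: pd.DataFrame, with_fb: bool, with_intercept: bool) -> np.ndarray:
    cols = []
    if with_intercept:
        cols.append(np.ones(len(df)))
    if with_fb:
        cols.append(df["fb_m"].to_numpy(float))
    cols.append(df["d_m"].to_numpy(float))
    return np.column_stack(cols)


def fit_dispersal(
    plots,
    method: str = "log_ols",
    p0_mode: str = "free",
    zero_policy: str = "drop",
    floor: float | None = None,
    fix_a: float | None = None,
) -> DispersalFit:
    """Fit ``CP = p0 * 10**(a*FB + b*D)`` to plot records.

    Parameters
    ----------
    plots
        FieldGrid, plot DataFrame, or iterable of records with at least
        ``row, d_m, fb_m, n_ears, avk, actual_cp`` fields.
    method
        ``"log_ols"`` — least squares on log10 CP (default);
        ``"nls"`` — nonlinear least squares on the raw CP scale;
        ``"glm"`` — Poisson regression of grain counts with log link and
        ``log(n_ears*avk)`` offset (count-scale likelihood; robust to the
        detection limit).
    p0_mode
        ``"free"`` estimates the intercept; ``"fixed"`` pins it at the
        first-sampled-row average CP (the model's data-summary reading).
        Ignored by ``"glm"`` (always free).
    zero_policy
        ``"drop"`` excludes below-detection plots from log/raw fits;
        ``"floor"`` substitutes ``floor`` (default half a detectable
        kernel, 1/(2*n_ears*avk)) for them. GLM uses the raw counts and
        ignores this.
    fix_a
        Pin the border coefficient at this value (e.g. from an external
        fit) instead of estimating it.
    """
    df = _as_frame(plots)
    if len(df) == 0:
        raise ValueError("no plots supplied")
    if df["d_m"].nunique() < 2:
        raise ValueError("need >= 2 distinct distances D to fit the distance coefficient")
    if method not in ("log_ols", "nls", "glm"):
        raise ValueError(f"unknown fit method {method!r}")
    if zero_policy not in ("drop", "floor"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    cp = df["actual_cp"].to_numpy(float)
    if np.all(cp == 0):
        raise ValueError("all plot CP rates are zero: no dispersal signal to fit")

    p0_first = estimate_p0(df)
    fb = df["fb_m"].to_numpy(float)
    fb_varies = np.unique(fb).size > 1
    estimate_a = fb_varies and fix_a is None
    a_fixed = not estimate_a

    kernels = (df["n_ears"] * df["avk"]).to_numpy(float)
    default_floor = 1.0 / (2.0 * kernels)
    floor_vec = np.full(len(df), floor) if floor is not None else default_floor
    fit_floor = float(floor) if floor is not None else float(np.median(default_floor))
    n_zero = int(np.sum(cp < floor_vec))

    if method == "glm":
        fit_a, fit_b, fit_p0 = _fit_glm(df, estimate_a, fix_a, kernels)
        n_used = len(df)
    else:
        if zero_policy == "drop":
            keep = cp >= floor_vec if method == "log_ols" else np.ones(len(df), bool)
            # raw-scale NLS keeps zeros: they are informative there
            sub = df[keep]
            y_cp = cp[keep] if method == "log_ols" else cp
        else:
            sub = df
            y_cp = np.maximum(cp, floor_vec)
        if method == "log_ols":
            n_params = 1 + estimate_a + (p0_mode == "free")
            if len(sub) < n_params:
                raise ValueError("fewer above-floor plots than model parameters")
            if sub["d_m"].nunique() < 2:
                raise ValueError("above-floor plots span < 2 distances; cannot fit b")
            fit_a, fit_b, fit_p0 = _fit_log_ols(sub, y_cp, p0_mode, p0_first, estimate_a, fix_a)
            n_used = len(sub)
        else:
            fit_a, fit_b, fit_p0 = _fit_nls(df, y_cp, p0_mode, p0_first, estimate_a, fix_a)
            n_used = len(df)

    if fix_a is not None:
        fit_a = float(fix_a)
    return DispersalFit(
        p0=float(fit_p0),
        a=float(fit_a),
        b=float(fit_b),
        n_plots_used=int(n_used),
        fit_floor=fit_floor,
        a_fixed=a_fixed,
        p0_mode=("free" if method == "glm" else p0_mode),
        method=method,
        zero_policy=zero_policy,
        p0_first_row=float(p0_first),
        n_zero_cp=n_zero,
    )


def _fit_log_ols(sub, y_cp, p0_mode, p0_first, estimate_a, fix_a):
    y = np.log10(y_cp)
    if fix_a is not None:
        y = y - fix_a * sub["fb_m"].to_numpy(float)
    free = p0_mode == "free"
    X = _design(sub, with_fb=estimate_a, with_intercept=free)
    if not free:
        if p0_first <= 0:
            raise ValueError("first-row average CP is zero; cannot fix p0 on the log scale")
        y = y - np.log10(p0_first)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: FB and D are collinear in these plots")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    i = 0
    if free:
        p0_hat = 10.0 ** beta[0]
        i = 1
    else:
        p0_hat = p0_first
    a_hat = beta[i] if estimate_a else 0.0
    b_hat = beta[i + 1] if estimate_a else beta[i]
    return a_hat, b_hat, p0_hat


def _fit_nls(df, y_cp, p0_mode, p0_first, estimate_a, fix_a):
    from scipy.optimize import least_squares

    fb = df["fb_m"].to_numpy(float)
    d = df["d_m"].to_numpy(float)
    if fix_a is not None:
        offset = fix_a * fb
    else:
        offset = np.zeros_like(fb)
    free = p0_mode == "free"

    # start from a rough log-scale fit on detected plots
    det = y_cp > 0
    try:
        a0, b0, p00 = _fit_log_ols(df[det], y_cp[det], "free", p0_first, estimate_a, fix_a)
    except (ValueError, np.linalg.LinAlgError):
        a0, b0, p00 = 0.0, -0.1, max(p0_first, 1e-6)
    theta0 = [np.log10(max(p00, 1e-12))] if free else []
    if estimate_a:
        theta0.append(a0)
    theta0.append(b0)

    def resid(theta):
        i = 0
        if free:
            logp0 = theta[0]
            i = 1
        else:
            logp0 = np.log10(max(p0_first, 1e-300))
        a = theta[i] if estimate_a else 0.0
        b = theta[i + 1] if estimate_a else theta[i]
        pred = 10.0 ** (logp0 + a * fb + b * d + offset)
        return pred - y_cp

    sol = least_squares(resid, theta0, method="lm")
    theta = sol.x
    i = 0
    p0_hat = p0_first
    if free:
        p0_hat = 10.0 ** theta[0]
        i = 1
    a_hat = theta[i] if estimate_a else 0.0
    b_hat = theta[i + 1] if estimate_a else theta[i]
    return a_hat, b_hat, p0_hat


def _fit_glm(df, estimate_a, fix_a, kernels):
    import statsmodels.api as sm

    counts = df["purple_grains"].to_numpy(float)
    offset = np.log(kernels)
    if fix_a is not None:
        offset = offset + LN10 * fix_a * df["fb_m"].to_numpy(float)
    X = _design(df, with_fb=estimate_a, with_intercept=True)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: FB and D are collinear in these plots")
    # Warm-start Newton from the log-scale OLS fit: the default IRLS loop can
    # stall far from the optimum when most plots have near-zero expected counts.
    cp = df["actual_cp"].to_numpy(float)
    det = cp >= 1.0 / (2.0 * kernels)
    if df["d_m"].to_numpy(float)[det].size and np.unique(df["d_m"].to_numpy(float)[det]).size < 2:
        # all counts at one distance: the decay slope diverges to -inf
        raise ValueError("detected plots span < 2 distances; cannot fit b")
    p0_first = estimate_p0(df)
    try:
        a0, b0, p00 = _fit_log_ols(df[det], cp[det], "free", p0_first, estimate_a, fix_a)
    except (ValueError, np.linalg.LinAlgError):
        a0, b0, p00 = 0.0, -0.1, max(p0_first, 1e-6)
    start = [np.log(max(p00, 1e-12))]
    if estimate_a:
        start.append(a0 * LN10)
    start.append(b0 * LN10)
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(start_params=np.asarray(start), method="newton", maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("count-scale fit diverged (non-finite coefficients)")
    beta = res.params / LN10  # natural-log coefficients -> base-10
    p0_hat = 10.0 ** beta[0]
    a_hat = beta[1] if estimate_a else 0.0
    b_hat = beta[2] if estimate_a else beta[1]
    return a_hat, b_hat, p0_hat


def predict_cp(fit: DispersalFit, fb_m, d_m):
    """Model CP at border width(s) ``fb_m`` and distance(s) ``d_m``, clamped to [0, 1]."""
    fb = np.asarray(fb_m, float)
    d = np.asarray(d_m, float)
    pred = fit.p0 * 10.0 ** (fit.a * fb + fit.b * d)
    pred = np.minimum(pred, 1.0)
    if pred.ndim == 0:
        return float(pred)
    return pred


def predict_field(fit: DispersalFit, field) -> np.ndarray:
    """Predicted CP for every plot of a field/plot table, in table order."""
    df = _as_frame(field)
    return np.asarray(predict_cp(fit, df["fb_m"].to_numpy(float), df["d_m"].to_numpy(float)))
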