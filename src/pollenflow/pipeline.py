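"""Bootstrap comparison of sampling schemes.

The orchestration mirrors the evaluation protocol: the raw full-plots
survey is resampled with replacement B times; on every bootstrap field
each sampling scheme selects its plots, the dispersal model is fitted to
that sample, predictions are made for every plot of the field, and the
criteria (RMSE, Pearson r, relative error, field-average predicted CP
with its CI) are computed against the *raw* field's actual CP rates.
Per-scheme aggregates (means/SDs, PBCI of RMSE, CI coverage, box-plot
summaries) are recomputable exactly from the stored replicate rows.

The default bootstrap unit is the ear *within* each plot: an iid
resample across plots would destroy the distance-CP gradient that the
schemes are designed to exploit. Plot-level resampling (optionally
stratified by distance row) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import pandas as pd

from .field import FieldGrid
from .dispersal import fit_dispersal, predict_field
from .metrics import ReplicateMetrics, rmse, pearson_r, relative_error, pbci, ci_coverage, iqr_summary
from .schemes import build_scheme, SchemeLayout

__all__ = [
    "SchemeSpec",
    "PipelineConfig",
    "PipelineResult",
    "bootstrap_field",
    "run_replicate",
    "run_pipeline",
    "score_layout",
    "summarize_replicates",
    "BOOTSTRAP_MODES",
]

BOOTSTRAP_MODES = ("within_plot_ears", "iid_plots_stratified_by_distance", "iid_plots", "none")

_POSITION_COLS = ["plot_id", "row", "col", "d_m", "fb_m"]


@dataclass(frozen=True)
class SchemeSpec:
    """One scheme to evaluate: name, layout parameters, seed policy.

    ``reseed_per_replicate`` re-randomizes SYS starts / SRS draws on each
    bootstrap replicate (capturing placement variability); set it False to
    freeze one random layout across all replicates. Fixed-layout schemes
    ignore it.
    """

    name: str
    params: dict = dc_field(default_factory=dict)
    reseed_per_replicate: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full scheme-comparison run."""

    schemes: tuple
    n_boot: int = 1000
    bootstrap_mode: str = "within_plot_ears"
    root_seed: int = 0
    fit_method: str = "glm"
    p0_mode: str = "free"
    zero_policy: str = "drop"
    floor: float | None = None
    fix_a: float | None = None
    include_full_plots: bool = True
    max_failure_rate: float = 0.10

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.bootstrap_mode not in BOOTSTRAP_MODES:
            raise ValueError(f"unknown bootstrap_mode {self.bootstrap_mode!r}")
        specs = tuple(
            s if isinstance(s, SchemeSpec) else SchemeSpec(s[0], dict(s[1]) if len(s) > 1 else {})
            for s in self.schemes
        )
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("scheme names must be unique within a run")
        object.__setattr__(self, "schemes", specs)

    def fit_kwargs(self) -> dict:
        return {
            "method": self.fit_method, "p0_mode": self.p0_mode,
            "zero_policy": self.zero_policy, "floor": self.floor, "fix_a": self.fix_a,
        }


@dataclass
class PipelineResult:
    """Replicate-level rows plus per-scheme aggregates."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    truth: float
    config: PipelineConfig


def _resample_within_plot(grains: float, n_ears: int, avk: int, rng) -> float:
    """Bootstrap a plot total by resampling its (imputed) ears with replacement.

    Per-ear counts are not stored in the plot table, so ears are imputed
    by an equal-probability multinomial split of the plot total before
    resampling; totals are capped at plot capacity.
    """
    total = int(round(grains))
    if total == 0 or n_ears == 1:
        return float(total)
    ears = rng.multinomial(total, np.full(n_ears, 1.0 / n_ears))
    picks = rng.integers(0, n_ears, size=n_ears)
    return float(min(ears[picks].sum(), n_ears * avk))


def bootstrap_field(field: FieldGrid, mode: str = "within_plot_ears", seed=None) -> FieldGrid:
    """One bootstrap resample of a full-plots survey; grid shape preserved."""
    if mode not in BOOTSTRAP_MODES:
        raise ValueError(f"unknown bootstrap_mode {mode!r}")
    if mode == "none":
        return field
    rng = np.random.default_rng(seed)
    df = field.plots
    if mode == "within_plot_ears":
        grains = df["purple_grains"].to_numpy(float).copy()
        n_ears = df["n_ears"].to_numpy(int)
        avk = df["avk"].to_numpy(int)
        for i in np.flatnonzero(grains > 0):
            grains[i] = _resample_within_plot(grains[i], n_ears[i], avk[i], rng)
        out = df.assign(purple_grains=grains, actual_cp=grains / (n_ears * avk))
        return FieldGrid(field.geometry, out)

    meas_cols = [c for c in df.columns if c not in _POSITION_COLS]
    if mode == "iid_plots":
        idx = rng.integers(0, len(df), size=len(df))
    else:  # iid_plots_stratified_by_distance
        idx = np.empty(len(df), dtype=int)
        for _, grp in df.groupby("row"):
            locs = grp.index.to_numpy()
            idx[locs] = rng.choice(locs, size=len(locs), replace=True)
    out = df[_POSITION_COLS].copy()
    for c in meas_cols:
        out[c] = df[c].to_numpy()[idx]
    out["actual_cp"] = out["purple_grains"] / (out["n_ears"] * out["avk"])
    return FieldGrid(field.geometry, out)


def score_layout(raw_field: FieldGrid, sample: pd.DataFrame, fit_kwargs: dict):
    """Fit the dispersal model to ``sample`` and score it on the whole raw field.

    Returns ``(metrics_dict, fit)``; the criteria compare predictions for
    every plot with the raw field's actual CP.
    """
    fit = fit_dispersal(sample, **fit_kwargs)
    preds = predict_field(fit, raw_field)
    obs = raw_field.plots["actual_cp"].to_numpy(float)
    re_mean, re_sd = relative_error(preds, obs)
    mean_pred = float(preds.mean())
    n = preds.size
    half = 1.96 * preds.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return {
        "rmse": rmse(preds, obs),
        "r": pearson_r(preds, obs),
        "rel_err_mean": re_mean,
        "rel_err_sd": re_sd,
        "mean_pred_cp": mean_pred,
        "ci_low": mean_pred - half,
        "ci_high": mean_pred + half,
    }, fit


def run_replicate(
    raw_field: FieldGrid,
    boot_field: FieldGrid,
    layout: SchemeLayout,
    fit_kwargs: dict,
    replicate_index: int = 0,
) -> ReplicateMetrics:
    """Place a layout on a bootstrap field, fit, and score against the raw field."""
    sample = boot_field.subset(layout.positions)
    try:
        scores, _ = score_layout(raw_field, sample, fit_kwargs)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return ReplicateMetrics(
            scheme_name=layout.scheme_name, replicate_index=replicate_index,
            n_sample=layout.n, failed=True, failure=str(exc),
        )
    return ReplicateMetrics(
        scheme_name=layout.scheme_name, replicate_index=replicate_index,
        n_sample=layout.n, **scores,
    )


def _scheme_seed(root_seed: int, scheme_idx: int, replicate: int | None):
    entropy = [root_seed, 202, scheme_idx]
    if replicate is not None:
        entropy.append(replicate)
    return np.random.SeedSequence(entropy)


def run_pipeline(field: FieldGrid, config: PipelineConfig) -> PipelineResult:
    """Run the full B-replicate comparison for every configured scheme.

    Deterministic: a pure function of (field, config); every replicate's
    bootstrap draw and scheme randomness derives from ``root_seed``. One
    bootstrap field per replicate is shared by all schemes (the protocol
    resamples the survey once, then applies each scheme to it). The full
    plots survey is included as the reference scheme unless disabled.
    """
    specs = list(config.schemes)
    if config.include_full_plots and not any(s.name == "full_plots" for s in specs):
        specs.insert(0, SchemeSpec("full_plots"))
    fit_kwargs = config.fit_kwargs()
    truth = field.mean_actual_cp

    fixed_layouts: dict[str, SchemeLayout] = {}
    for k, spec in enumerate(specs):
        if spec.name not in ("SYS", "SRS"):
            fixed_layouts[spec.name] = build_scheme(spec.name, field.geometry, spec.params)
        elif not spec.reseed_per_replicate:
            fixed_layouts[spec.name] = build_scheme(
                spec.name, field.geometry, spec.params, seed=_scheme_seed(config.root_seed, k, None)
            )

    rows = []
    for i in range(config.n_boot):
        boot = bootstrap_field(
            field, config.bootstrap_mode, seed=np.random.SeedSequence([config.root_seed, 101, i])
        )
        for k, spec in enumerate(specs):
            layout = fixed_layouts.get(spec.name)
            if layout is None:
                layout = build_scheme(
                    spec.name, field.geometry, spec.params,
                    seed=_scheme_seed(config.root_seed, k, i),
                )
            rows.append(run_replicate(field, boot, layout, fit_kwargs, replicate_index=i))

    replicates = pd.DataFrame([asdict(r) for r in rows])
    for spec in specs:
        sub = replicates[replicates["scheme_name"] == spec.name]
        fail_rate = sub["failed"].mean()
        if fail_rate > config.max_failure_rate:
            raise RuntimeError(
                f"scheme {spec.name}: {sub['failed'].sum()} of {len(sub)} replicates "
                f"failed to fit ({100 * fail_rate:.1f}% > "
                f"{100 * config.max_failure_rate:.0f}% allowed); "
                "check the scheme's coverage of detectable plots"
            )
    summary = summarize_replicates(replicates, truth)
    order = {s.name: j for j, s in enumerate(specs)}
    summary = summary.sort_values("scheme", key=lambda s: s.map(order)).reset_index(drop=True)
    return PipelineResult(replicates=replicates, summary=summary, truth=truth, config=config)


def summarize_replicates(replicates: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Per-scheme aggregation of replicate rows.

    RMSE and relative error are summarized as mean ± SD across replicates
    (the relative-error SD is the spread of the per-replicate means); the
    PBCI is of the replicate RMSEs; coverage counts replicate CIs
    containing ``truth``; the box-plot columns summarize the replicate
    field-average predicted CP.
    """
    out = []
    for scheme, grp in replicates.groupby("scheme_name", sort=False):
        ok = grp[~grp["failed"]]
        row = {
            "scheme": scheme,
            "n": int(grp["n_sample"].mode().iat[0]) if len(grp) else 0,
            "n_boot": len(grp),
            "n_failed": int(grp["failed"].sum()),
        }
        if len(ok) == 0:
            out.append(row)
            continue
        r_ = ok["rmse"].to_numpy(float)
        row["rmse_mean"] = float(np.mean(r_))
        row["rmse_sd"] = float(np.std(r_, ddof=1)) if len(r_) > 1 else 0.0
        if len(r_) >= 2:
            row["rmse_pbci_low"], row["rmse_pbci_high"] = pbci(r_)
        else:
            row["rmse_pbci_low"] = row["rmse_pbci_high"] = float(r_[0])
        row["r_mean"] = float(ok["r"].mean())
        row["rel_err_mean"] = float(ok["rel_err_mean"].mean())
        row["rel_err_sd"] = (
            float(ok["rel_err_mean"].std(ddof=1)) if len(ok) > 1 else 0.0
        )
        row["coverage_pct"] = ci_coverage(grp.to_dict("records"), truth)
        box = iqr_summary(ok["mean_pred_cp"].to_numpy(float))
        row["mean_pred_q1"] = box.q1
        row["mean_pred_median"] = box.median
        row["mean_pred_q3"] = box.q3
        row["iqr"] = box.iqr
        out.append(row)
    return pd.DataFrame(out)
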