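"""Synthetic full-plots maize field surveys.

A pollen-recipient field is modelled as a rectangular grid of sampling
plots. Row 0 abuts the pollen-source side; each column strip may be
separated from the source by an unplanted field border (isolation strip)
of width FB. The cross-pollination (CP) rate of a plot at distance D from
the source-field edge follows the log-linear dispersal model

    CP = p0 * 10**(a*FB + b*D),

truncated to [0, 1]. D is measured from the edge of the pollen-source
field to the near edge of the plot, so a plot in row r of a strip with
border width FB sits at D = FB + r*plot_depth. The observation layer
scatters purple-grain counts on white ears: each plot contributes
``n_ears`` ears of ``avk`` kernels each, and every kernel is independently
cross-pollinated with probability CP (binomial mode) or with an
ear-level random effect (beta-binomial mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FieldGeometry",
    "GeneratorConfig",
    "FieldGrid",
    "generate_field",
    "preset",
    "true_cp_grid",
    "plant_density_per_ha",
    "with_two_strips",
    "PRESET_NAMES",
]

PRESET_NAMES = ("2009-1", "2009-2", "2010-1")


@dataclass(frozen=True)
class FieldGeometry:
    """Rectangular plot grid plus border layout.

    Parameters
    ----------
    n_rows, n_cols
        Grid size; rows run along the distance axis (row 0 nearest the
        pollen source).
    plot_depth_m, plot_width_m
        Plot extent along and across the distance axis, in metres.
    border_segments
        ``[((col_start, col_stop), fb_m), ...]`` assigning a field-border
        (isolation) width to each half-open column range. The ranges must
        partition ``range(n_cols)`` exactly once.
    plants_per_plot
        Plants (hence first ears) per plot.
    avk
        Average kernels per ear.
    """

    n_rows: int
    n_cols: int
    plot_depth_m: float
    plot_width_m: float
    border_segments: tuple = (((0, None), 0.0),)
    plants_per_plot: int = 10
    avk: int = 400

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.plot_depth_m <= 0 or self.plot_width_m <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.plants_per_plot < 1 or self.avk < 1:
            raise ValueError("plants_per_plot and avk must be >= 1")
        segs = []
        for (start, stop), fb in self.border_segments:
            stop = self.n_cols if stop is None else stop
            if fb < 0:
                raise ValueError("border width FB must be >= 0")
            segs.append(((int(start), int(stop)), float(fb)))
        object.__setattr__(self, "border_segments", tuple(segs))
        covered = np.zeros(self.n_cols, dtype=int)
        for (start, stop), _ in self.border_segments:
            if not (0 <= start < stop <= self.n_cols):
                raise ValueError(f"border segment ({start}, {stop}) outside column range")
            covered[start:stop] += 1
        if not np.all(covered == 1):
            raise ValueError("border_segments must partition the columns exactly once")

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_cols

    def fb_by_col(self) -> np.ndarray:
        """Border width (m) for each column."""
        fb = np.empty(self.n_cols)
        for (start, stop), width in self.border_segments:
            fb[start:stop] = width
        return fb

    def fb_for(self, col: int) -> float:
        return float(self.fb_by_col()[col])

    def d_for(self, row: int, col: int) -> float:
        """Distance (m) from the source-field edge to the plot's near edge."""
        return self.fb_for(col) + row * self.plot_depth_m

    def grid_frame(self) -> pd.DataFrame:
        """Row-major table of positions with derived distances."""
        rows, cols = np.divmod(np.arange(self.n_plots), self.n_cols)
        fb = self.fb_by_col()[cols]
        return pd.DataFrame(
            {
                "plot_id": [f"r{r}c{c}" for r, c in zip(rows, cols)],
                "row": rows,
                "col": cols,
                "d_m": fb + rows * self.plot_depth_m,
                "fb_m": fb,
            }
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating mechanism for a synthetic full-plots survey.

    ``p0`` is the CP rate at D=0, FB=0; ``a`` (per m) scales the border
    effect and ``b`` (per m) the distance decay. ``noise_model`` is one of
    ``"binomial"`` (independent kernels), ``"beta_binomial"`` (ear-level
    random effect with intraclass correlation ``overdispersion_rho``) or
    ``"none"`` (idealized noise-free survey: fractional grain totals equal
    to their expectation, so the plot CP equals the true rate exactly).
    """

    geometry: FieldGeometry
    p0: float = 0.3
    a: float = 0.6261
    b: float = -0.6784
    noise_model: str = "binomial"
    overdispersion_rho: float = 0.0
    seed: int = 0
    notes: str = ""

    def __post_init__(self):
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.noise_model not in ("binomial", "beta_binomial", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")


class FieldGrid:
    """A full-plots survey: geometry plus one record per plot.

    ``plots`` is a row-major DataFrame with columns
    ``plot_id,row,col,d_m,fb_m,n_ears,purple_grains,avk,actual_cp`` and,
    for synthetic fields, ``true_p``.
    """

    def __init__(self, geometry: FieldGeometry, plots: pd.DataFrame):
        required = {"plot_id", "row", "col", "d_m", "fb_m", "n_ears", "purple_grains", "avk"}
        missing = required - set(plots.columns)
        if missing:
            raise ValueError(f"plot table missing columns: {sorted(missing)}")
        if plots.duplicated(["row", "col"]).any():
            dupes = plots[plots.duplicated(["row", "col"])][["row", "col"]].values[:3]
            raise ValueError(f"duplicate (row, col) positions, e.g. {dupes.tolist()}")
        plots = plots.reset_index(drop=True)
        cap = plots["n_ears"] * plots["avk"]
        bad = (plots["purple_grains"] < 0) | (plots["purple_grains"] > cap)
        if bad.any():
            plot = plots.loc[bad.idxmax()]
            raise ValueError(
                f"plot {plot['plot_id']}: purple_grains={plot['purple_grains']} "
                f"outside [0, n_ears*avk={plot['n_ears'] * plot['avk']}]"
            )
        if "actual_cp" not in plots.columns:
            plots = plots.assign(actual_cp=plots["purple_grains"] / cap)
        self.geometry = geometry
        self.plots = plots

    def __len__(self) -> int:
        return len(self.plots)

    @property
    def mean_actual_cp(self) -> float:
        """Field-average actual CP rate over all plots."""
        return float(self.plots["actual_cp"].mean())

    def subset(self, positions) -> pd.DataFrame:
        """Plot records at the given ``(row, col)`` positions, in order."""
        idx = self.plots.set_index(["row", "col"]).index
        lookup = pd.Series(np.arange(len(self.plots)), index=idx)
        try:
            locs = lookup.loc[list(map(tuple, positions))].to_numpy()
        except KeyError as exc:
            raise KeyError(f"position not on the grid: {exc}") from exc
        return self.plots.iloc[locs].reset_index(drop=True)

    def all_positions(self):
        return list(zip(self.plots["row"].tolist(), self.plots["col"].tolist()))


def true_cp_grid(config: GeneratorConfig) -> np.ndarray:
    """True per-plot CP rates (n_rows × n_cols), truncated to [0, 1]."""
    geo = config.geometry
    fb = geo.fb_by_col()[None, :]
    d = fb + np.arange(geo.n_rows)[:, None] * geo.plot_depth_m
    p = config.p0 * 10.0 ** (config.a * fb + config.b * d)
    return np.minimum(p, 1.0)


def generate_field(config: GeneratorConfig) -> FieldGrid:
    """Draw one synthetic full-plots survey.

    Deterministic under a fixed ``(config, seed)``: plot draws are taken
    from a single seeded stream in row-major plot order, so every sampling
    scheme applied to the result sees the identical field.
    """
    geo = config.geometry
    fb = geo.fb_by_col()[None, :]
    d = fb + np.arange(geo.n_rows)[:, None] * geo.plot_depth_m
    p_raw = config.p0 * 10.0 ** (config.a * fb + config.b * d)
    n_trunc = int(np.sum(p_raw > 1.0))
    if n_trunc:
        warnings.warn(
            f"{n_trunc} plot(s) have model CP > 1 and were truncated to 1; "
            "check (p0, a, b) against the field geometry",
            UserWarning,
            stacklevel=2,
        )
    p = np.minimum(p_raw, 1.0)

    n_ears = geo.plants_per_plot
    kernels = n_ears * geo.avk
    rng = np.random.default_rng(config.seed)
    if config.noise_model == "none":
        grains = p * kernels
    elif config.noise_model == "binomial":
        grains = rng.binomial(kernels, p).astype(float)
    else:  # beta_binomial
        rho = config.overdispersion_rho
        if rho == 0.0:
            grains = rng.binomial(kernels, p).astype(float)
        else:
            s = (1.0 - rho) / rho  # Beta concentration giving ICC rho
            pe = np.empty((geo.n_rows, geo.n_cols, n_ears))
            interior = (p > 0) & (p < 1)
            pe[...] = p[..., None]
            if interior.any():
                alpha = (p[interior] * s)[:, None] * np.ones(n_ears)
                beta = ((1.0 - p[interior]) * s)[:, None] * np.ones(n_ears)
                pe[interior, :] = rng.beta(alpha, beta)
            grains = rng.binomial(geo.avk, pe).sum(axis=-1).astype(float)

    table = geo.grid_frame()
    flat_p = p.reshape(-1)
    flat_grains = grains.reshape(-1)
    # idealized mode: report the exact rate, immune to p*k/k rounding
    actual_cp = flat_p if config.noise_model == "none" else flat_grains / kernels
    table = table.assign(
        n_ears=n_ears,
        purple_grains=flat_grains,
        avk=geo.avk,
        actual_cp=actual_cp,
        true_p=flat_p,
    )
    return FieldGrid(geo, table)


def plant_density_per_ha(row_spacing_m: float = 0.75, plant_spacing_m: float = 0.25) -> float:
    """Plants per hectare implied by row and within-row plant spacing."""
    return 10_000.0 / (row_spacing_m * plant_spacing_m)


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Generator configuration emulating one of the three field seasons.

    ``"2009-1"``: 41 rows × 40 cols = 1640 plots of 2.5 × 0.75 m², no
    border (FB = 0 everywhere). ``"2009-2"``: 78 × 40 = 3120 plots of
    1.25 × 0.75 m², right half of the columns behind a 6.75 m border.
    ``"2010-1"``: 91 × 40 = 3640 plots of 1.25 × 0.75 m², right half
    behind a 7.5 m border.

    The row × column factorizations and the half-and-half strip split are
    assumptions (only total plot counts, plot sizes and border widths are
    fixed by the survey designs); both are overridable by replacing the
    geometry. Defaults: a = 0.6261 /m, b = −0.6784 /m, p0 = 0.3,
    avk = 400, one first ear per plant, binomial kernel noise.
    """
    if name == "2009-1":
        geo = FieldGeometry(
            n_rows=41, n_cols=40, plot_depth_m=2.5, plot_width_m=0.75,
            border_segments=(((0, None), 0.0),), plants_per_plot=10, avk=400,
        )
        notes = "41x40 factorization of the 1640 plots assumed; no border strip."
    elif name == "2009-2":
        geo = FieldGeometry(
            n_rows=78, n_cols=40, plot_depth_m=1.25, plot_width_m=0.75,
            border_segments=(((0, 20), 0.0), ((20, None), 6.75)),
            plants_per_plot=5, avk=400,
        )
        notes = "78x40 factorization of the 3120 plots and half-width 6.75 m strip assumed."
    elif name == "2010-1":
        geo = FieldGeometry(
            n_rows=91, n_cols=40, plot_depth_m=1.25, plot_width_m=0.75,
            border_segments=(((0, 20), 0.0), ((20, None), 7.5)),
            plants_per_plot=5, avk=400,
        )
        notes = "91x40 factorization of the 3640 plots and half-width 7.5 m strip assumed."
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    return GeneratorConfig(geometry=geo, seed=seed, notes=notes)


def with_two_strips(config: GeneratorConfig, fb_m: float = 6.75) -> GeneratorConfig:
    """Variant of ``config`` whose right column half sits behind a border.

    Convenience for border-effect experiments on an otherwise borderless
    geometry (e.g. the 2009-1 grid).
    """
    geo = config.geometry
    half = geo.n_cols // 2
    geo2 = replace(geo, border_segments=(((0, half), 0.0), ((half, None), float(fb_m))))
    return replace(config, geometry=geo2)
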