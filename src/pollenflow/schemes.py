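"""Sampling-scheme layouts on a plot grid.

Nine layouts are supported: straight transects from the pollen-source
edge (T_two, T_four, T_six), a cross transect (T_cross), a V-shaped
transect (T_V), the Joaquima Messeguer stratified layouts for low and
high expected pollen flow (JM_L, JM_H), systematic random sampling on a
lattice with random start (SYS), and simple random sampling (SRS). All
layouts are parameterized rules on the grid geometry; the fixed-layout
schemes are deterministic functions of geometry + parameters.

Rounding convention: requested metric positions map to the nearest grid
cell, ties resolved to the smaller index — except along V-transect arms,
where ties resolve toward the arms' meeting point (which keeps the two
arms symmetric about the field's centre line).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import FieldGeometry

__all__ = [
    "SchemeLayout",
    "layout_transects",
    "layout_cross",
    "layout_v",
    "layout_jm",
    "layout_sys",
    "layout_srs",
    "layout_full",
    "build_scheme",
    "default_scheme_specs",
    "SCHEME_NAMES",
    "DEFAULT_DISTANCES_M",
]

log = logging.getLogger(__name__)

SCHEME_NAMES = ("T_two", "T_four", "T_six", "T_cross", "T_V", "JM_L", "JM_H", "SYS", "SRS")

# Distance ladder (m) for source-edge transects, densified near the source
# where CP changes fastest.
DEFAULT_DISTANCES_M = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 30.0)


def _half_down(x) -> int:
    """Round to nearest integer, ties to the smaller value."""
    return int(np.ceil(np.asarray(x, float) - 0.5))


def _round_toward(x: float, direction: float) -> int:
    """Round to nearest, ties in the sign of ``direction`` (0 -> down)."""
    if direction > 0:
        return int(np.floor(x + 0.5))
    return _half_down(x)


@dataclass(frozen=True)
class SchemeLayout:
    """A named scheme with its ordered, duplicate-free plot positions."""

    scheme_name: str
    positions: tuple
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        pos = tuple((int(r), int(c)) for r, c in self.positions)
        if len(set(pos)) != len(pos):
            raise ValueError(f"{self.scheme_name}: duplicate positions")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return len(self.positions)

    def validate_on(self, geometry: FieldGeometry) -> None:
        for r, c in self.positions:
            if not (0 <= r < geometry.n_rows and 0 <= c < geometry.n_cols):
                raise ValueError(
                    f"{self.scheme_name}: position ({r}, {c}) outside "
                    f"{geometry.n_rows}x{geometry.n_cols} grid"
                )


def _dedupe(seq):
    seen, out = set(), []
    for p in seq:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def _rows_for_distances(geometry: FieldGeometry, distances_m) -> list[int]:
    """Grid row nearest each requested edge distance (near-edge D = row*depth)."""
    rows = []
    for dist in distances_m:
        r = _half_down(dist / geometry.plot_depth_m)
        rows.append(min(max(r, 0), geometry.n_rows - 1))
    if len(set(rows)) < len(rows):
        log.info("requested distances collapse onto %d distinct rows", len(set(rows)))
    return _dedupe(rows)


def layout_transects(
    geometry: FieldGeometry, k_transects: int, sample_distances_m=DEFAULT_DISTANCES_M
) -> SchemeLayout:
    """``k`` evenly spaced source-edge transects sampled at given distances.

    Transect columns sit at round((j + 0.5) * n_cols / k), j = 0..k-1; on
    each, one plot at the row whose near edge is closest to each requested
    distance from the source-side field edge.
    """
    if not 1 <= k_transects <= geometry.n_cols:
        raise ValueError("k_transects must be between 1 and n_cols")
    cols = _dedupe(
        min(max(_half_down((j + 0.5) * geometry.n_cols / k_transects), 0), geometry.n_cols - 1)
        for j in range(k_transects)
    )
    rows = _rows_for_distances(geometry, sample_distances_m)
    positions = [(r, c) for c in cols for r in rows]
    name = {2: "T_two", 4: "T_four", 6: "T_six"}.get(k_transects, f"T_{k_transects}")
    return SchemeLayout(name, tuple(positions), {
        "k_transects": k_transects, "sample_distances_m": tuple(sample_distances_m),
        "transect_cols": tuple(cols),
    })


def layout_cross(
    geometry: FieldGeometry,
    sample_distances_m=DEFAULT_DISTANCES_M,
    lateral_col_step: int = 2,
) -> SchemeLayout:
    """One longitudinal centre-column transect plus one lateral centre-row transect.

    The longitudinal arm is sampled at the requested distances; the
    lateral arm at every ``lateral_col_step``-th column. Centre lines use
    the lower median for even extents; the intersection counts once.
    """
    if lateral_col_step < 1:
        raise ValueError("lateral_col_step must be >= 1")
    center_col = (geometry.n_cols - 1) // 2
    center_row = (geometry.n_rows - 1) // 2
    rows = _rows_for_distances(geometry, sample_distances_m)
    positions = [(r, center_col) for r in rows]
    positions += [(center_row, c) for c in range(0, geometry.n_cols, lateral_col_step)]
    return SchemeLayout("T_cross", tuple(_dedupe(positions)), {
        "sample_distances_m": tuple(sample_distances_m),
        "lateral_col_step": lateral_col_step,
        "center_row": center_row, "center_col": center_col,
    })


def layout_v(geometry: FieldGeometry, n_per_arm: int = 10) -> SchemeLayout:
    """Two straight arms from the source-side corners to the far-side centre.

    Each arm runs from (0, 0) resp. (0, n_cols-1) to
    (n_rows-1, lower-median column), discretized to ``n_per_arm`` plots by
    rounding evenly spaced points to grid cells (ties toward the meeting
    point); duplicates merge.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if geometry.n_rows < 2:
        raise ValueError("V-transect degenerates on a single-row grid")
    end = (geometry.n_rows - 1, (geometry.n_cols - 1) // 2)
    positions = []
    for start_col in (0, geometry.n_cols - 1):
        start = (0, start_col)
        for j in range(n_per_arm):
            t = j / (n_per_arm - 1)
            r = _round_toward(start[0] + t * (end[0] - start[0]), end[0] - start[0])
            c = _round_toward(start[1] + t * (end[1] - start[1]), end[1] - start[1])
            positions.append((r, c))
    return SchemeLayout("T_V", tuple(_dedupe(positions)), {"n_per_arm": n_per_arm})


def _edge_offsets(offsets_m, spacing_m, extent: int, what: str) -> list[int]:
    """Cell indices nearest the given metric offsets from both opposite edges."""
    idx = []
    for off in offsets_m:
        k = _half_down(off / spacing_m)
        if k > extent - 1:
            warnings.warn(
                f"JM offset {off} m exceeds the field's {what} extent; "
                "clamped to the farthest cell",
                UserWarning, stacklevel=3,
            )
            k = extent - 1
        idx.append(k)               # from the near/left edge
        idx.append(extent - 1 - k)  # from the far/right edge
    return idx


def layout_jm(
    geometry: FieldGeometry,
    variant: str = "low",
    near_offsets_m=(0.0, 3.0),
    high_offset_m: float = 10.0,
) -> SchemeLayout:
    """Joaquima Messeguer stratified layout (low / high expected flow).

    Four transects trisect the field: two columns at the trisection points
    of the cross-field side and two rows at the trisection points of the
    distance side. Plots sit on every transect at the cells nearest 0 m
    and 3 m from each field edge the transect meets, plus the four
    transect junctions. The high-flow variant adds the cells nearest 10 m
    from each edge, so JM_L is a subset of JM_H by construction.
    """
    if variant not in ("low", "high"):
        raise ValueError(f"unknown JM variant {variant!r}")
    if geometry.n_rows < 3 or geometry.n_cols < 3:
        raise ValueError("JM layout needs a field of at least 3x3 plots")
    offsets = tuple(near_offsets_m) + ((high_offset_m,) if variant == "high" else ())
    tri_cols = _dedupe(
        [_half_down(geometry.n_cols / 3), _half_down(2 * geometry.n_cols / 3)]
    )
    tri_rows = _dedupe(
        [_half_down(geometry.n_rows / 3), _half_down(2 * geometry.n_rows / 3)]
    )
    col_transect_rows = _dedupe(
        _edge_offsets(offsets, geometry.plot_depth_m, geometry.n_rows, "depth")
    )
    row_transect_cols = _dedupe(
        _edge_offsets(offsets, geometry.plot_width_m, geometry.n_cols, "width")
    )
    positions = [(r, c) for c in tri_cols for r in col_transect_rows]
    positions += [(r, c) for r in tri_rows for c in row_transect_cols]
    positions += [(r, c) for r in tri_rows for c in tri_cols]  # junctions
    name = "JM_L" if variant == "low" else "JM_H"
    return SchemeLayout(name, tuple(_dedupe(positions)), {
        "variant": variant, "near_offsets_m": tuple(near_offsets_m),
        "high_offset_m": high_offset_m,
        "trisection_rows": tuple(tri_rows), "trisection_cols": tuple(tri_cols),
    })


def layout_sys(
    geometry: FieldGeometry,
    row_step: int,
    col_step: int,
    seed=None,
    start: tuple | None = None,
) -> SchemeLayout:
    """Systematic sampling on a lattice with a (seeded) random start.

    The start cell is drawn uniformly from [0, row_step) x [0, col_step)
    unless ``start`` is given explicitly.
    """
    if row_step < 1 or col_step < 1:
        raise ValueError("lattice steps must be >= 1")
    if start is None:
        rng = np.random.default_rng(seed)
        start = (int(rng.integers(0, row_step)), int(rng.integers(0, col_step)))
    r0, c0 = start
    positions = [
        (r, c)
        for r in range(r0, geometry.n_rows, row_step)
        for c in range(c0, geometry.n_cols, col_step)
    ]
    return SchemeLayout("SYS", tuple(positions), {
        "row_step": row_step, "col_step": col_step, "start": (int(r0), int(c0)),
    })


def layout_srs(geometry: FieldGeometry, n: int, seed=None) -> SchemeLayout:
    """Simple random sample of ``n`` distinct plots, uniform without replacement."""
    total = geometry.n_plots
    if not 1 <= n <= total:
        raise ValueError(f"SRS sample size {n} outside [1, {total}]")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n, replace=False)
    positions = [(int(i // geometry.n_cols), int(i % geometry.n_cols)) for i in flat]
    return SchemeLayout("SRS", tuple(positions), {"n": n})


def layout_full(geometry: FieldGeometry) -> SchemeLayout:
    """The full plots survey: every plot, row-major."""
    positions = [(r, c) for r in range(geometry.n_rows) for c in range(geometry.n_cols)]
    return SchemeLayout("full_plots", tuple(positions), {})


_BUILDERS = {
    "T_two": lambda geo, p, seed: layout_transects(geo, 2, p.get("sample_distances_m", DEFAULT_DISTANCES_M)),
    "T_four": lambda geo, p, seed: layout_transects(geo, 4, p.get("sample_distances_m", DEFAULT_DISTANCES_M)),
    "T_six": lambda geo, p, seed: layout_transects(geo, 6, p.get("sample_distances_m", DEFAULT_DISTANCES_M)),
    "T_cross": lambda geo, p, seed: layout_cross(
        geo, p.get("sample_distances_m", DEFAULT_DISTANCES_M), p.get("lateral_col_step", 2)
    ),
    "T_V": lambda geo, p, seed: layout_v(geo, p.get("n_per_arm", 10)),
    "JM_L": lambda geo, p, seed: layout_jm(geo, "low"),
    "JM_H": lambda geo, p, seed: layout_jm(geo, "high"),
    "SYS": lambda geo, p, seed: layout_sys(
        geo, p["row_step"], p["col_step"], seed=seed, start=p.get("start")
    ),
    "SRS": lambda geo, p, seed: layout_srs(geo, p["n"], seed=seed),
    "full_plots": lambda geo, p, seed: layout_full(geo),
}


def build_scheme(name: str, geometry: FieldGeometry, params: dict | None = None, seed=None) -> SchemeLayout:
    """Build a layout by scheme name; ``seed`` feeds SYS/SRS randomness."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown scheme {name!r}; expected one of {tuple(_BUILDERS)}")
    layout = _BUILDERS[name](geometry, params or {}, seed)
    layout.validate_on(geometry)
    return layout


def default_scheme_specs(preset_name: str) -> list[tuple[str, dict]]:
    """Default (scheme, params) list per field preset.

    SYS lattice steps and SRS sizes follow the survey sample sizes:
    2009-1 SYS steps (6, 7) -> 42 plots from start (0, 0), SRS n=322;
    2009-2 SYS (8, 6) -> 70, SRS n=355; 2010-1 SYS (5, 10) -> 76,
    SRS n=361.
    """
    sys_steps = {"2009-1": (6, 7), "2009-2": (8, 6), "2010-1": (5, 10)}
    srs_n = {"2009-1": 322, "2009-2": 355, "2010-1": 361}
    if preset_name not in sys_steps:
        raise ValueError(f"unknown preset {preset_name!r}")
    rs, cs = sys_steps[preset_name]
    specs = [(name, {}) for name in ("T_two", "T_four", "T_six", "T_cross", "T_V", "JM_L", "JM_H")]
    specs.append(("SYS", {"row_step": rs, "col_step": cs}))
    specs.append(("SRS", {"n": srs_n[preset_name]}))
    return specs
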