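"""Plot-table, layout and summary file formats, plus run manifests.

All files are UTF-8 CSV (comma separator, ``.`` decimal, mandatory
header) or JSON. Numeric fields round-trip at full precision: floats are
written with Python's shortest-repr formatting, so read-after-write
reproduces every value bit-for-bit; display rounding happens only in
human-readable rendering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .field import FieldGeometry, FieldGrid
from .schemes import SchemeLayout

__all__ = [
    "read_plot_table",
    "write_plot_table",
    "write_layout",
    "read_layout",
    "write_summary",
    "read_summary",
    "build_manifest",
    "write_manifest",
]

REQUIRED_COLUMNS = ["plot_id", "row", "col", "d_m", "fb_m", "n_ears", "purple_grains", "avk"]
_NUMERIC = ["row", "col", "d_m", "fb_m", "n_ears", "purple_grains", "avk"]


def _FLOAT_FMT(x) -> str:
    """Shortest decimal that round-trips the float64 exactly."""
    return repr(float(x))


def read_plot_table(path, geometry: FieldGeometry | None = None) -> FieldGrid:
    """Load a plot-table CSV into a validated FieldGrid.

    The header must contain ``plot_id,row,col,d_m,fb_m,n_ears,
    purple_grains,avk``; extra columns are preserved. ``actual_cp`` is
    (re)computed on load. If ``geometry`` is omitted, a minimal geometry
    is inferred from the grid indices and distance spacing.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad_row = int(df.index[vals.isna()][0]) + 2  # header + 1-based

            raise ValueError(f"{path.name}: non-numeric value in column {col!r} at line {bad_row}")
        df[col] = vals
    cap = df["n_ears"] * df["avk"]
    bad = (df["purple_grains"] < 0) | (df["purple_grains"] > cap)
    if bad.any():
        plot = df.loc[bad.idxmax()]
        raise ValueError(
            f"{path.name}: plot {plot['plot_id']}: purple_grains={plot['purple_grains']} "
            f"exceeds n_ears*avk={plot['n_ears'] * plot['avk']}"
        )
    df["actual_cp"] = df["purple_grains"] / cap
    if geometry is None:
        geometry = _infer_geometry(df)
    return FieldGrid(geometry, df)


def _infer_geometry(df: pd.DataFrame) -> FieldGeometry:
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    depth = 1.0
    d_net = df["d_m"] - df["fb_m"]
    multi = df[df["row"] > 0]
    if len(multi):
        depth = float((d_net[multi.index] / multi["row"]).iloc[0])
    fb_by_col = df.groupby("col")["fb_m"].first()
    segments, start = [], 0
    cols = sorted(fb_by_col.index)
    for i in range(1, len(cols) + 1):
        if i == len(cols) or fb_by_col[cols[i]] != fb_by_col[cols[start]]:
            segments.append(((cols[start], cols[i - 1] + 1), float(fb_by_col[cols[start]])))
            start = i
    return FieldGeometry(
        n_rows=n_rows, n_cols=n_cols, plot_depth_m=depth, plot_width_m=0.75,
        border_segments=tuple(segments) or (((0, None), 0.0),),
        plants_per_plot=int(df["n_ears"].iloc[0]), avk=int(df["avk"].iloc[0]),
    )


def write_plot_table(field: FieldGrid, path, include_true_p: bool = True) -> Path:
    """Write a FieldGrid to CSV (``true_p`` kept only for synthetic fields)."""
    path = Path(path)
    df = field.plots
    if not include_true_p and "true_p" in df.columns:
        df = df.drop(columns=["true_p"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_layout(layout: SchemeLayout, path) -> Path:
    """Write a layout as ``scheme,row,col`` CSV plus a JSON replay manifest."""
    path = Path(path)
    pd.DataFrame(
        {"scheme": layout.scheme_name,
         "row": [r for r, _ in layout.positions],
         "col": [c for _, c in layout.positions]}
    ).to_csv(path, index=False)
    manifest = path.with_suffix(".json")
    manifest.write_text(json.dumps(
        {"scheme": layout.scheme_name, "n": layout.n, "params": _jsonable(layout.params)},
        indent=2,
    ))
    return path


def read_layout(path) -> SchemeLayout:
    df = pd.read_csv(path)
    name = str(df["scheme"].iloc[0]) if len(df) else "unknown"
    positions = tuple(zip(df["row"].astype(int), df["col"].astype(int)))
    manifest = Path(path).with_suffix(".json")
    params = json.loads(manifest.read_text())["params"] if manifest.exists() else {}
    return SchemeLayout(name, positions, params)


SUMMARY_COLUMNS = [
    "scheme", "n", "n_boot", "n_failed", "rmse_mean", "rmse_sd",
    "rmse_pbci_low", "rmse_pbci_high", "r_mean", "rel_err_mean", "rel_err_sd",
    "coverage_pct", "mean_pred_q1", "mean_pred_median", "mean_pred_q3", "iqr",
]


def write_summary(result, out_dir, manifest: dict | None = None) -> dict:
    """Write replicates.csv, summary.csv and summary.json for a pipeline run.

    ``summary.json`` mirrors the survey-table layout (one object per
    scheme: n, RMSE mean±sd and PBCI, r, relative error mean±sd, coverage
    in % to one decimal in the rendered field, IQR summary) plus the run
    manifest reference.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.replicates.to_csv(out_dir / "replicates.csv", index=False, float_format=_FLOAT_FMT)
    summary = result.summary.reindex(columns=[c for c in SUMMARY_COLUMNS if c in result.summary.columns])
    summary.to_csv(out_dir / "summary.csv", index=False, float_format=_FLOAT_FMT)
    payload = {
        "truth_mean_actual_cp": result.truth,
        "schemes": _jsonable(summary.to_dict(orient="records")),
        "rendered": [
            {
                "scheme": row["scheme"],
                "coverage_pct": None if pd.isna(row.get("coverage_pct")) else f"{row['coverage_pct']:.1f}",
            }
            for row in summary.to_dict(orient="records")
        ],
    }
    if manifest is not None:
        payload["manifest"] = _jsonable(manifest)
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, allow_nan=True))
    return {
        "replicates": out_dir / "replicates.csv",
        "summary_csv": out_dir / "summary.csv",
        "summary_json": out_dir / "summary.json",
    }


def read_summary(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "summary.csv", float_precision="round_trip")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(config, root_seed: int, input_files=(), version: str | None = None) -> dict:
    """Replay manifest: tool version, config echo, seeds, input checksums."""
    from . import __version__

    return {
        "tool": "pollenflow",
        "version": version or __version__,
        "root_seed": int(root_seed),
        "config": _jsonable(config),
        "inputs": {str(p): file_sha256(p) for p in input_files},
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
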