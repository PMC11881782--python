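"""CSV/JSON exchange formats.

Grids travel as CSV with columns x_deg, y_deg and optionally mu_hat_db;
PMFs as a location-by-threshold matrix (one column per dB bin); structural
maps as long-format x_deg, y_deg, omega on a regular lattice. All
coordinates are field degrees, right-eye convention unless stated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TestGrid
from .observer import StructuralMap


def write_grid_csv(path, grid: TestGrid, estimates=None) -> None:
    df = pd.DataFrame({"x_deg": grid.points[:, 0], "y_deg": grid.points[:, 1]})
    if estimates is not None:
        df["mu_hat_db"] = np.asarray(estimates, dtype=float)
    df.to_csv(path, index=False)


def read_grid_csv(path, eye: str = "right") -> TestGrid:
    df = pd.read_csv(path)
    return TestGrid(df[["x_deg", "y_deg"]].to_numpy(dtype=float), eye=eye)


def write_pmfs_csv(path, pmfs: np.ndarray, thresh_domain) -> None:
    cols = [f"p_{t:g}dB" for t in np.asarray(thresh_domain, dtype=float)]
    pd.DataFrame(np.asarray(pmfs, dtype=float), columns=cols).to_csv(
        path, index_label="location")


def read_pmfs_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (pmfs, threshold_domain)."""
    df = pd.read_csv(path, index_col=0)
    domain = np.array([float(c[2:-2]) for c in df.columns])
    return df.to_numpy(dtype=float), domain


def write_structural_map_csv(path, smap: StructuralMap) -> None:
    xx, yy = np.meshgrid(smap.x, smap.y)
    pd.DataFrame({"x_deg": xx.ravel(), "y_deg": yy.ravel(),
                  "omega": smap.values.ravel()}).to_csv(path, index=False)


def read_structural_map_csv(path) -> StructuralMap:
    df = pd.read_csv(path)
    x = np.unique(df["x_deg"].to_numpy(dtype=float))
    y = np.unique(df["y_deg"].to_numpy(dtype=float))
    vals = (df.pivot(index="y_deg", columns="x_deg", values="omega")
            .sort_index().sort_index(axis=1).to_numpy(dtype=float))
    return StructuralMap(x, y, vals)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_summary_json(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2))


def runs_to_csv(path, runs) -> None:
    rows = []
    for r in runs:
        row = {"run_id": r.run_id, "seed": r.seed, "policy": r.policy,
               "n_seed": r.n_seed, "n_points": len(r.points)}
        row.update(r.metrics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
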