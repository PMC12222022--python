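"""Plain-text readers and writers for the pipeline's tabular interfaces.

Traces travel as long CSV (cell_id, t_s, dff_pct [, episode_id]) or a wide
matrix CSV; expression calls as (cell_id, gene, call); point fields as
(point_id, frame, x, y, is_guidepost, true_match_id).  Raw ROI input is
(cell_id, t_s, f_cell, f_annulus).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TraceSet


def write_traces_long(traces: TraceSet, path) -> None:
    df = traces.to_long_frame()
    n_c = len(traces.cell_ids)
    df["episode_id"] = np.tile(traces.episode_ids, n_c)
    df.to_csv(path, index=False)


def read_traces_long(path) -> TraceSet:
    df = pd.read_csv(path)
    cell_ids = list(pd.unique(df["cell_id"]))
    first = df[df["cell_id"] == cell_ids[0]]
    t = first["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV must contain at least two samples per cell")
    fs = 1.0 / float(np.median(np.diff(t)))
    episode_ids = (
        first["episode_id"].to_numpy(dtype=int)
        if "episode_id" in df.columns
        else np.zeros(t.size, dtype=int)
    )
    dff = np.empty((len(cell_ids), t.size))
    for i, cid in enumerate(cell_ids):
        sub = df[df["cell_id"] == cid]
        if len(sub) != t.size:
            raise ValueError(f"cell {cid}: trace length differs from first cell")
        dff[i] = sub["dff_pct"].to_numpy(dtype=float)
    return TraceSet(t=t, dff=dff, cell_ids=cell_ids, episode_ids=episode_ids,
                    sampling_rate=fs)


def write_traces_wide(traces: TraceSet, path) -> None:
    traces.to_wide_frame().to_csv(path)


def read_raw_roi_long(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "t_s", "f_cell", "f_annulus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw ROI CSV missing columns {sorted(missing)}")
    return df


def write_expression(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell_id", "gene", "call"} - set(df.columns)
    if missing:
        raise ValueError(f"expression CSV missing columns {sorted(missing)}")
    return df


def expression_to_calls(df: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Long expression frame -> per-cell {gene: call} mappings."""
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.cell_id, {})[row.gene] = row.call
    return out


def write_points(field, path) -> None:
    """Write a simulated FieldSet as the standard points CSV."""
    guide = set(int(i) for i in field.guidepost_idx)
    rows = []
    for frame, pts in (("ish", field.ish), ("invivo", field.invivo)):
        for i, (x, y) in enumerate(pts):
            rows.append(
                {
                    "point_id": f"{frame}_{i:04d}",
                    "frame": frame,
                    "x": x,
                    "y": y,
                    "is_guidepost": i in guide,
                    "true_match_id": i,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_points(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"point_id", "frame", "x", "y", "is_guidepost"} - set(df.columns)
    if missing:
        raise ValueError(f"points CSV missing columns {sorted(missing)}")
    return df
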