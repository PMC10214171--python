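"""Trace and results I/O.

Traces travel as wide CSV (column ``time_h`` plus one column per channel)
or long TSV (columns ``time_h``, ``channel``, ``value``), with an optional
JSON sidecar (``<stem>.json``) holding slice metadata and treatment events.
Imaging movies come in as multi-frame grayscale TIFF stacks from which
per-ROI mean-intensity traces are extracted.  Time is hours from recording
start everywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TraceSet

__all__ = ["read_traces", "write_traces", "extract_roi_traces", "FormatError"]

log = logging.getLogger("scnrhythm")


class FormatError(ValueError):
    pass


def _validate_grid(times: np.ndarray, source: str) -> np.ndarray:
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0)) + 2  # 1-based line of the offender
        raise FormatError(f"{source}: non-monotone time at data line {bad}")
    dt = float(np.median(diffs))
    if np.max(np.abs(diffs - dt)) > 0.01 * dt:
        log.warning("%s: non-uniform grid, resampling onto dt=%.4g h", source, dt)
        return np.arange(times[0], times[-1] + dt / 2, dt)
    return times


def read_traces(path: str | Path, dialect: str = "wide_csv") -> TraceSet:
    """Read one slice's recording from disk.

    Non-uniform grids are linearly resampled onto the median dt with a
    logged warning; metadata is merged from ``<stem>.json`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide_csv":
        df = pd.read_csv(path)
        if "time_h" not in df.columns:
            raise FormatError(f"{path}: missing 'time_h' column")
        times = df["time_h"].to_numpy(float)
        channels = {
            c: df[c].to_numpy(float) for c in df.columns if c != "time_h"
        }
    elif dialect == "long_tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"time_h", "channel", "value"}
        if not need.issubset(df.columns):
            raise FormatError(f"{path}: long dialect needs columns {sorted(need)}")
        wide = df.pivot(index="time_h", columns="channel", values="value")
        times = wide.index.to_numpy(float)
        channels = {str(c): wide[c].to_numpy(float) for c in wide.columns}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(np.unique(times)) != len(times):
        raise FormatError(f"{path}: duplicated time stamps")
    grid = _validate_grid(times, str(path))
    if grid is not times and len(grid) != len(times):
        channels = {k: np.interp(grid, times, v) for k, v in channels.items()}
        times = grid

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TraceSet(
        slice_id=meta.get("slice_id", path.stem),
        times=times,
        channels=channels,
        genotype=meta.get("genotype", "WT"),
        events=[tuple(e) for e in meta.get("events", [])],
        provenance=meta.get("provenance", {}),
    )


def write_traces(ts: TraceSet, path: str | Path) -> Path:
    """Write a wide CSV plus JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_h": ts.times})
    for name, v in ts.channels.items():
        df[name] = v
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            dict(
                slice_id=ts.slice_id,
                genotype=ts.genotype,
                events=[[lab, t] for lab, t in ts.events],
                provenance=ts.provenance,
            ),
            indent=2,
        )
    )
    return path


# --------------------------------------------------------------------------
# TIFF movie front-end


def _roi_mask(roi, shape) -> np.ndarray:
    """Boolean mask from a rectangle (x, y, w, h) or polygon vertex list."""
    h, w = shape
    roi = np.asarray(roi, float)
    if roi.shape == (4,):
        x0, y0, rw, rh = roi
        if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
            raise ValueError(f"ROI {roi.tolist()} outside frame bounds {shape}")
        mask = np.zeros((h, w), bool)
        mask[int(y0) : int(y0 + rh), int(x0) : int(x0 + rw)] = True
        return mask
    # polygon: list of (x, y) vertices, 0-based, x right, y down
    verts = roi.reshape(-1, 2)
    if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or (
        verts[:, 0].max() > w or verts[:, 1].max() > h
    ):
        raise ValueError("polygon ROI outside frame bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    px = xx + 0.5  # pixel centres
    py = yy + 0.5
    inside = np.zeros((h, w), bool)
    x1, y1 = verts[-1]
    for x2, y2 in verts:  # even-odd crossing rule
        crosses = ((y1 > py) != (y2 > py)) & (
            px < (x2 - x1) * (py - y1) / (y2 - y1 + 1e-300) + x1
        )
        inside ^= crosses
        x1, y1 = x2, y2
    return inside


def extract_roi_traces(
    tiff_path: str | Path,
    rois: dict[str, object],
    frame_interval: float,
    background_roi: object | None = None,
    slice_id: str | None = None,
) -> TraceSet:
    """Per-ROI mean intensity per frame from a grayscale TIFF stack.

    ``rois`` maps channel name -> rectangle ``(x, y, w, h)`` or polygon
    vertex list in pixel coordinates (0-based, x right, y down).  When a
    background ROI is given, its per-frame mean is subtracted from every
    channel.  Times are frame index * ``frame_interval`` hours.
    """
    import tifffile

    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
        log.warning("%s: single-frame stack; trace has length 1", tiff_path)
    frames = stack.astype(float)
    shape = frames.shape[1:]

    bg = 0.0
    if background_roi is not None:
        bmask = _roi_mask(background_roi, shape)
        bg = frames[:, bmask].mean(axis=1)

    n = frames.shape[0]
    times = np.arange(n) * frame_interval
    channels = {}
    for name, roi in rois.items():
        mask = _roi_mask(roi, shape)
        channels[name] = frames[:, mask].mean(axis=1) - bg
    if n == 1:  # TraceSet needs >= 2 points; pad for the degenerate case
        times = np.array([0.0, frame_interval])
        channels = {k: np.repeat(v, 2) for k, v in channels.items()}
    return TraceSet(
        slice_id=slice_id or tiff_path.stem, times=times, channels=channels
    )
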