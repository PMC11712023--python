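"""Reading and writing the pipeline's on-disk formats.

Stacks are multi-page grayscale TIFFs (8/16-bit integer or 32-bit float),
one channel per file, with pixel size and frame interval supplied by the
caller/config (commercial acquisition software keeps them in proprietary
metadata).  ROIs are small JSON objects; midline paths and traces are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .imaging import RoiShape, RoiTrace, TimeLapseStack
from .kymo import Kymograph, MidlinePath

__all__ = [
    "read_stack",
    "write_stack",
    "read_roi_json",
    "write_roi_json",
    "read_path_csv",
    "write_path_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_kymograph_csv",
]


def read_stack(
    path, pixel_size: float, frame_interval: float, channel_label: str = ""
) -> TimeLapseStack:
    """Load a multi-page grayscale TIFF as a time-lapse stack."""
    frames = tifffile.imread(str(path))
    return TimeLapseStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_label=channel_label,
    )


def write_stack(path, stack_or_array) -> None:
    """Write a stack (or bare array) as a 32-bit float multi-page TIFF."""
    frames = getattr(stack_or_array, "frames", stack_or_array)
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def write_roi_json(path, roi: RoiShape) -> None:
    obj = {"kind": roi.kind, "center_um": list(roi.center), "angle_deg": roi.angle}
    if roi.kind == "circle":
        obj["radius_um"] = roi.radius
    else:
        obj["semi_axes_um"] = list(roi.semi_axes)
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_roi_json(path) -> RoiShape:
    obj = json.loads(Path(path).read_text())
    try:
        kind = obj["kind"]
        center = tuple(obj["center_um"])
    except KeyError as e:
        raise InputError(f"ROI JSON missing key {e}") from None
    if kind == "circle":
        return RoiShape(kind=kind, center=center, radius=obj["radius_um"])
    return RoiShape(
        kind=kind,
        center=center,
        semi_axes=tuple(obj["semi_axes_um"]),
        angle=obj.get("angle_deg", 0.0),
    )


def write_path_csv(path, midlines, line_width: int | None = None) -> None:
    """Write per-frame midline paths: columns frame, x_px, y_px, tip-first."""
    if isinstance(midlines, MidlinePath):
        midlines = [midlines]
    rows = []
    for f, m in enumerate(midlines):
        for x, y in m.points:
            rows.append((f, x, y))
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px"]).to_csv(path, index=False)


def read_path_csv(path, line_width: int = 10) -> list[MidlinePath]:
    df = pd.read_csv(path)
    missing = {"frame", "x_px", "y_px"} - set(df.columns)
    if missing:
        raise InputError(f"path CSV missing columns {sorted(missing)}")
    return [
        MidlinePath(points=g[["x_px", "y_px"]].to_numpy(), line_width=line_width)
        for _, g in df.groupby("frame", sort=True)
    ]


def write_trace_csv(path, trace: RoiTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "value": trace.values, "normalization": trace.normalization}
    ).to_csv(path, index=False)


def read_trace_csv(path) -> RoiTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise InputError(f"trace CSV missing columns {sorted(missing)}")
    norm = str(df["normalization"].iloc[0]) if "normalization" in df.columns else "none"
    return RoiTrace(
        times=df["time_s"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        normalization=norm,
    )


def write_kymograph_csv(path, kymo: Kymograph) -> None:
    """Kymograph matrix as CSV: rows = frames, columns = distance (µm) from tip."""
    cols = [f"{i * kymo.pixel_size:.6g}" for i in range(kymo.matrix.shape[1])]
    pd.DataFrame(kymo.matrix, columns=cols).to_csv(path, index_label="frame")
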