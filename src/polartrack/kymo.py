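"""Kymograph construction and the tip-distance statistic.

A kymograph stacks, frame by frame, the intensity profile sampled along the
tube midline: rows are time, columns are distance from the tip.  The
"average distance from tip" statistic slides a 10-row bin down the time axis
in 5-row steps, averages each bin's rows into one profile, scores the
distance of that profile's brightest column from the tip, and averages the
per-bin distances — a 150-frame movie yields 29 overlapping bins.

The midline path is supplied tip-first (column 0 of the kymograph is the
tube tip); for growing tubes a per-frame path re-anchored at the
instantaneous tip position is expected, exactly what the synthetic tube
generator emits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InputError, StatisticsError
from .imaging import TimeLapseStack
from .stats import BoxStats, box_stats, ttest_two_tailed

__all__ = [
    "MidlinePath",
    "Kymograph",
    "TipDistanceResult",
    "extract_profile",
    "build_kymograph",
    "binned_tip_distances",
    "compare_groups",
]


@dataclass(frozen=True)
class MidlinePath:
    """Ordered pixel coordinates along the tube axis, tip first.

    ``points`` is an (N, 2) array of (x, y) pixel coordinates, starting at
    the tube tip (distance 0) and running inward; consecutive points must be
    at most √2 px apart so that one point corresponds to roughly one
    kymograph column.  ``line_width`` pixels are averaged perpendicular to
    the path at each point.
    """

    points: np.ndarray
    line_width: int = 10

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InputError("path needs >= 2 (x, y) points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps > np.sqrt(2) + 1e-9):
            raise InputError("consecutive path points must be <= sqrt(2) px apart")
        if self.line_width < 1:
            raise InputError("line_width must be >= 1")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Kymograph:
    """Time × distance-from-tip intensity matrix with pixel/time calibration."""

    matrix: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise InputError("kymograph matrix must be 2-D (time × distance)")
        if not np.all(np.isfinite(m)):
            raise InputError("kymograph entries must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TipDistanceResult:
    """Per-bin peak distances (µm) and their mean, for one pollen tube."""

    bin_distances: np.ndarray
    average_distance: float
    n_bins: int
    bin_height_px: int = 10
    step_px: int = 5

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_distances, dtype=float)
        object.__setattr__(self, "bin_distances", d)
        if self.n_bins != len(d):
            raise InputError("n_bins must equal len(bin_distances)")


def _path_directions(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each path point (central differences, one-sided at ends)."""
    tangents = np.gradient(points, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return tangents / norms


def extract_profile(frame: np.ndarray, path: MidlinePath) -> np.ndarray:
    """Intensity profile along a midline path, averaged across its width.

    At each path point the local tangent is estimated by central differences;
    ``line_width`` samples are taken along the perpendicular, centered on the
    point at 1-px spacing, interpolated bilinearly, and averaged.
    ``profile[0]`` corresponds to the tip.

    Raises
    ------
    GeometryError
        If any sample falls outside the frame, reporting the first offending
        path index.
    """
    img = np.asarray(frame, dtype=float)
    h, w = img.shape
    pts = path.points
    tangents = _path_directions(pts)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(path.line_width, dtype=float) - (path.line_width - 1) / 2.0
    # sample grid: (n_points, line_width, 2) in (x, y) px
    samples = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = samples[..., 0], samples[..., 1]
    bad = (xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)
    if bad.any():
        idx = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise GeometryError(f"path sample leaves the frame at path index {idx}")
    vals = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1)
    return vals.reshape(xs.shape).mean(axis=1)


def build_kymograph(stack: TimeLapseStack, paths) -> Kymograph:
    """Stack per-frame midline profiles into a kymograph.

    ``paths`` is either one :class:`MidlinePath` (broadcast to every frame)
    or a sequence with one path per frame.  When per-frame paths differ in
    length, every row is truncated to the shortest path so no column extends
    beyond imaged tube in any frame.  Row count equals frame count; the
    caller is expected to have smoothed the stack (3×3 moving average) first.
    """
    if stack.n_frames < 1:
        raise InputError("stack has no frames")
    if isinstance(paths, MidlinePath):
        paths = [paths] * stack.n_frames
    else:
        paths = list(paths)
        if len(paths) != stack.n_frames:
            raise InputError(f"got {len(paths)} paths for {stack.n_frames} frames")
    n_cols = min(len(p) for p in paths)
    rows = [
        extract_profile(stack.frames[t], p)[:n_cols] for t, p in enumerate(paths)
    ]
    return Kymograph(
        matrix=np.vstack(rows),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )


def binned_tip_distances(
    kymo: Kymograph, bin_height_px: int = 10, step_px: int = 5
) -> TipDistanceResult:
    """Average distance of the peak signal from the tip, over sliding bins.

    Bins start at rows 0, step, 2·step, … while ``start + bin_height <=
    n_rows`` (so 150 rows / bin 10 / step 5 gives 29 bins).  Each bin's rows
    are averaged column-wise; the bin's distance is the argmax column ×
    pixel_size, ties broken toward the tip; the result's
    ``average_distance`` is the mean over bins.
    """
    m = kymo.matrix
    if m.shape[0] < bin_height_px:
        raise InputError(
            f"kymograph has {m.shape[0]} rows, fewer than bin height {bin_height_px}"
        )
    starts = range(0, m.shape[0] - bin_height_px + 1, step_px)
    distances = []
    for s in starts:
        profile = m[s : s + bin_height_px].mean(axis=0)
        distances.append(int(np.argmax(profile)) * kymo.pixel_size)  # first max = toward tip
    distances = np.asarray(distances)
    return TipDistanceResult(
        bin_distances=distances,
        average_distance=float(distances.mean()),
        n_bins=len(distances),
        bin_height_px=bin_height_px,
        step_px=step_px,
    )


def compare_groups(groups: dict) -> dict:
    """Compare tip-distance results between labeled treatment groups.

    ``groups`` maps a label (e.g. ``"control"``, ``"LatB 5 nM"``) to a list
    of :class:`TipDistanceResult` (or bare average distances).  Returns per
    group the mean, SD (ddof=1), SE, n, and box statistics, plus two-tailed
    Student's t-test p-values for every pair.
    """
    if len(groups) < 2:
        raise StatisticsError("need >= 2 groups to compare")
    samples = {}
    for label, results in groups.items():
        vals = np.asarray(
            [r.average_distance if isinstance(r, TipDistanceResult) else float(r) for r in results]
        )
        if len(vals) < 2:
            raise StatisticsError(f"group {label!r} has < 2 tubes")
        samples[label] = vals
    summary = {
        label: {
            "n": len(v),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "box": box_stats(v),
        }
        for label, v in samples.items()
    }
    labels = list(samples)
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            _, p = ttest_two_tailed(samples[a], samples[b])
            pairwise[(a, b)] = p
    return {"groups": summary, "pairwise_p": pairwise}
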