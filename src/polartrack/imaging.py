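"""Shared image primitives for fluorescence time-lapse quantification.

This module holds the containers and pixel-level operations every imaging
stage builds on: the time-lapse stack model, per-frame moving-average
smoothing, geometric ROIs with mean-intensity traces, maximum-intensity
z-projection, and bright-spot counting on projected images.

Coordinate convention
---------------------
x increases to the right (columns), y increases downward (rows), and the
origin sits at the *center* of the top-left pixel.  Physical coordinates are
``µm = px × pixel_size``.  A pixel belongs to an ROI when its center lies
inside (or on the boundary of) the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import GeometryError, InputError, ParameterError

__all__ = [
    "TimeLapseStack",
    "RoiShape",
    "RoiTrace",
    "SpotCallResult",
    "moving_average",
    "roi_mean_trace",
    "z_project",
    "count_spots",
    "fraction_with_spot",
]


@dataclass(frozen=True)
class TimeLapseStack:
    """A single-channel time-lapse: frames plus acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)`` of nonnegative finite intensities
        (arbitrary units).  A single 2-D frame is promoted to ``(1, H, W)``.
    pixel_size:
        Lateral pixel size in µm per pixel (> 0).
    frame_interval:
        Time between consecutive frames in seconds (> 0).
    channel_label:
        Free-text channel description (e.g. ``"Venus"``, ``"CFP"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, ...]
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise InputError(f"frames must be (T, H, W) with T >= 1, got shape {frames.shape}")
        if not np.all(np.isfinite(frames)):
            raise InputError("frame intensities must be finite")
        if np.any(frames < 0):
            raise InputError("frame intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ParameterError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame in pixels."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiShape:
    """A geometric ROI in physical (µm) coordinates.

    ``kind`` is one of ``"circle"``, ``"ellipse"`` or ``"rectangle"``.
    Circles take ``radius``; ellipses and rectangles take ``semi_axes``
    (half-width along the shape's own x axis, half-height along its y axis)
    and an optional counterclockwise rotation ``angle`` in degrees.
    """

    kind: str
    center: tuple[float, float]
    radius: float | None = None
    semi_axes: tuple[float, float] | None = None
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse", "rectangle"):
            raise ParameterError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle":
            if self.radius is None or self.radius <= 0:
                raise ParameterError("circle ROI requires radius > 0")
        else:
            if self.semi_axes is None or min(self.semi_axes) <= 0:
                raise ParameterError(f"{self.kind} ROI requires positive semi_axes")

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Boolean mask: which (x, y) µm points lie inside the shape."""
        x = np.asarray(x_um, dtype=float) - self.center[0]
        y = np.asarray(y_um, dtype=float) - self.center[1]
        if self.kind == "circle":
            return x * x + y * y <= self.radius**2
        # rotate into the shape's own frame (angle is CCW in image coords)
        theta = np.deg2rad(self.angle)
        u = x * np.cos(theta) + y * np.sin(theta)
        v = -x * np.sin(theta) + y * np.cos(theta)
        a, b = self.semi_axes
        if self.kind == "ellipse":
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return (np.abs(u) <= a) & (np.abs(v) <= b)

    def pixel_mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Pixel-center-inside mask for an image of the given (H, W) shape."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        return self.contains(xx * pixel_size, yy * pixel_size)


@dataclass(frozen=True)
class RoiTrace:
    """Per-frame mean intensity over an ROI.

    ``normalization`` records the trace's state: ``"none"`` (raw means),
    ``"first_frame"`` (divided by the first value) or ``"paired_ratio"``
    (pointwise ratio of two ROI traces).
    """

    times: np.ndarray
    values: np.ndarray
    roi: RoiShape | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise InputError("times and values must be 1-D arrays of equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SpotCallResult:
    """Outcome of spot counting on one projected image."""

    n_spots: int
    spot_centroids: list = field(default_factory=list)  # (x_um, y_um) pairs
    threshold_used: float = float("nan")
    min_area_used: int = 0

    def __post_init__(self) -> None:
        if self.n_spots != len(self.spot_centroids):
            raise InputError("n_spots must equal len(spot_centroids)")


def moving_average(stack: TimeLapseStack, window: int) -> TimeLapseStack:
    """Smooth each frame with a ``window × window`` neighborhood mean.

    Applied strictly per frame (no temporal mixing).  Boundaries are handled
    by edge reflection (the edge row/column is mirrored, i.e. ``abcd ->
    ba|abcd|dc``).  For even windows the footprint is floor-centered: its
    top-left corner sits at offset (−1, −1) from the output pixel, so a 4×4
    window covers offsets −1..+2 on both axes.

    Parameters
    ----------
    stack:
        Input time-lapse.
    window:
        Side length of the square averaging window; the tip-tracking pipeline
        uses 3 and the ratiometric Ca²⁺ pipeline uses 4, but any ``>= 1`` is
        accepted.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    origin = -1 if window % 2 == 0 else 0
    smoothed = ndimage.uniform_filter(
        stack.frames, size=(1, window, window), mode="reflect", origin=(0, origin, origin)
    )
    # floating error in the separable filter can leave values a hair below 0
    return replace(stack, frames=np.clip(smoothed, 0.0, None))


def roi_mean_trace(stack: TimeLapseStack, roi: RoiShape) -> RoiTrace:
    """Mean intensity inside an ROI, per frame.

    Pixels are included when their centers fall inside the shape; NaN pixels
    (e.g. masked ratio pixels) are ignored in the mean.

    Raises
    ------
    GeometryError
        If no pixel center lies inside the ROI.
    """
    mask = roi.pixel_mask(stack.shape, stack.pixel_size)
    if not mask.any():
        raise GeometryError(f"ROI {roi.kind} at {roi.center} µm contains no pixel centers")
    vals = stack.frames[:, mask]
    if np.isnan(vals).all(axis=1).any():
        raise GeometryError(f"ROI {roi.kind} at {roi.center} µm is fully masked in some frame")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=1)
    return RoiTrace(times=stack.times, values=means, roi=roi, normalization="none")


def z_project(slices, method: str = "max") -> np.ndarray:
    """Project a z-series of 2-D slices onto one image.

    ``method="max"`` (default) takes the per-pixel maximum — the conventional
    choice before spot scoring; ``"mean"`` and ``"sum"`` are also available.
    """
    arrays = [np.asarray(s, dtype=float) for s in slices]
    if len(arrays) == 0:
        raise InputError("z_project requires at least one slice")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise InputError(f"slice {i} has shape {a.shape}, expected {shape}")
    cube = np.stack(arrays)
    if method == "max":
        return cube.max(axis=0)
    if method == "mean":
        return cube.mean(axis=0)
    if method == "sum":
        return cube.sum(axis=0)
    raise ParameterError(f"unknown projection method {method!r}")


def count_spots(
    image: np.ndarray,
    threshold: float | str = "mad",
    min_area_px: int = 4,
    mad_k: float = 5.0,
    pixel_size: float = 1.0,
) -> SpotCallResult:
    """Count bright spots in a (projected) image.

    The image is binarized at a threshold — either a fixed intensity value,
    or (``threshold="mad"``) ``median + mad_k × MAD`` of the whole image, a
    robust background-relative default.  8-connected components with area
    ``>= min_area_px`` are counted as spots; centroids are returned in µm.

    Zero spots is a valid result, never an error.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise InputError("image must be finite and nonnegative")
    if min_area_px < 1:
        raise ParameterError("min_area_px must be >= 1")
    if threshold == "mad":
        med = np.median(img)
        mad = np.median(np.abs(img - med))
        thr = med + mad_k * mad
    else:
        thr = float(threshold)
    labels = measure.label(img > thr, connectivity=2)
    centroids = []
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            cy, cx = region.centroid
            centroids.append((cx * pixel_size, cy * pixel_size))
    return SpotCallResult(
        n_spots=len(centroids),
        spot_centroids=centroids,
        threshold_used=thr,
        min_area_used=min_area_px,
    )


def fraction_with_spot(results) -> float:
    """Percentage of grains with at least one called spot.

    Accepts a sequence of :class:`SpotCallResult` (or bare spot counts) and
    returns ``100 × (#grains with n_spots >= 1) / #grains``.
    """
    counts = [r.n_spots if isinstance(r, SpotCallResult) else int(r) for r in results]
    if len(counts) == 0:
        raise InputError("fraction_with_spot requires at least one grain result")
    return 100.0 * sum(1 for c in counts if c >= 1) / len(counts)
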