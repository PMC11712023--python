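"""Ratiometric FRET Ca²⁺ analysis: ratio stacks and spike timing.

The Yellow Cameleon (YC3.6) sensor reports cytosolic Ca²⁺ through the
YFP:CFP emission ratio.  This module builds per-pixel ratio images as
``(YFP / CFP) × scale`` (scale 4000 by convention), extracts ROI ratio
traces, detects the brief first Ca²⁺ spike that follows the rapid ratio
drop at hydration onset, and aligns traces so that spike to a common
anchor time for cohort comparison.

Spike definition (operationalized)
----------------------------------
The spike time is the first local maximum of the first-point-normalized ROI
ratio trace after the rapid drop: the drop is detected where the trace first
falls below ``(1 − drop_fraction)`` of its running maximum over the trailing
``drop_window_s`` seconds; the search then runs from the post-drop minimum
forward within ``search_window_s``.  A light boxcar smoothing and a minimum
prominence guard against calling shot-noise blips as peaks; both are
exposed as parameters.  This is a reproducible operationalization of a
criterion the original analysis applied by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError, InputError, ParameterError, StatisticsError
from .imaging import RoiShape, RoiTrace, TimeLapseStack, roi_mean_trace
from .stats import ttest_two_tailed

__all__ = [
    "RatioStack",
    "SpikeTiming",
    "ratio_stack",
    "display_rescale_to_first",
    "ratio_roi_trace",
    "spike_time",
    "align_to_spike",
    "compare_spike_timing",
]

DEFAULT_SCALE = 4000.0


@dataclass(frozen=True)
class RatioStack:
    """Per-pixel (YFP/CFP) × scale frames with a validity mask.

    Pixels whose CFP signal fell below the floor carry NaN and are excluded
    from ROI means.  ``display_rescaled`` flags stacks that have been mapped
    to the first frame's min/max for display; analysis consumes raw ratios.
    """

    frames: np.ndarray  # (T, H, W), NaN where masked
    mask: np.ndarray  # (T, H, W) bool, True = valid
    scale: float
    pixel_size: float
    frame_interval: float
    display_rescaled: bool = False

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if frames.shape != mask.shape or frames.ndim != 3:
            raise InputError("frames and mask must share a (T, H, W) shape")
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")
        valid = frames[mask]
        if valid.size and (not np.all(np.isfinite(valid))):
            raise InputError("unmasked ratio values must be finite")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "mask", mask)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class SpikeTiming:
    """Timing of the first Ca²⁺ spike in one grain's ratio trace (minutes)."""

    spike_time: float
    drop_time: float
    peak_value: float
    detected: bool

    def __post_init__(self) -> None:
        if self.detected and not self.drop_time < self.spike_time:
            raise InputError("drop_time must precede spike_time when detected")


def ratio_stack(
    yfp: TimeLapseStack,
    cfp: TimeLapseStack,
    scale: float = DEFAULT_SCALE,
    cfp_floor: float | None = None,
) -> RatioStack:
    """Per-pixel ``scale × YFP / CFP`` with low-CFP pixels masked.

    Both channels must be congruent (same shape, frame count, calibration)
    and are expected pre-smoothed with a 4×4 moving average.  ``cfp_floor``
    defaults to 1% of the CFP dynamic range (min + 0.01 × (max − min)),
    which keeps background pixels from blowing up the ratio; pixels below
    the floor are masked (NaN) and excluded from downstream ROI means.
    """
    if yfp.frames.shape != cfp.frames.shape:
        raise InputError(
            f"YFP {yfp.frames.shape} and CFP {cfp.frames.shape} stacks are not congruent"
        )
    if yfp.pixel_size != cfp.pixel_size or yfp.frame_interval != cfp.frame_interval:
        raise InputError("YFP and CFP stacks must share pixel_size and frame_interval")
    if cfp_floor is None:
        lo, hi = cfp.frames.min(), cfp.frames.max()
        cfp_floor = lo + 0.01 * (hi - lo)
        if cfp_floor <= 0:  # all-zero CFP would mask nothing otherwise
            cfp_floor = np.finfo(float).tiny
    mask = cfp.frames >= cfp_floor
    frames = np.full(yfp.frames.shape, np.nan)
    np.divide(yfp.frames, cfp.frames, out=frames, where=mask)
    frames[mask] *= scale
    return RatioStack(
        frames=frames,
        mask=mask,
        scale=scale,
        pixel_size=yfp.pixel_size,
        frame_interval=yfp.frame_interval,
    )


def display_rescale_to_first(ratio: RatioStack) -> RatioStack:
    """Affine display rescale: first-frame min -> 0, max -> 1, all frames.

    Values outside [0, 1] in later frames are allowed.  Purely for display;
    analysis operations consume the raw ratio.  Refuses already-rescaled
    input and a constant first frame.
    """
    if ratio.display_rescaled:
        raise InputError("stack is already display-rescaled")
    first = ratio.frames[0][ratio.mask[0]]
    if first.size < 2 or first.min() == first.max():
        raise AnalysisError("first frame has no dynamic range to rescale to")
    lo, hi = first.min(), first.max()
    return replace(ratio, frames=(ratio.frames - lo) / (hi - lo), display_rescaled=True)


def ratio_roi_trace(ratio: RatioStack, roi: RoiShape) -> RoiTrace:
    """Mean ratio inside an ROI per frame, ignoring masked pixels."""
    return roi_mean_trace(ratio, roi)


def _normalized(trace: RoiTrace) -> None:
    if trace.normalization != "first_frame" or abs(trace.values[0] - 1.0) > 1e-9:
        raise InputError("spike_time requires a trace normalized to its first time point")


def spike_time(
    trace: RoiTrace,
    drop_fraction: float = 0.15,
    drop_window_s: float = 120.0,
    search_window_s: float = 900.0,
    smooth_samples: int = 3,
    min_prominence: float = 0.1,
) -> SpikeTiming:
    """First Ca²⁺ spike time after the rapid hydration drop, in minutes.

    Parameters
    ----------
    trace:
        ROI ratio trace normalized to its first time point, >= 10 samples.
    drop_fraction, drop_window_s:
        The rapid drop is the first sample below ``(1 − drop_fraction)`` of
        the running maximum over the trailing ``drop_window_s`` seconds.
    search_window_s:
        How far past the drop to search for the spike (default 15 min — the
        spike is an early-hydration event).
    smooth_samples, min_prominence:
        Boxcar width and peak-prominence floor (on the normalized trace)
        used when locating the spike, to reject single-sample noise blips.

    Returns a :class:`SpikeTiming` with ``detected=False`` when no rapid
    drop, or no subsequent qualifying local maximum, exists.  ``drop_time``
    is the post-drop minimum; plateau peaks resolve to their first sample.
    """
    _normalized(trace)
    if len(trace) < 10:
        raise InputError("spike_time requires >= 10 samples")
    t, v = trace.times, trace.values
    undetected = SpikeTiming(float("nan"), float("nan"), float("nan"), False)

    drop_idx = None
    for j in range(1, len(v)):
        recent = v[(t >= t[j] - drop_window_s) & (t < t[j])]
        if recent.size and v[j] < (1.0 - drop_fraction) * recent.max():
            drop_idx = j
            break
    if drop_idx is None:
        return undetected

    end = np.searchsorted(t, t[drop_idx] + search_window_s, side="right")
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        vs = np.convolve(np.pad(v, smooth_samples // 2, mode="edge"), kernel, mode="same")
        vs = vs[smooth_samples // 2 : smooth_samples // 2 + len(v)]
    else:
        vs = v
    # the post-drop minimum is the *first* trough after the drop (where the
    # fall bottoms out), not the window's global minimum — the trace can dip
    # lower again after an early spike has come and gone
    troughs, _ = find_peaks(-vs[drop_idx:end], prominence=min_prominence, plateau_size=(1, None))
    if len(troughs):
        min_idx = drop_idx + int(troughs[0])
    else:
        min_idx = drop_idx + int(np.argmin(vs[drop_idx:end]))
    seg = vs[min_idx:end]
    peaks, _ = find_peaks(seg, prominence=min_prominence, plateau_size=(1, None))
    if len(peaks) == 0:
        return undetected
    # refine to the raw trace's maximum near the smoothed peak
    p = min_idx + int(peaks[0])
    lo = max(p - smooth_samples // 2, min_idx + 1)
    hi = min(p + smooth_samples // 2 + 1, len(v))
    p = lo + int(np.argmax(v[lo:hi]))
    return SpikeTiming(
        spike_time=float(t[p] / 60.0),
        drop_time=float(t[min_idx] / 60.0),
        peak_value=float(v[p]),
        detected=True,
    )


def align_to_spike(traces, timings, anchor_min: float = 5.0):
    """Shift each trace so its first Ca²⁺ spike lands at ``anchor_min``.

    Mirrors the convention of plotting pollination time courses with the
    first spike at 5 min.  Values are untouched; only times shift by
    ``(anchor − spike_time)``.  Every timing must be detected.
    """
    traces = list(traces)
    timings = list(timings)
    if len(traces) != len(timings):
        raise InputError("one timing per trace required")
    missing = [i for i, s in enumerate(timings) if not s.detected]
    if missing:
        raise AnalysisError(f"cannot align traces with undetected spikes: indices {missing}")
    out = []
    for trace, timing in zip(traces, timings):
        shift_s = (anchor_min - timing.spike_time) * 60.0
        out.append(replace(trace, times=trace.times + shift_s))
    return out


def compare_spike_timing(group_a, group_b) -> dict:
    """Per-group spike-time mean ± SD (minutes) and Student's two-tailed p."""

    def _times(group, name):
        vals = np.asarray([s.spike_time for s in group if s.detected], dtype=float)
        if len(vals) < 2:
            raise StatisticsError(f"group {name} has < 2 detected spikes")
        return vals

    a = _times(group_a, "a")
    b = _times(group_b, "b")
    _, p = ttest_two_tailed(a, b)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "n_a": len(a),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "n_b": len(b),
        "p": p,
    }
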