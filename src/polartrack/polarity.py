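"""Polarized-site dynamics in germinating pollen grains.

Before the pollen tube emerges, reporters accumulate at the future
germination site in oscillatory pulses.  This module quantifies that
behaviour from ROI traces: the relative polarity ratio (polarized-site ROI
over whole-grain ROI), first-time-point normalization, oscillation peak
detection, and the peak-to-peak lag between two co-polarizing reporters
(e.g. a Ca²⁺ reporter leading a vesicle/scaffold reporter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError, NormalizationError, ParameterError
from .imaging import RoiTrace

__all__ = [
    "PeakSet",
    "LagEstimate",
    "relative_polarity",
    "normalize_to_first",
    "detect_local_peaks",
    "peak_lag",
]


@dataclass(frozen=True)
class PeakSet:
    """Detected oscillation peaks of one trace: times (minutes) and values."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    prominence_used: float
    min_separation_used: float

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        v = np.asarray(self.peak_values, dtype=float)
        if t.shape != v.shape:
            raise InputError("one value per peak time required")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InputError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", t)
        object.__setattr__(self, "peak_values", v)

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class LagEstimate:
    """Matched peak-to-peak lags (minutes): response peak − reference peak."""

    paired_lags: np.ndarray
    mean_lag: float
    sd_lag: float
    se_lag: float
    n_pairs: int
    unmatched_reference: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.paired_lags, dtype=float)
        object.__setattr__(self, "paired_lags", lags)
        if self.n_pairs != len(lags):
            raise InputError("n_pairs must equal len(paired_lags)")


def relative_polarity(site_trace: RoiTrace, grain_trace: RoiTrace) -> RoiTrace:
    """Pointwise ratio of polarized-site intensity to whole-grain intensity.

    Both traces must share a time axis; the ratio cancels common
    illumination changes, so a rising trace means genuine accumulation at
    the polarized site rather than a global intensity drift.
    """
    if len(site_trace) != len(grain_trace) or not np.allclose(
        site_trace.times, grain_trace.times
    ):
        raise InputError("site and grain traces must share their time axis")
    bad = np.nonzero(grain_trace.values <= 0)[0]
    if bad.size:
        raise NormalizationError(f"whole-grain intensity is <= 0 at frame {int(bad[0])}")
    return RoiTrace(
        times=site_trace.times,
        values=site_trace.values / grain_trace.values,
        roi=site_trace.roi,
        normalization="paired_ratio",
    )


def normalize_to_first(trace: RoiTrace) -> RoiTrace:
    """Divide a trace by its first value so the trace starts at 1.0."""
    first = trace.values[0]
    if first <= 0:
        raise NormalizationError(f"first value must be > 0, got {first}")
    return replace(trace, values=trace.values / first, normalization="first_frame")


def detect_local_peaks(
    trace: RoiTrace,
    prominence: float = 0.05,
    min_separation_min: float = 1.0,
) -> PeakSet:
    """Local maxima of an oscillating trace, as times in minutes.

    Peaks must rise at least ``prominence`` (trace units; the default suits
    first-frame-normalized traces) above their surroundings and be separated
    by at least ``min_separation_min``.  A plateau peak is reported at the
    plateau's first sample.  An empty result is valid (e.g. monotone traces).
    """
    if len(trace) < 3:
        raise InputError("peak detection requires >= 3 samples")
    if prominence <= 0 or min_separation_min <= 0:
        raise ParameterError("prominence and min_separation_min must be > 0")
    dt = float(np.min(np.diff(trace.times)))
    distance = max(1, int(round(min_separation_min * 60.0 / dt)))
    idx, props = find_peaks(
        trace.values, prominence=prominence, distance=distance, plateau_size=(1, None)
    )
    left = props.get("left_edges", idx)  # plateau -> first sample
    return PeakSet(
        peak_times=trace.times[left] / 60.0,
        peak_values=trace.values[left],
        prominence_used=prominence,
        min_separation_used=min_separation_min,
    )


def peak_lag(reference: PeakSet, response: PeakSet, window_min: float = 5.0) -> LagEstimate:
    """Forward greedy matching of response peaks to reference peaks.

    Each reference peak (in time order) is matched to the earliest unused
    response peak occurring at or after it within ``window_min`` minutes;
    lags are ``response − reference`` (so a responder that follows the
    reference gives positive lags).  Reference peaks with no eligible
    response peak are counted, not dropped silently.
    """
    if window_min <= 0:
        raise ParameterError("window_min must be > 0")
    lags = []
    used = np.zeros(len(response), dtype=bool)
    unmatched = 0
    for rt in reference.peak_times:
        candidates = np.nonzero(
            (~used)
            & (response.peak_times >= rt)
            & (response.peak_times <= rt + window_min)
        )[0]
        if candidates.size == 0:
            unmatched += 1
            continue
        j = int(candidates[0])
        used[j] = True
        lags.append(float(response.peak_times[j] - rt))
    lags = np.asarray(lags)
    n = len(lags)
    mean = float(lags.mean()) if n else float("nan")
    sd = float(lags.std(ddof=1)) if n > 1 else float("nan")
    se = sd / np.sqrt(n) if n > 1 else float("nan")
    return LagEstimate(
        paired_lags=lags,
        mean_lag=mean,
        sd_lag=sd,
        se_lag=se,
        n_pairs=n,
        unmatched_reference=unmatched,
    )
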