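"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Each generator renders the kind of raw input the corresponding analysis
stage consumes — time-lapse TIFF-style stacks, midline paths, ROI
geometry, fraction-profile tables — together with a :class:`SynthTruth`
record carrying every injected parameter, so closed-loop parameter-recovery
tests (and users) can score the downstream statistics against known truth.

Defaults reflect the acquisition conditions of the quantifications they
emulate: 3-s frame intervals and 150 frames for growing pollen tubes,
1-min intervals for grain polarization, 10-s intervals over ~30 min for
ratiometric Ca²⁺ movies, four sucrose fractions for co-migration tables,
and three z-slices at 3-µm spacing for callose scoring.

Noise model: additive Gaussian on intensities, truncated at zero.  The
ratiometric generator additionally applies a per-frame multiplicative
jitter to the acceptor channel so that ROI-averaged ratio traces carry the
requested noise level (per-pixel noise alone would average away over an
ROI).  No optical PSF, photobleaching, or 3-D rendering is modeled.

Every generator draws all randomness from a single ``numpy`` Generator
seeded by its ``seed`` argument; the same seed reproduces outputs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comigration import DEFAULT_FRACTIONS, FractionProfileTable
from .errors import GeometryError, ParameterError
from .imaging import RoiShape, TimeLapseStack
from .kymo import MidlinePath

import pandas as pd

__all__ = [
    "SynthTruth",
    "TubeSim",
    "GrainDualSim",
    "FretSim",
    "FractionSim",
    "CalloseSim",
    "simulate_tube_movie",
    "simulate_grain_dual_channel",
    "simulate_fret_movie",
    "simulate_fraction_table",
    "simulate_callose_zstack",
]


@dataclass(frozen=True)
class SynthTruth:
    """Ground-truth record for one simulated scenario.

    ``params`` holds the full injected parameter set (distances, lags, spike
    times, planted id sets, noise levels, per-frame tip positions, ROI
    geometry — whatever the scenario needs to score its statistic).
    """

    scenario: str
    seed: int
    params: dict


@dataclass(frozen=True)
class TubeSim:
    stack: TimeLapseStack
    paths: list  # one tip-first MidlinePath per frame
    truth: SynthTruth


@dataclass(frozen=True)
class GrainDualSim:
    channel1: TimeLapseStack  # reference (leads)
    channel2: TimeLapseStack  # response (lags)
    site_roi: RoiShape
    grain_roi: RoiShape
    truth: SynthTruth


@dataclass(frozen=True)
class FretSim:
    cfp: TimeLapseStack
    yfp: TimeLapseStack
    roi: RoiShape
    truth: SynthTruth


@dataclass(frozen=True)
class FractionSim:
    table: FractionProfileTable
    truth: SynthTruth


@dataclass(frozen=True)
class CalloseSim:
    grains: list  # per grain: list of 2-D slices (the z-stack)
    pixel_size: float
    truth: SynthTruth


def _noisy(rng: np.random.Generator, image: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return image
    return np.clip(image + rng.normal(0.0, sd, size=image.shape), 0.0, None)


# ---------------------------------------------------------------------------
# elongating pollen tube with a tip-focused fluorophore band


def simulate_tube_movie(
    length0_um: float = 20.0,
    growth_rate_um_s: float = 0.02,
    osc_amplitude_um: float = 0.5,
    osc_period_s: float = 50.0,
    band_distance_um: float = 4.17,
    band_sigma_um: float = 1.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_sd: float = 100.0,
    pixel_size: float = 0.2,
    frame_interval: float = 3.0,
    n_frames: int = 150,
    tube_width_um: float = 5.0,
    seed: int = 0,
) -> TubeSim:
    """Render a growing pollen tube with an oscillating tip-focused band.

    The tube is a horizontal 2-D capsule (rectangle plus a semicircular cap)
    of fixed width whose tip advances as ``length0 + growth_rate · t +
    osc_amplitude · sin(2πt / osc_period)``.  Fluorescence is a constant
    tube background plus a Gaussian band centered ``band_distance_um``
    behind the instantaneous tip, plus truncated Gaussian pixel noise.  A
    tip-first midline path re-anchored at the instantaneous tip is emitted
    for every frame, ready for kymograph construction.

    Defaults emulate typical confocal tube acquisitions (3-s intervals, 150
    frames = 450 s) with the control condition's ~4 µm band distance; the
    default noise is 10% of the band amplitude.
    """
    if band_distance_um < 0 or n_frames < 1:
        raise ParameterError("band_distance_um must be >= 0 and n_frames >= 1")
    if band_distance_um + 3 * band_sigma_um > length0_um:
        raise ParameterError("band does not fit inside the initial tube length")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    tip_um = length0_um + growth_rate_um_s * t + osc_amplitude_um * np.sin(
        2 * np.pi * t / osc_period_s
    )
    half_w = tube_width_um / 2.0
    height_px = int(np.ceil((tube_width_um + 4.0) / pixel_size))
    width_px = int(np.ceil((tip_um.max() + half_w + 4.0) / pixel_size))
    yc_px = height_px // 2
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    x_um = xx * pixel_size
    y_um = (yy - yc_px) * pixel_size

    frames = np.empty((n_frames, height_px, width_px))
    paths = []
    for k in range(n_frames):
        tip = tip_um[k]
        shaft = (x_um <= tip) & (np.abs(y_um) <= half_w)
        cap = (x_um - tip) ** 2 + y_um**2 <= half_w**2
        inside = shaft | cap
        dist_from_tip = tip - x_um
        band = amplitude * np.exp(
            -((dist_from_tip - band_distance_um) ** 2) / (2 * band_sigma_um**2)
        )
        img = np.where(inside, background + band, 0.0)
        frames[k] = _noisy(rng, img, noise_sd)
        tip_px = tip / pixel_size
        n_pts = int(np.floor(tip_px)) + 1
        xs = tip_px - np.arange(n_pts)
        pts = np.stack([xs, np.full(n_pts, float(yc_px))], axis=1)
        paths.append(MidlinePath(points=pts, line_width=10))

    stack = TimeLapseStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_label="Venus",
    )
    truth = SynthTruth(
        scenario="tube",
        seed=seed,
        params={
            "band_distance_um": band_distance_um,
            "band_sigma_um": band_sigma_um,
            "tip_positions_um": tip_um,
            "length0_um": length0_um,
            "growth_rate_um_s": growth_rate_um_s,
            "osc_amplitude_um": osc_amplitude_um,
            "osc_period_s": osc_period_s,
            "amplitude": amplitude,
            "background": background,
            "noise_sd": noise_sd,
            "tube_width_um": tube_width_um,
        },
    )
    return TubeSim(stack=stack, paths=paths, truth=truth)


# ---------------------------------------------------------------------------
# pollen grain with two co-polarizing oscillatory reporters


def simulate_grain_dual_channel(
    grain_axes_um: tuple[float, float] = (10.0, 8.0),
    site_offset_um: tuple[float, float] | None = None,
    site_radius_um: float = 2.5,
    osc_period_min: float = 6.0,
    lag_min: float = 2.74,
    amplitudes: tuple[float, float] = (300.0, 300.0),
    background: float = 500.0,
    noise_sd: float = 15.0,
    frame_interval_min: float = 1.0,
    n_frames: int = 31,
    pixel_size: float = 0.5,
    seed: int = 0,
) -> GrainDualSim:
    """Two-channel movie of a polarizing grain with a known peak lag.

    Channel 1 (the reference, e.g. a Ca²⁺ reporter) oscillates at the
    polarized site with period ``osc_period_min``; channel 2 follows the
    same oscillation delayed by ``lag_min`` minutes.  The whole grain
    carries a constant background in both channels.  Defaults emulate
    1-min-interval polarization imaging with the reported ~2.7-min lag;
    noise defaults to 3% of the background.
    """
    a, b = grain_axes_um
    if site_offset_um is None:
        site_offset_um = (a - site_radius_um - 0.5, 0.0)
    ox, oy = site_offset_um
    if (ox / a) ** 2 + (oy / b) ** 2 > 1.0:
        raise GeometryError("polarized site center lies outside the grain")
    if lag_min < 0:
        raise ParameterError("lag_min must be >= 0")
    rng = np.random.default_rng(seed)
    # each grain starts its oscillation at a random phase, as real grains
    # polarize asynchronously; this also dithers frame-quantization error
    # across a cohort
    phase_min = float(rng.uniform(0.0, osc_period_min))
    margin = 2.0
    cx, cy = a + margin, b + margin
    width_px = int(np.ceil(2 * cx / pixel_size)) + 1
    height_px = int(np.ceil(2 * cy / pixel_size)) + 1
    grain = RoiShape(kind="ellipse", center=(cx, cy), semi_axes=(a, b))
    site = RoiShape(kind="circle", center=(cx + ox, cy + oy), radius=site_radius_um)
    grain_mask = grain.pixel_mask((height_px, width_px), pixel_size)
    site_mask = site.pixel_mask((height_px, width_px), pixel_size)

    t_min = np.arange(n_frames) * frame_interval_min

    def site_signal(tt, amp):
        return amp * 0.5 * (
            1.0 + np.sin(2 * np.pi * (tt - phase_min) / osc_period_min - np.pi / 2)
        )

    ch = []
    for amp, delay in ((amplitudes[0], 0.0), (amplitudes[1], lag_min)):
        frames = np.zeros((n_frames, height_px, width_px))
        for k, tk in enumerate(t_min):
            img = np.where(grain_mask, background, 0.0)
            img = img + np.where(site_mask, site_signal(tk - delay, amp), 0.0)
            frames[k] = _noisy(rng, img, noise_sd)
        ch.append(
            TimeLapseStack(
                frames=frames,
                pixel_size=pixel_size,
                frame_interval=frame_interval_min * 60.0,
                channel_label=f"ch{len(ch) + 1}",
            )
        )
    # site_signal peaks where sin(2π(t−phase)/P − π/2) = 1, i.e. t = phase + P/2 + k·P
    first_peak = (phase_min + osc_period_min / 2.0) % osc_period_min
    peak_times_ref = np.arange(first_peak, t_min[-1] + 1e-9, osc_period_min)
    truth = SynthTruth(
        scenario="grain_dual",
        seed=seed,
        params={
            "lag_min": lag_min,
            "osc_period_min": osc_period_min,
            "phase_min": phase_min,
            "reference_peak_times_min": peak_times_ref,
            "grain_axes_um": grain_axes_um,
            "site_center_um": site.center,
            "site_radius_um": site_radius_um,
            "amplitudes": amplitudes,
            "background": background,
            "noise_sd": noise_sd,
        },
    )
    return GrainDualSim(
        channel1=ch[0], channel2=ch[1], site_roi=site, grain_roi=grain, truth=truth
    )


# ---------------------------------------------------------------------------
# two-channel FRET movie of a hydrating grain


def ratio_schedule(
    t_s: np.ndarray,
    baseline_ratio: float,
    drop_depth: float,
    drop_time_min: float,
    fall_duration_s: float,
    spike_time_min: float,
    spike_width_s: float,
    spike_height: float,
    rise_slope_per_min: float,
) -> np.ndarray:
    """Target YFP:CFP ratio (relative units) over time for a hydrating grain.

    Baseline until ``drop_time``; linear fall of ``drop_depth`` of the
    baseline over ``fall_duration_s``; then a gradual linear rise, with a
    brief Gaussian spike (FWHM ``spike_width_s``) at ``spike_time``.
    """
    drop_t = drop_time_min * 60.0
    fall_end = drop_t + fall_duration_s
    floor = baseline_ratio * (1.0 - drop_depth)
    r = np.full_like(t_s, baseline_ratio, dtype=float)
    falling = (t_s >= drop_t) & (t_s < fall_end)
    r[falling] = baseline_ratio - drop_depth * baseline_ratio * (
        (t_s[falling] - drop_t) / fall_duration_s
    )
    after = t_s >= fall_end
    r[after] = floor + rise_slope_per_min * (t_s[after] - fall_end) / 60.0
    sigma = spike_width_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    r = r + spike_height * np.exp(-((t_s - spike_time_min * 60.0) ** 2) / (2 * sigma**2))
    return r


def simulate_fret_movie(
    baseline_ratio: float = 1.0,
    drop_depth: float = 0.4,
    drop_time_min: float = 1.5,
    fall_duration_s: float = 60.0,
    spike_time_min: float = 4.87,
    spike_width_s: float = 20.0,
    spike_height: float = 0.3,
    rise_slope_per_min: float = 0.02,
    noise_sd: float = 0.05,
    frame_interval_s: float = 10.0,
    duration_min: float = 30.0,
    grain_radius_um: float = 10.0,
    cfp_level: float = 200.0,
    pixel_size: float = 0.5,
    seed: int = 0,
) -> FretSim:
    """CFP + YFP movie whose ROI ratio trace follows baseline → rapid drop
    during hydration → brief spike → gradual rise.

    The donor (CFP) is constant inside the grain; the acceptor (YFP)
    follows ``CFP × r(t)`` where ``r`` is the :func:`ratio_schedule`, so the
    scaled ratio image is ``4000 × r(t)`` inside the grain.  ``noise_sd``
    is the target SD of the ROI-averaged normalized ratio trace: it is
    applied as a per-frame multiplicative jitter on the acceptor (which
    survives ROI averaging) plus matching truncated per-pixel noise on both
    channels.  Defaults emulate 10-s sampling over 30 min with the observed
    ~4.9-min spike, < 30 s wide.
    """
    if not drop_time_min < spike_time_min:
        raise ParameterError("drop_time_min must precede spike_time_min")
    if spike_width_s > 30.0:
        raise ParameterError("spike_width_s must be <= 30 s (the spike is brief)")
    rng = np.random.default_rng(seed)
    t_s = np.arange(0.0, duration_min * 60.0 + 1e-9, frame_interval_s)
    r = ratio_schedule(
        t_s,
        baseline_ratio,
        drop_depth,
        drop_time_min,
        fall_duration_s,
        spike_time_min,
        spike_width_s,
        spike_height,
        rise_slope_per_min,
    )
    if np.any(r <= 0):
        raise ParameterError("ratio schedule produces nonpositive intensities")

    size_um = 2 * grain_radius_um + 4.0
    n_px = int(np.ceil(size_um / pixel_size)) + 1
    c = (n_px // 2) * pixel_size
    grain = RoiShape(kind="circle", center=(c, c), radius=grain_radius_um)
    grain_mask = grain.pixel_mask((n_px, n_px), pixel_size)
    roi = RoiShape(kind="circle", center=(c, c), radius=2.5)

    jitter = 1.0 + (rng.normal(0.0, noise_sd, size=len(t_s)) if noise_sd > 0 else 0.0)
    cfp_frames = np.empty((len(t_s), n_px, n_px))
    yfp_frames = np.empty_like(cfp_frames)
    for k in range(len(t_s)):
        cfp_img = np.where(grain_mask, cfp_level, 0.0)
        yfp_img = np.where(grain_mask, cfp_level * r[k] * (jitter[k] if noise_sd > 0 else 1.0), 0.0)
        cfp_frames[k] = _noisy(rng, cfp_img, noise_sd * cfp_level * 0.2)
        yfp_frames[k] = _noisy(rng, yfp_img, noise_sd * cfp_level * 0.2)
    meta = dict(pixel_size=pixel_size, frame_interval=frame_interval_s)
    truth = SynthTruth(
        scenario="fret",
        seed=seed,
        params={
            "spike_time_min": spike_time_min,
            "drop_time_min": drop_time_min,
            "baseline_ratio": baseline_ratio,
            "drop_depth": drop_depth,
            "spike_width_s": spike_width_s,
            "spike_height": spike_height,
            "rise_slope_per_min": rise_slope_per_min,
            "noise_sd": noise_sd,
            "hydration_start_min": 0.0,
            "roi_center_um": roi.center,
            "roi_radius_um": roi.radius,
            "ratio_schedule": r,
        },
    )
    return FretSim(
        cfp=TimeLapseStack(frames=cfp_frames, channel_label="CFP", **meta),
        yfp=TimeLapseStack(frames=yfp_frames, channel_label="YFP", **meta),
        roi=roi,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# sucrose-fraction co-migration table


def simulate_fraction_table(
    n_proteins: int = 3046,
    n_comigrating: int = 340,
    n_fractions: int = 4,
    profile_noise_sd: float = 0.01,
    cutoff_guard: float = 0.8,
    bait_id: str = "AT1G48090",
    seed: int = 0,
) -> FractionSim:
    """Fraction-profile table with a planted set of bait co-migrators.

    The bait profile is drawn once (Dirichlet); the planted co-migrating
    proteins are the bait profile plus truncated Gaussian noise
    (renormalized); the remaining proteins are drawn independently from a
    flat Dirichlet, **rejection-sampled so their Pearson r against the bait
    stays at or below** ``cutoff_guard`` — without this a 4-point Dirichlet
    profile chance-correlates above 0.8 with a typical bait in roughly one
    draw out of eight, which would make the planted labels meaningless as
    ground truth.  The planted set includes the bait itself (it trivially
    co-migrates with itself at r = 1), so at zero noise exactly
    ``n_comigrating`` proteins pass a screen at the guard cutoff.

    Defaults are full screen scale: 3046 detected proteins of which 340
    co-migrate across the four gradient fractions.
    """
    if not 1 <= n_comigrating <= n_proteins:
        raise ParameterError("need 1 <= n_comigrating <= n_proteins")
    if n_fractions < 3:
        raise ParameterError("need >= 3 fractions")
    rng = np.random.default_rng(seed)
    labels = (
        list(DEFAULT_FRACTIONS)
        if n_fractions == 4
        else [f"F{i + 1}" for i in range(n_fractions)]
    )
    bait = rng.dirichlet(np.full(n_fractions, 2.0))
    while bait.std() < 0.05:  # a near-flat bait makes correlation meaningless
        bait = rng.dirichlet(np.full(n_fractions, 2.0))

    n_planted_extra = n_comigrating - 1
    n_background = n_proteins - n_comigrating
    ids = [f"AT{i + 1:07d}" for i in range(n_proteins - 1)]
    planted_ids = ids[:n_planted_extra]
    background_ids = ids[n_planted_extra:]

    def _corr(rows: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=1, keepdims=True)
        bc = bait - bait.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (bc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return rc @ bc / denom

    planted = np.tile(bait, (n_planted_extra, 1))
    if profile_noise_sd > 0:
        planted = np.clip(
            planted + rng.normal(0.0, profile_noise_sd, size=planted.shape), 1e-12, None
        )
        planted /= planted.sum(axis=1, keepdims=True)

    background = rng.dirichlet(np.ones(n_fractions), size=n_background)
    if n_background:
        for _ in range(1000):
            r = _corr(background)
            bad = ~(r <= cutoff_guard)  # catches NaN (zero-variance) rows too
            if not bad.any():
                break
            background[bad] = rng.dirichlet(np.ones(n_fractions), size=int(bad.sum()))
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("background rejection sampling did not converge")

    rows = np.vstack([bait[None, :], planted, background]) if n_background else np.vstack(
        [bait[None, :], planted]
    )
    index = [bait_id] + planted_ids + background_ids
    df = pd.DataFrame(rows, index=index, columns=labels)
    df.index.name = "protein_id"
    table = FractionProfileTable(abundances=df, bait_id=bait_id, normalized=True)
    truth = SynthTruth(
        scenario="fractions",
        seed=seed,
        params={
            "planted_set": frozenset([bait_id] + planted_ids),
            "bait_profile": bait,
            "n_proteins": n_proteins,
            "n_comigrating": n_comigrating,
            "profile_noise_sd": profile_noise_sd,
            "cutoff_guard": cutoff_guard,
        },
    )
    return FractionSim(table=table, truth=truth)


# ---------------------------------------------------------------------------
# callose-spot z-stacks


def simulate_callose_zstack(
    n_grains: int = 100,
    spot_prevalence: float = 0.726,
    spots_per_positive: int = 1,
    spot_intensity: float = 500.0,
    spot_sigma_um: float = 1.0,
    n_slices: int = 3,
    slice_interval_um: float = 3.0,
    background: float = 50.0,
    noise_sd: float = 10.0,
    image_size_um: float = 24.0,
    pixel_size: float = 0.5,
    seed: int = 0,
) -> CalloseSim:
    """Per-grain z-stacks with callose-like bright spots at known prevalence.

    Each grain gets ``n_slices`` slices of constant background plus noise;
    grains drawn positive (Bernoulli ``spot_prevalence``) receive
    ``spots_per_positive`` Gaussian spots, each placed in one random slice
    at a random in-bounds position.  The default prevalence matches the
    wild-type callose-spot rate the mutant comparison is scored against.
    """
    if not 0.0 <= spot_prevalence <= 1.0:
        raise ParameterError("spot_prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_px = int(round(image_size_um / pixel_size))
    sigma_px = spot_sigma_um / pixel_size
    margin = int(np.ceil(3 * sigma_px)) + 1
    positive = rng.random(n_grains) < spot_prevalence
    grains = []
    spot_positions = []
    for g in range(n_grains):
        slices = np.full((n_slices, n_px, n_px), background)
        positions = []
        if positive[g]:
            yy, xx = np.mgrid[0:n_px, 0:n_px]
            centers: list = []
            for _ in range(spots_per_positive):
                # keep planted spots apart so they stay distinct after
                # projection (they would otherwise merge into one component)
                for _attempt in range(1000):
                    z = int(rng.integers(n_slices))
                    cy = rng.uniform(margin, n_px - 1 - margin)
                    cx = rng.uniform(margin, n_px - 1 - margin)
                    if all(
                        np.hypot(cy - py, cx - px_) >= 7.5 * sigma_px
                        for py, px_ in centers
                    ):
                        break
                else:
                    raise ParameterError(
                        "cannot place distinct spots: increase image_size_um "
                        "or reduce spots_per_positive"
                    )
                centers.append((cy, cx))
                r2 = (yy - cy) ** 2 + (xx - cx) ** 2
                # truncate at 3σ so spots have compact support and the
                # noiseless background stays exactly constant
                spot = np.where(
                    r2 <= (3 * sigma_px) ** 2,
                    spot_intensity * np.exp(-r2 / (2 * sigma_px**2)),
                    0.0,
                )
                slices[z] += spot
                positions.append((cx * pixel_size, cy * pixel_size, z))
        slices = _noisy(rng, slices, noise_sd)
        grains.append([slices[z] for z in range(n_slices)])
        spot_positions.append(positions)
    truth = SynthTruth(
        scenario="callose",
        seed=seed,
        params={
            "spot_prevalence": spot_prevalence,
            "positive": positive,
            "n_positive": int(positive.sum()),
            "spot_positions_um": spot_positions,
            "spots_per_positive": spots_per_positive,
            "spot_intensity": spot_intensity,
            "spot_sigma_um": spot_sigma_um,
            "slice_interval_um": slice_interval_um,
            "background": background,
            "noise_sd": noise_sd,
        },
    )
    return CalloseSim(grains=grains, pixel_size=pixel_size, truth=truth)
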