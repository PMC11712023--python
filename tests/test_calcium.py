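"""Ratiometric processing and Ca²⁺ spike timing."""

import numpy as np
import pytest

from polartrack import (
    RoiShape,
    RoiTrace,
    TimeLapseStack,
    align_to_spike,
    compare_spike_timing,
    display_rescale_to_first,
    moving_average,
    normalize_to_first,
    ratio_roi_trace,
    ratio_stack,
    simulate_fret_movie,
    spike_time,
)
from polartrack.calcium import SpikeTiming
from polartrack.errors import AnalysisError, InputError, StatisticsError


def _stack(frames):
    return TimeLapseStack(np.asarray(frames, dtype=float), 0.5, 10.0)


def _trace(values, dt_s=10.0, normalization="first_frame"):
    values = np.asarray(values, dtype=float)
    return RoiTrace(
        times=np.arange(len(values)) * dt_s, values=values, normalization=normalization
    )


class TestRatioStack:
    def test_equal_channels_give_scale(self, rng):
        frames = rng.uniform(10, 100, size=(3, 8, 8))
        r = ratio_stack(_stack(frames), _stack(frames), cfp_floor=1.0)
        np.testing.assert_allclose(r.frames, 4000.0)

    def test_double_yfp_gives_8000(self, rng):
        cfp = rng.uniform(10, 100, size=(2, 6, 6))
        r = ratio_stack(_stack(2 * cfp), _stack(cfp), cfp_floor=1.0)
        np.testing.assert_allclose(r.frames, 8000.0)

    def test_zero_cfp_pixel_is_masked(self):
        cfp = np.full((1, 4, 4), 50.0)
        cfp[0, 2, 2] = 0.0
        r = ratio_stack(_stack(np.full((1, 4, 4), 50.0)), _stack(cfp), cfp_floor=1.0)
        assert np.isnan(r.frames[0, 2, 2])
        assert not r.mask[0, 2, 2]
        # masked pixel excluded from ROI means
        roi = RoiShape(kind="rectangle", center=(0.75, 0.75), semi_axes=(0.8, 0.8))
        trace = ratio_roi_trace(r, roi)
        assert trace.values[0] == pytest.approx(4000.0)

    def test_common_scaling_cancels(self, rng):
        yfp = rng.uniform(10, 100, size=(2, 6, 6))
        cfp = rng.uniform(10, 100, size=(2, 6, 6))
        r1 = ratio_stack(_stack(yfp), _stack(cfp), cfp_floor=1.0)
        r2 = ratio_stack(_stack(5 * yfp), _stack(5 * cfp), cfp_floor=5.0)
        np.testing.assert_allclose(r1.frames, r2.frames)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            ratio_stack(_stack(np.ones((2, 4, 4))), _stack(np.ones((3, 4, 4))))


class TestDisplayRescale:
    def test_affine_maps_midpoint_to_half(self):
        frames = np.array([[[2000.0, 6000.0], [4000.0, 4000.0]]])
        r = ratio_stack(_stack(frames / 4000 * 50), _stack(np.full((1, 2, 2), 50.0)), cfp_floor=1.0)
        out = display_rescale_to_first(r)
        assert out.frames[0, 1, 0] == pytest.approx(0.5)

    def test_refuses_double_rescale(self, rng):
        frames = rng.uniform(10, 100, size=(2, 5, 5))
        r = ratio_stack(_stack(frames), _stack(rng.uniform(10, 100, size=(2, 5, 5))), cfp_floor=1.0)
        once = display_rescale_to_first(r)
        with pytest.raises(InputError):
            display_rescale_to_first(once)

    def test_round_trip_recovers_original(self, rng):
        yfp = rng.uniform(10, 100, size=(3, 6, 6))
        cfp = rng.uniform(10, 100, size=(3, 6, 6))
        r = ratio_stack(_stack(yfp), _stack(cfp), cfp_floor=1.0)
        lo, hi = r.frames[0].min(), r.frames[0].max()
        out = display_rescale_to_first(r)
        np.testing.assert_allclose(out.frames * (hi - lo) + lo, r.frames, rtol=1e-10)

    def test_constant_first_frame_rejected(self):
        r = ratio_stack(_stack(np.full((2, 4, 4), 50.0)), _stack(np.full((2, 4, 4), 50.0)), cfp_floor=1.0)
        with pytest.raises(AnalysisError):
            display_rescale_to_first(r)


class TestSpikeTime:
    def test_monotone_rise_not_detected(self):
        trace = _trace(np.linspace(1.0, 2.0, 60))
        assert not spike_time(trace).detected

    def test_unnormalized_trace_rejected(self):
        trace = _trace(np.linspace(5.0, 2.0, 30), normalization="none")
        with pytest.raises(InputError):
            spike_time(trace)

    def test_constructed_trace_peak_at_five_minutes(self):
        """Baseline 1.0, fall to 0.6 over 1–3 min, bump at 5 min, slow rise."""
        t = np.arange(0, 900, 10.0)
        v = np.ones_like(t)
        falling = (t >= 60) & (t < 180)
        v[falling] = 1.0 - 0.4 * (t[falling] - 60) / 120.0
        after = t >= 180
        v[after] = 0.6 + 0.0005 * (t[after] - 180)
        v += 0.25 * np.exp(-((t - 300.0) ** 2) / (2 * 8.0**2))
        timing = spike_time(_trace(v))
        assert timing.detected
        assert timing.spike_time == pytest.approx(5.0, abs=10.0 / 60.0)
        assert timing.drop_time < timing.spike_time

    def test_simulator_recovery_with_default_noise(self):
        sim = simulate_fret_movie(spike_time_min=4.87, seed=1)
        r = ratio_stack(moving_average(sim.yfp, 4), moving_average(sim.cfp, 4))
        trace = normalize_to_first(ratio_roi_trace(r, sim.roi))
        timing = spike_time(trace)
        assert timing.detected
        assert abs(timing.spike_time - 4.87) <= 10.0 / 60.0 + 1e-9

    def test_invariant_to_appending_post_spike_samples(self):
        sim = simulate_fret_movie(noise_sd=0.0, seed=0, duration_min=30.0)
        sim_long = simulate_fret_movie(noise_sd=0.0, seed=0, duration_min=45.0)
        times = []
        for s in (sim, sim_long):
            r = ratio_stack(moving_average(s.yfp, 4), moving_average(s.cfp, 4))
            trace = normalize_to_first(ratio_roi_trace(r, s.roi))
            times.append(spike_time(trace).spike_time)
        assert times[0] == pytest.approx(times[1])


class TestAlignToSpike:
    def _timing(self, minute):
        return SpikeTiming(spike_time=minute, drop_time=minute - 1, peak_value=1.0, detected=True)

    def test_spike_at_anchor_unchanged(self):
        trace = _trace(np.ones(20))
        out = align_to_spike([trace], [self._timing(5.0)], anchor_min=5.0)[0]
        np.testing.assert_allclose(out.times, trace.times)

    def test_late_spike_shifts_back(self):
        trace = _trace(np.ones(20))
        out = align_to_spike([trace], [self._timing(7.0)], anchor_min=5.0)[0]
        np.testing.assert_allclose(out.times, trace.times - 120.0)

    def test_undetected_spike_raises(self):
        trace = _trace(np.ones(20))
        bad = SpikeTiming(float("nan"), float("nan"), float("nan"), False)
        with pytest.raises(AnalysisError, match="0"):
            align_to_spike([trace], [bad])

    def test_cohort_aligns_to_common_anchor(self):
        """Spikes spread over 3–7 min all land at 5 min after alignment."""
        rng = np.random.default_rng(3)
        traces, timings = [], []
        for _ in range(8):
            s = simulate_fret_movie(spike_time_min=float(rng.uniform(3, 7)), seed=int(rng.integers(2**31)))
            r = ratio_stack(moving_average(s.yfp, 4), moving_average(s.cfp, 4))
            trace = normalize_to_first(ratio_roi_trace(r, s.roi))
            timing = spike_time(trace)
            assert timing.detected
            traces.append(trace)
            timings.append(timing)
        aligned = align_to_spike(traces, timings, anchor_min=5.0)
        for shifted, orig, timing in zip(aligned, traces, timings):
            spike_idx = int(np.argmin(np.abs(orig.times / 60.0 - timing.spike_time)))
            # after the shift, the spike sample sits exactly at the anchor
            assert shifted.times[spike_idx] / 60.0 == pytest.approx(5.0)


class TestCompareSpikeTiming:
    def _cohort(self, times):
        return [SpikeTiming(t, t - 1.0, 1.2, True) for t in times]

    def test_identical_groups_p_one(self):
        g = self._cohort([4.0, 5.0, 6.0])
        res = compare_spike_timing(g, g)
        assert res["p"] == pytest.approx(1.0)

    def test_matched_timing_distributions_usually_not_significant(self):
        """Cohorts drawn from the WT-like and mutant-like spike-time
        distributions (means 4.87 vs 5.10 min) rarely separate at n=20."""
        rng = np.random.default_rng(11)
        n_sig = 0
        for _ in range(20):
            a = self._cohort(rng.normal(4.87, 1.70, size=20))
            b = self._cohort(rng.normal(5.10, 1.69, size=20))
            if compare_spike_timing(a, b)["p"] < 0.05:
                n_sig += 1
        assert n_sig <= 4

    def test_separated_distributions_significant(self):
        rng = np.random.default_rng(12)
        a = self._cohort(rng.normal(5.0, 1.0, size=20))
        b = self._cohort(rng.normal(10.0, 1.0, size=20))
        assert compare_spike_timing(a, b)["p"] < 1e-3

    def test_too_few_detected_rejected(self):
        with pytest.raises(StatisticsError):
            compare_spike_timing(self._cohort([5.0]), self._cohort([5.0, 6.0]))
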