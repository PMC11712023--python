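"""Peak-to-peak lag between two co-polarizing reporters.

Ten simulated grains each carry two oscillating reporters at the polarized
site: the reference channel (a Ca2+ reporter) leads, the response channel
follows 2.74 min later.  Peaks are detected on first-point-normalized
5-µm-site ROI traces and matched reference→response within a 5-min window.
"""

import numpy as np

from polartrack import (
    detect_local_peaks,
    normalize_to_first,
    peak_lag,
    roi_mean_trace,
    simulate_grain_dual_channel,
)

all_lags = []
for seed in range(10):
    sim = simulate_grain_dual_channel(lag_min=2.74, seed=seed)
    ref = normalize_to_first(roi_mean_trace(sim.channel1, sim.site_roi))
    resp = normalize_to_first(roi_mean_trace(sim.channel2, sim.site_roi))
    est = peak_lag(detect_local_peaks(ref), detect_local_peaks(resp), window_min=5.0)
    all_lags.extend(est.paired_lags)
    print(f"grain {seed}: {est.n_pairs} matched pairs, mean lag {est.mean_lag:.2f} min, "
          f"{est.unmatched_reference} unmatched reference peak(s)")

print(f"\npooled over {len(all_lags)} pairs: "
      f"{np.mean(all_lags):.2f} +/- {np.std(all_lags, ddof=1):.2f} min (mean +/- SD)")
# At 1-min sampling each peak time is frame-quantized, so individual lags
# scatter around the injected 2.74 min; the pooled mean recovers it.
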