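"""Kymograph tip-distance scoring of a growing pollen tube.

Simulates a 150-frame (3-s interval) movie of an elongating tube carrying a
tip-focused fluorophore band 4.17 µm behind the apex, builds the kymograph
along the tip-first midline, and scores the average distance of the peak
signal from the tip over 29 overlapping 10-px bins stepped 5 px.
"""

from polartrack import (
    binned_tip_distances,
    build_kymograph,
    moving_average,
    simulate_tube_movie,
)

sim = simulate_tube_movie(band_distance_um=4.17, seed=1)
smoothed = moving_average(sim.stack, 3)  # 3×3 noise reduction before the kymograph
kymo = build_kymograph(smoothed, sim.paths)
result = binned_tip_distances(kymo, bin_height_px=10, step_px=5)

print(f"kymograph: {kymo.n_rows} rows x {kymo.matrix.shape[1]} columns")
print(f"bins: {result.n_bins}")
print(f"average distance from tip: {result.average_distance:.2f} um "
      f"(injected {sim.truth.params['band_distance_um']} um)")
# The recovered distance is pixel-quantized (0.2 um/px), so 4.17 um reads
# back as 4.2 um; 150 frames always give 29 overlapping bins.
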