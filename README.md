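# polartrack

Quantification of pollen polarization dynamics from fluorescence
time-lapse imaging and fractionation proteomics.

When an *Arabidopsis* pollen grain lands on a stigma it hydrates, builds a
polarized "germination plaque" at the future tube-emergence site, fires a
brief cytosolic Ca²⁺ spike, and sends out a tube whose tip concentrates
secretory vesicles and polarity factors. Studies of this process lean on a
small set of bespoke quantifications that are usually performed by hand in
imaging GUIs. `polartrack` implements them as a tested, scriptable library
for cell biologists working on tip growth and pollen germination:

- **Kymograph tip-distance scoring** — build a time × distance-from-tip
  kymograph along the tube midline (line width 10 px, 3×3 pre-smoothing),
  slide a 10-px bin down the time axis in 5-px steps (150 frames → 29
  overlapping bins), score each bin's peak-intensity distance from the tip,
  and average: the *average distance from tip* statistic used to compare
  drug treatments (e.g. latrunculin B vs control) by two-tailed Student's
  *t*-test.
- **Ratiometric Ca²⁺ spike timing** — per-pixel (YFP/CFP) × 4000 ratio
  images from a FRET sensor (YC3.6-style) after 4×4 smoothing, 5-µm-ROI
  traces normalized to the first time point, detection of the first spike
  after the rapid hydration drop, and spike-anchored alignment (spike at
  5 min) for cohort overlays.
- **Dual-reporter peak-lag estimation** — oscillation peaks of two
  co-polarizing reporters at the polarized site, matched
  reference→response within a window; the lag statistic behind "reporter B
  peaks *x* min after each Ca²⁺ peak".
- **Callose-spot scoring** — maximum-intensity projection of 3-slice
  z-stacks, robust thresholding (median + 5·MAD), 8-connected component
  counting, and the percentage of grains with ≥ 1 spot.
- **Co-migration screening** — Pearson correlation of each protein's
  sucrose-fraction abundance profile against a tagged bait (strictly
  r > 0.8 passes), co-IP uniqueness set logic, and the cross-reference of
  both evidence lines.

Because the underlying microscopy data of such studies is rarely deposited,
every analysis ships with a seeded synthetic-data generator
(`simulate_*`) that renders the corresponding raw input with known ground
truth — injected band distance, spike time, peak lag, planted co-migrator
set, spot prevalence — so parameter recovery is testable end to end.

## Worked example

```python
from polartrack import (simulate_tube_movie, moving_average,
                        build_kymograph, binned_tip_distances)

sim = simulate_tube_movie(band_distance_um=4.17, seed=1)   # 150 frames, 3 s
kymo = build_kymograph(moving_average(sim.stack, 3), sim.paths)
result = binned_tip_distances(kymo, bin_height_px=10, step_px=5)
print(kymo.n_rows, result.n_bins, round(result.average_distance, 2))
```

prints

```
150 29 4.2
```

— a 150-frame movie yields a 150-row kymograph and exactly 29 overlapping
bins; the injected 4.17-µm tip-band distance reads back as 4.20 µm because
recovery is quantized to the 0.2-µm pixel grid. The other capabilities are
demonstrated the same way in `examples/` (one short script each):
`tube_tip_distance.py`, `calcium_spike_timing.py` (spike injected at
4.87 min, recovered at 4.83 min with 10-s frames), `dual_reporter_lag.py`
(2.74-min lag, pooled recovery 2.70 ± 0.46 min over 10 grains),
`comigration_screen.py` (340/3046 planted co-migrators recovered with zero
false positives), and `callose_spot_scoring.py`.

A thin CLI wraps the same stages:

```sh
polartrack simulate --scenario tube --seed 1 --out sim/
polartrack kymo --stack sim/tube.tif --path sim/path.csv --out kymo/
polartrack stats --chisq 60 40
```

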