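# flickermap

Label-free intensity-fluctuation analysis of high-speed microscopy
recordings of hair cells: per-pixel temporal-SD "activity" maps, hotspot
detection, background-normalized ΔI/I traces, sub-pixel hair-bundle
tracking, maximum shifted-correlation statistics, and frequency-sweep
phase-locking curves — together with a ground-truth-annotated simulator
of the recordings, so every stage is testable without microscope data.

## Who this is for

Hair cells of the inner ear transduce nanometer-scale hair-bundle
deflections into electrical signals.  Wide-field bright-field imaging at
~1000 frames/s reveals localized light-intensity fluctuations inside the
cell body ("hotspots") that accompany spontaneous and driven bundle
motion.  This package implements the analysis chain for such recordings:
it is aimed at auditory/vestibular biophysics labs who record 16-bit TIFF
stacks (e.g. 108.3 nm/px at 1000 fps) and want a reproducible pipeline
from raw frames to correlation and entrainment statistics.

## The statistics at the core

For a recording of N frames **I**₁ … **I**_N, the pipeline computes the
per-pixel temporal mean and the population SD of the (optionally
background-normalized) intensity,

    μ = (1/N) Σₖ Iₖ        σ = sqrt( (1/N) Σₖ (Iₖ − μ)² )

and treats σ as an activity heatmap.  Supra-threshold regions
(σ > mean + k·SD within the analysis mask, 8-connected, k = 3 by
default) become hotspots.  Each hotspot's trace is the ROI-mean intensity
normalized per frame to a background ROI,

    ΔI/I[k] = (⟨Iₖ⟩_roi − ⟨Iₖ⟩_bg) / ⟨Iₖ⟩_bg .

Similarity to the bundle's displacement trace x(t) (tracked to sub-pixel
precision from its intensity ridge) is scored by the maximal Pearson
coefficient over all integer time shifts within a lag window; pairs with
max-shift correlation ≥ 0.2 (a conservative, ~4-null-SD threshold) count
as correlated.  Entrainment by a stepped frequency sweep is quantified by
the phase-locked response: per 10-cycle segment at frequency f, the
amplitude 2|Σ_t x_t e^(−i2πf t/fs)|/M of the trace's component at exactly
the stimulus frequency.

## Worked example

`examples/03_bundle_correlation.py` simulates a 3 s control recording
(128×128 px, 1000 fps) with two somatic hotspots driven by the bundle's
spontaneous 15 Hz oscillation with a 20 ms lag, then runs the full
pipeline:

```
bundle trace: rms 16.8 nm
  hotspot 0: max corr 0.638 at lag 20 samples (20 ms) -> correlated: True
  hotspot 1: max corr 0.638 at lag 20 samples (20 ms) -> correlated: True
  control ROI outside the cell: max corr 0.053 -> correlated: False
```

The tracker recovers the bundle's ~17 nm rms motion, both hotspots clear
the 0.2 correlation threshold at exactly the injected 20 ms lag, and an
ROI outside the cell stays at the noise level.  The other examples cover
activity maps (`01`), hotspot detection and ΔI/I spectra (`02`),
suppression statistics — cutting the hotspot modulation to 35% appears as
a −64.9% spectral-peak change while the salicylate condition changes
nothing (`04`) — and sweep phase-locking curves at 50 vs 10 nm drive
(`05`).

A thin CLI mirrors the library for shell use:

```sh
flickermap simulate --config scene.yaml --condition control --seed 7 --out data/
flickermap hotspots --stack data/stack_z0.tif --background 20,11,5 --out hotspots.csv
flickermap correlate --a bundle.csv --b hotspot.csv
```

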