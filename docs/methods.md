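# Methods

This note records the models, conventions, parameter choices and known
limitations behind `flickermap`, at the level of detail a maintainer or a
reviewer of results produced with it would want.

## Activity statistics

The activity map uses the *population* temporal SD, σ = sqrt((1/N)Σ(Iₖ−μ)²),
not the n−1 sample estimator — the map is a descriptive image statistic,
and at the N ≥ 1000 frames typical of these recordings the two differ
negligibly; the population form is the one used in this analysis
tradition.  "Normalized intensity" is implemented as optional per-frame
division by the spatial mean of a designated background region (whole
frame if none), which cancels global illumination drift exactly (a pure
per-frame multiplicative gain leaves σ unchanged; this is a tested
invariant).  `ActivityMap.normalized` records which mode produced a map.

Hotspot detection is a reproducible stand-in for what is, in practice,
often a manual selection from the heatmap: threshold at
mean(σ|mask) + k·SD(σ|mask) with k = 3, 8-connected components, minimum
area 4 px, ROI disks of radius 5 px (≈0.54 µm at 108.3 nm/px), ranked by
peak σ with lexicographic (row, col) tie-breaks so output order is total.
The analysis mask should exclude the bundle ridge, whose motion dominates
σ; `soma_analysis_mask` does this for simulated scenes.

ΔI/I extraction follows fluorescence-imaging convention: ROI disk mean
minus per-frame background disk mean, divided by the background mean.
The ROI and background disks must be disjoint, and the background should
lie outside the cell.  Note that a disk larger than the hotspot dilutes
the recovered modulation by the blob/disk area ratio (~0.3 for the
default geometry); this scales out of every ratio statistic (percent
changes, phase-lock ratios) but matters when reading ΔI/I amplitudes as
absolute gains.

## Bundle tracking

The tracker is a floor-subtracted projection-profile centroid with an
optional 1-D Gaussian-fit refinement.  Per frame: subtract the ROI's 10th
percentile (robust to shot noise, and exactly cancels any spatially
uniform offset — a tested invariant); average the residual into integer
bins along the motion axis, normalizing by the bin's pixel count so a
circular ROI does not overweight central bins; keep bins above 20% of
the profile peak (rejecting the background-noise residual, which would
otherwise pull the centroid toward the ROI center by tens of percent);
take the intensity-weighted centroid of the kept bins.  Displacement is
(position − baseline) × pixel pitch; the baseline is the mean position
(or the first frame).  On a noiseless Gaussian ridge this estimator is
exact to machine precision for integer-pixel steps and linear to within
2% over ±2 px; with default camera noise a 60 nm, 10 Hz motion (0.55 px
amplitude) is recovered to a few percent.  The Gaussian-fit mode
least-squares fits the same binned profile and falls back to the
centroid (with a warning) on non-convergence.  Whether the original
recordings were tracked with edge profiles or centroids is not
determinable from published descriptions; this implementation is the
standard centroid-family tracker for such data.

## Spectra, peaks, and correlation

Amplitude spectra are one-sided with the convention a(f₀) = A for an
on-bin sinusoid of amplitude A: a = 2|rfft(x−x̄)·w|/Σw, with the DC (and
even-length Nyquist) bin halved, no zero-padding (resolution fs/M), and
optional Hann window corrected by its coherent gain.  "Max" normalization
divides by the spectral peak (peak exactly 1), the form used when
comparing bundle and hotspot spectra.  Parseval holds in this convention
as Σa² · M/2 = Σ(x−x̄)² for on-bin compositions and is tested as such.

`max_shift_correlation(a, b)` scans integer lags ℓ ∈ [−L, +L], comparing
a[t] with b[t+ℓ] (positive lag = b trails a), re-centering and re-scaling
each overlap; implemented with one FFT cross-correlation plus prefix
sums (O(n log n)) and verified against a brute-force per-lag loop.
Unbounded shifts would let short overlaps produce degenerate
correlations, so L defaults to min(n/2, 500) with a minimum overlap of
half the shorter trace; zero-variance overlaps are skipped.  The signed
maximum is returned (an absolute-value mode exists); ties break toward
the smallest |lag|, then the negative lag.  The correlated/uncorrelated
threshold is 0.2 inclusive, adopted as a constant from prior calibration
of bundle-pair statistics (~4 SDs above a noise-pair null); a 1000-rep
Monte-Carlo in the test suite confirms that for independent stationary
noise pairs (n = 5000, L = 500) even the 99.99th percentile of the
max-shift correlation stays below it.

## Phase-locked response

Sweeps are stepped: each of the 30 (default) log-spaced frequencies from
1 to 100 Hz is held for exactly 10 cycles, segments tile the recording
(closed-open intervals), and segment lengths round to the nearest sample
with a 16-sample floor.  The response at step i is the single-frequency
discrete Fourier projection 2|Σ x_t e^(−i2πf_i t/fs)|/M of the
mean-subtracted segment — identical to the FFT-bin amplitude on
integer-cycle segments, and robust (sub-percent error) when rounding
makes the cycle count slightly non-integer, which is why projection was
chosen over nearest-bin lookup.  Whether the original 10-cycle portions
tiled or overlapped the sweep is not stated anywhere; tiling is assumed.
Dispersion envelopes across repeat sweeps are min–max
(`aggregate_curves`); single sweeps report none.

## The synthetic-recording generator

The simulator emulates what the analysis assumes about real recordings:
a static bright-field scene (soma polygon at 1.15× a 1000-count
background), a bundle rendered as a Gaussian intensity ridge (SD 2 px,
amplitude 800 counts) translating along the motion axis, somatic hotspots
as isotropic Gaussian blobs (SD = radius/2) whose amplitude is
background × ΔI/I-modulation, camera shot noise (exact Poisson below 50
counts, Gaussian with variance counts/gain above — indistinguishable
there and much faster), Gaussian read noise, and saturating quantization
to 8/16 bits.  Frames are rendered in fixed 1024-frame chunks so long
sweeps never hold a float copy of the full stack; chunking is part of the
deterministic RNG stream, so outputs are bit-reproducible for a seed.

Parameter defaults and why:

- **Camera** — 1000 fps, 108.3 nm/px, 16-bit, 0.46 e⁻/count, 1.6 counts
  read noise: an ORCA-Flash4.0-class sCMOS at 60× as used for such
  recordings.
- **Bundle** — two-state relaxation oscillation at 15 Hz, ±10 nm
  (≈20 nm peak-to-peak), gamma-jittered dwell times with CV 0.1,
  duty cycle 0.5, smoothed by a 2 ms low-pass, plus 3 nm Gaussian
  position noise.  Bullfrog saccular bundles oscillate in the
  ~5–50 Hz, tens-of-nm range with square-wave-like limit cycles; the
  sinusoid mode exists for analytic tests.  CV 0.1 makes the oscillator
  coherent enough that a 3 s recording localizes its spectral peak to a
  single FFT bin; real bundles are often noisier (dwell CVs up to ~1),
  which trades spectral sharpness for faster decorrelation — see
  Limitations.
- **Entrainment** — binary threshold at 25 nm stimulus amplitude,
  between the non-effective 10 nm and effective 50 nm drives; above it
  the bundle follows the stimulus waveform plus position noise, below it
  it remains spontaneous.  A full Arnold-tongue model is out of scope.
- **Hotspots** — optical gain 0.004 ΔI/I per nm of bundle displacement
  (the true gain of the biological coupling is unknown; this value makes
  a 10 nm oscillation a ~4% ΔI/I modulation, the few-percent scale seen
  in real hotspot traces, and yields detection SNRs where the pipeline
  operates comfortably rather than at its edge), configurable lag,
  per-depth attenuation (1.0 → 0.35 across six axial sections, emulating
  the falloff of fluctuation amplitude with depth), and a suppression
  factor in [0, 1] standing in for tip-link destruction.
- **Conditions** — `control` and `salicylate` are identical by
  construction (prestin block does not touch these dynamics);
  `bapta` zeroes every hotspot's modulation and disables entrainment.
  Conditions sharing a master seed reuse the same bundle/hotspot/camera
  RNG streams, so control-vs-treated comparisons are paired exactly as
  in the real experiments.
- **Sweep realization** — stepped discrete frequencies (default 30
  log-spaced steps, 1–100 Hz, 10 cycles each), each segment starting at
  phase zero.  Whether the original sweep was stepped or continuous, and
  its spacing, is not stated; stepped-log is the stand-in.

## What the simulator does and does not emulate

It reproduces the statistical structure the pipeline relies on —
shot-noise-limited σ floors, localized coherent modulation, lags, depth
attenuation, paired pharmacology, stimulus protocols.  It does **not**
model the optical PSF beyond per-section attenuation, stereocilia fine
structure, focus drift, photobleaching, sample motion, or non-Poisson
camera artifacts.  Passing tests therefore demonstrate that the analysis
recovers what it claims from data obeying its assumptions, not that
those assumptions hold for any particular microscope.

## Problem sizes and numerical choices

The test suite and acceptance script run the end-to-end scenarios at
3000 frames × 128×128 px (spontaneous/pharmacology) and full-length
1–100 Hz sweeps (~67,500 frames) at 64×64 px — sizes chosen so a
complete run stays in the minutes range on one CPU while every stage
still operates far above its detection limits.  Statistics accumulate in
float64 with two passes (exact mean, then moments); rendering uses
float32 intermediates, which leaves quantization (±0.5 count) as the
dominant rounding.  Degenerate inputs (flat tracker profiles, zero
background means, zero-variance overlaps, empty masks or bands,
all-zero spectra under max normalization) raise `ValueError` rather than
returning NaNs.

## Known limitations

- The detection rule, ROI shapes and the 0.2 threshold are adopted
  conventions; the threshold's original null calibration is reproduced
  only qualitatively (Monte-Carlo consistency), not re-derived.
- With the default dwell CV of 0.1 the spontaneous oscillator stays
  partially coherent across a 10-cycle sweep segment, so the weak-drive
  phase-lock curve shows a genuine bump at the step nearest the
  spontaneous frequency (strong/weak response ratios of ~4–10× there,
  vs 20–700× elsewhere).  A noisier oscillator suppresses the bump but
  broadens spectral peaks; both regimes are reachable through
  `BundleModel.dwell_noise_cv`.
- ΔI/I amplitudes are diluted by the ROI/blob geometry (see above);
  absolute-gain inference from ΔI/I requires matching the ROI to the
  hotspot extent.
- The tracker assumes a single dominant ridge in its ROI; two bundles or
  a probe shadow in the ROI violate it.
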