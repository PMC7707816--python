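# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic benchmarks do and do not show
about real data.

## Imaging model

A synthetic volume is a set of channels of identical shape `(z, y, x)`
with 8-bit intensities, voxel size 0.1 × 0.1 µm in xy and 0.2 µm in z —
the geometry of high-NA confocal stacks of immunostained brainstem tissue.
Each bouton is rendered as an anisotropic 3D Gaussian punctum
(σ_xy = 0.3 µm, σ_z = 0.4 µm by default). These widths are generator
defaults for a sub-micron terminal at this sampling, not measured values;
they are exposed in `BoutonPopulation`. Puncta are rendered out to 4σ and
placed by rejection sampling with a minimum mutual separation (default
2 µm) and a margin that guarantees every target bouton admits a full VOI.

A class-true marker channel receives `α · (ρ·s + sqrt(1−ρ²)·e)` inside the
punctum, where `s` is the Vgat punctum profile, `e` is independent voxel
noise of matched scale and `ρ` is the marker co-localization strength
(default 1: the marker is a scaled copy, expected voxelwise R² → 1).
A class-false marker receives only background, or optionally a small
"bleed" fraction of the punctum to populate the 0.1–0.4 unclassified band.
Gaussian background noise is added last, then the volume is clipped to
[0, 255] and rounded.

Not modeled: PSF convolution, spectral bleed-through between detectors,
depth-dependent attenuation, tile stitching. Consequently the benchmarks
show that the scoring/classification pipeline is correct *given* punctate,
optically clean data; they do not measure robustness to optical artifacts.

## Co-localization scoring

* **Detection.** Gaussian smoothing (σ = 1 voxel in xy, 0.5 in z), then 3D
  local maxima above `background + 4·SD` (background estimated volume-wide
  by median/MAD, robust because puncta occupy few voxels), with an
  anisotropic exclusion neighborhood from the 0.5 µm minimum separation.
  Maxima whose VOI would cross a volume face are dropped rather than
  padded, so no voxels are fabricated.
* **VOI.** `round(1.5/0.1) × round(1.5/0.1) × round(1.0/0.2)` =
  15 × 15 × 5 voxels centered on the detected maximum.
* **Edge masking.** Shell voxels are those whose center lies within
  0.25 µm of any VOI face, measured as physical distance on all three axes
  (2 voxels per xy face, 1 section per z face at default geometry). Only
  shell voxels whose Vgat intensity exceeds
  `background mean + k·background SD` (k = 2 by default) are excluded;
  below-threshold shell voxels are retained.
* **Score.** OLS regression of marker on Vgat over included voxels; R² is
  reported. A negative slope returns exactly 0.01; a slope of exactly zero
  returns the computed R² (≈ 0), since a flat marker is uninformative but
  not anticorrelated. A constant marker (zero variance) scores 0. Zero
  Vgat variance or fewer than 10 included voxels raise errors rather than
  produce a number. For simple OLS, R² equals the squared Pearson
  correlation and is symmetric in the regression direction; only the sign
  of the slope (hence the floor) depends on the choice of regressing
  marker on Vgat, which is fixed and documented for reproducibility.
* **Classification.** Strict inequalities at 0.4/0.1; scores in between
  are reported as "unclassified" rather than silently pooled. Scores for
  absent channels are missing, never zero.

## Electrophysiology model

Quantal kernel `q(t) = A_norm·(1 − e^(−t/τ_r))·e^(−t/τ_d)`, sampled at
20 kHz and peak-normalized so its maximum (at
`t* = τ_r·ln(1 + τ_d/τ_r)`) equals the quantal amplitude. Default
kinetics order glycine faster and larger than GABA (glycine: 50 pA,
τ_r = 0.3 ms, τ_d = 5 ms; GABA: 30 pA, τ_r = 1 ms, τ_d = 15 ms); these
are generator choices respecting the qualitative ordering, not measured
constants. Amplitudes are lognormal with CV 0.3 by default.

Latency models: synchronous = Gaussian(μ = 1 ms, σ = 0.3 ms) truncated at
zero; asynchronous = 2 ms delay + Exponential(τ = 50 ms for single
stimuli, 150 ms in the train scenario) — within the tens-to-hundreds of
milliseconds over which asynchronous inhibitory release persists. Per
stimulus k the expected quantal count is `m·f^(k−1)` (Poisson, or
deterministic in the `fixed` count mode); asynchronous latencies are drawn
relative to their own stimulus and may extend past later ones, so
per-stimulus exponential release rates sum across a train — this single
mechanism produces the accumulating, non-decaying charge transfer of
asynchronous trains.

Synaptic current scales with driving force `(V_hold − V_rev)/(−60 mV)` and
is therefore zero at the 0 mV chloride reversal; with a high-chloride
internal at −60 mV currents are inward (negative), and all analyzers work
on magnitudes. Gap-junction bursts (three biphasic spikelets 2 ms apart by
default; shape configurable) are added without driving-force scaling,
since currents from electrically coupled neighbors do not reverse at
0 mV — the property both cleanup strategies exploit.

Noise is white Gaussian passed through a 4-pole Butterworth low-pass at
4 kHz (standing in for an amplifier Bessel filter; `filtered_noise_sd`
converts the white SD to the post-filter SD). The filter is applied to the
noise only: quantal kernels are already smooth on the 4 kHz scale, and
keeping the signal path unfiltered preserves the exact identity
`trace = Σ kernels + noise`, which the superposition tests verify
bit-for-bit at zero noise.

Not modeled: conductance-based membranes, subthreshold oscillations,
series-resistance filtering, stimulus artifacts beyond optional blanking.

## Evoked analysis choices

* Jitter uses the sample SD (n−1) of per-trial peak times, found on
  0.5 ms boxcar-smoothed trials to suppress single-sample noise peaks.
* Half-rise is measured from stimulus onset on the averaged trace, first
  50%-of-peak crossing, linear interpolation between samples.
* Decay is a single-exponential least-squares fit (offset fixed at the
  post-response baseline of the baseline-subtracted trace, i.e. zero) from
  the peak to the first 10%-of-peak crossing or the window end.
  Recommended response windows: 100 ms for synchronous inputs, 500 ms for
  asynchronous ones.
* The no-response criterion compares the averaged peak with the
  baseline-noise SD at a default factor of 5. A factor of 3 is routinely
  exceeded by noise alone because the peak is a maximum over thousands of
  correlated samples; 5 keeps a silent synapse flagged silent (and an
  absent pharmacological component at ratio exactly 0) while remaining far
  below any real response in the benchmark scenarios.
* Component subtraction computes kinetics on `mean(control) −
  mean(after drug)` and on the residual average; a component failing the
  no-response test contributes 0 to amplitude and charge ratios. Charge is
  additive by linearity of the integral, which the tests check exactly.
* Burst rejection drops trials whose maximum normalized sliding
  correlation with the burst template exceeds 0.6 (template supplied or
  estimated by aligning supra-threshold deflections in 0 mV sweeps).
  Burst subtraction scales the 0 mV average by a least-squares fit over a
  synaptic-free window (default: the pre-stimulus period) before
  subtracting from the −60 mV average.
* Train charge is integrated per inter-stimulus window (one ISI for the
  last stimulus) on the averaged, baseline-subtracted response and
  normalized to stimulus 1. A kernel tail of a few percent leaks into the
  following window at 50 Hz with τ_d = 5 ms; with the deterministic-count
  depressing scenario this keeps recovered plasticity within ~3% of
  `f^(k−1)`.

## Mini detection choices

Detection runs on a zero-phase 1 kHz low-passed copy. Candidate onsets are
rising-edge crossings of the first derivative above `deriv_k` (default 5)
times a robust scale (MAD × 1.4826); candidates are confirmed when the
baseline-subtracted 10 ms integral exceeds `integ_k` (default 3) ×
(smoothed-noise SD × window). Onsets closer than 5 ms merge into the
earlier one; a second event is accepted once the derivative re-crosses
after a sub-threshold gap. Amplitude is the peak within 10 ms of onset on
the lightly filtered trace against a local (3 → 0.5 ms pre-onset)
baseline; decay is the interpolated time from peak to 1/e of peak, with
the search capped 200 ms past the peak so detection stays linear in trace
length. Threshold values are implementation choices exposed in
`MiniDetectParams`.

## Scenario defaults and problem sizes

Named scenarios (`synaptiq.scenarios`) fix the study conditions:
quantal content 10 per stimulus for single-stimulus scenarios; 50 Hz × 10
trains starting at 50 ms; the depressing train uses deterministic counts
(content 400, f = 0.8, amplitude CV 0.2) because it serves as the
noiseless plasticity reference, and Poisson count fluctuations are
themselves noise; the asynchronous train uses content 40 with τ = 150 ms.
Benchmarks use 50 trials for single-input kinetics, 300 trials for the
asynchronous train, 600 s at 2 Hz for the mini benchmark, and a
512 × 512 × 15 voxel volume with 200 boutons (30% GlyT2⁺, peak/background
≈ 9) for classification recovery. Passing these benchmarks demonstrates
estimator correctness under the stated generative model — not robustness
to optical aberrations, electrode drift, or non-quantal currents, which
the generators deliberately do not produce.

## Known limitations

* The scorer offers regression R² only (no Manders/Costes style metrics),
  matching its intended use.
* Decay estimation assumes a single exponential; biexponential decays are
  reported as a compromise constant.
* The burst template estimator needs at least one clear burst per 0 mV
  trial it uses; with none it raises instead of guessing.
* Region summaries take region labels as given (label image or per-bouton
  strings); no atlas registration is attempted.
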