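# synaptiq

Tools for two measurement problems that arise when characterizing
inhibitory synaptic inputs in brainstem circuits:

1. **Bouton co-localization in 3D fluorescence volumes.** Inhibitory
   presynaptic terminals appear as sub-micron Vgat-positive puncta in
   confocal z-stacks. Whether a bouton is glycinergic (Syp-TdT reporter),
   carries fast synaptotagmins (Syt1/2 immunostain), or belongs to a
   virally-labeled projection (ChR2-YFP) is decided per bouton by how well
   the marker intensity tracks the Vgat intensity voxel-for-voxel.
2. **Kinetics of inhibitory postsynaptic currents (IPSCs).** Whether a
   synapse releases transmitter synchronously (tightly stimulus-locked) or
   asynchronously (persisting for tens to hundreds of milliseconds) shows
   up in trial-to-trial jitter of the IPSC peak, rise and decay times,
   charge transfer during stimulus trains, and miniature-event statistics.

Because raw microscopy and patch-clamp data of this kind are rarely
deposited, the package includes first-class synthetic generators for both
domains — volumes with known bouton classes, and quantal IPSC recordings
with known release statistics — so every analysis stage is validated
against ground truth.

## The core methods

**Co-localization score.** Around each detected bouton centroid a fixed
1.5 × 1.5 × 1 µm volume of interest (VOI; 15 × 15 × 5 voxels at
0.1 × 0.1 × 0.2 µm) is extracted. Shell voxels (outer 0.25 µm) whose Vgat
intensity exceeds `background + k·SD` are excluded as neighbor
contamination. Marker intensity is regressed on Vgat intensity over the
included voxels (ordinary least squares) and the coefficient of
determination R² is the score; for anticorrelated signals (fitted slope
< 0) the score is set to 0.01. Classification uses fixed thresholds:
GlyT2⁺ if R²(Vgat, Syp-TdT) > 0.4, GlyT2⁻ if < 0.1 (in-between is
unclassified); Syt1/2⁺ and YFP⁺ if the corresponding R² > 0.4.

**IPSC kinetics.** Quantal currents are modeled as
`q(t) = A·(1 − e^(−t/τ_r))·e^(−t/τ_d)` (peak-normalized). Per stimulus,
a Poisson number of quanta is released with latencies drawn from a
truncated Gaussian (synchronous) or delayed exponential (asynchronous).
The analyzers compute: jitter = SD (n−1) of per-trial peak times;
half-rise = time from stimulus to 50% of peak on the averaged trace;
decay τ = single-exponential fit from peak to 10% of peak; charge =
trapezoidal integral (pA·s = pC); drug-sensitive components by
`mean(control) − mean(after drug)`; per-stimulus charge in 50 Hz trains
normalized to the first stimulus; and miniature IPSCs by a first-derivative
threshold confirmed with a 10 ms integration threshold. Gap-junction burst
contamination is handled by template-correlation rejection or by scaled
subtraction of sweeps recorded at the 0 mV chloride reversal potential.

## Worked example

```sh
python examples/evoked_kinetics.py
```

prints (seed 1, 50 trials per condition):

```
 sync: jitter   0.31 ms | half-rise  1.28 ms | decay tau    8.9 ms | peak  391.3 pA | charge  4.285 pC
async: jitter  28.42 ms | half-rise  7.79 ms | decay tau   59.7 ms | peak   60.9 pA | charge  5.308 pC
```

The synchronous input has sub-millisecond jitter and a fast rise; the
asynchronous input shows jitter of tens of milliseconds with slow rise and
decay — the quantitative signature used to tell apart input sources with
and without fast synaptotagmins. The other examples
(`coloc_scoring.py`, `component_subtraction.py`, `train_dynamics.py`,
`mini_detection.py`) each exercise one capability end to end and print the
quantities with a one-line interpretation.

A thin CLI wraps the same functions
(`synaptiq simulate-volume | detect-boutons | score-coloc | report |
simulate-traces | analyze-evoked | detect-minis | run`); `synaptiq run`
executes a YAML-configured pipeline (see `examples/configs/`) and writes a
manifest sufficient to reproduce the run bit-for-bit.

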