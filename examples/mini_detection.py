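"""Detect miniature IPSCs with the derivative + integration threshold.

Simulates a 120 s recording of Poisson minis riding on band-limited noise
and runs the two-stage detector: onsets where the smoothed first
derivative crosses 5 robust noise scales, confirmed by a 10 ms integral
exceeding 3 noise-scaled units.
"""

from synaptiq import (
    GLYCINE_QUANTUM,
    AcquisitionSpec,
    MiniModel,
    detect_minis,
    simulate_minis,
    summarize_minis,
)

acq = AcquisitionSpec(sweep_duration=1.0, stimulus_times=())
duration = 120.0
sweeps = simulate_minis(MiniModel(rate_hz=2.0, amplitude_mean_pa=40.0),
                        GLYCINE_QUANTUM, acq, duration=duration, seed=5,
                        noise_sd=2.0)
events = detect_minis(sweeps)
summary = summarize_minis(events, duration, sweeps.acquisition,
                          trace=sweeps.trials[0])

print(f"generated events : {len(sweeps.truth)} (2.0 Hz Poisson)")
print(f"detected events  : {summary.n_events}")
print(f"frequency        : {summary.frequency_hz:.2f} Hz")
print(f"mean amplitude   : {summary.mean_amplitude_pa:.1f} pA")
print(f"avg-event decay  : {summary.average_decay_ms:.2f} ms")
print("\nFrequency and amplitude per cell are what a mini map summarizes; "
      "the averaged-event decay separates fast glycinergic from slow "
      "GABAergic minis.")
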