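"""Jitter, rise and decay of synchronous vs asynchronous IPSCs.

Simulates two inputs: one releasing with sub-millisecond Gaussian latency
(synchronous, the signature of Syt1/2-positive terminals) and one with an
exponential latency tail (asynchronous).  The analyzer measures per-trial
peak-time jitter, half-rise time, and the decay time constant of the
averaged current.
"""

from synaptiq import compute_kinetics
from synaptiq.scenarios import simulate_scenario

for name, window in (("sync", (0, 100)), ("async", (0, 500))):
    sweeps = simulate_scenario(name, seed=1, n_trials=50)
    k = compute_kinetics(sweeps, window_ms=window)
    print(f"{name:>5}: jitter {k.jitter_ms:6.2f} ms | half-rise "
          f"{k.half_rise_ms:5.2f} ms | decay tau {k.decay_tau_ms:6.1f} ms | "
          f"peak {k.peak_amplitude_pa:6.1f} pA | charge {k.charge_pc:6.3f} pC")

print("\nSynchronous release: jitter well below 1 ms and fast rise."
      "\nAsynchronous release: jitter of tens of ms and slow rise/decay --"
      " the same ordering used to tell input sources apart.")
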