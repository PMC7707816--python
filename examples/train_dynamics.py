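"""Charge transfer during 50 Hz stimulus trains.

Compares a synchronous input with weak short-term depression (charge per
stimulus falls as 0.8^(k-1)) against an asynchronous input whose release
accumulates between stimuli, producing steadily growing, tonic charge
transfer.
"""

import numpy as np

from synaptiq import analyze_train
from synaptiq.scenarios import simulate_scenario

for name, n_trials in (("train_sync", 50), ("train_async", 200)):
    sweeps = simulate_scenario(name, seed=3, n_trials=n_trials, noise_sd=0.0)
    tr = analyze_train(sweeps)
    print(f"{name}: normalized charge per stimulus "
          f"{np.round(tr.normalized_charge, 2)}")
    print(f"          last-IPSC decay tau {tr.last_ipsc_decay_tau_ms:.1f} ms")

print("\nDepressing synchronous input decays between stimuli (values fall "
      "toward 0.8^9 ~ 0.13); the asynchronous input's charge grows "
      "monotonically as per-stimulus release rates sum across the train.")
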