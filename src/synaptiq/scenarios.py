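"""Named recording scenarios.

Each scenario bundles a release model and acquisition settings that emulate
one of the characteristic inhibitory input types:

* ``sync``  — purely synchronous release (sub-millisecond Gaussian latency),
  mixed GABA/glycine quanta; the signature of inputs with fast Syt1/2.
* ``async`` — purely asynchronous GABAergic release (exponential latency
  tail lasting tens to hundreds of ms); the signature of inputs lacking
  Syt1/2.
* ``mixed`` — the sum of a synchronous glycinergic source and an
  asynchronous GABAergic source converging on one cell.
* ``train_sync`` / ``train_async`` — 50 Hz x 10 stimulus trains with the
  synchronous source showing weak short-term depression and the
  asynchronous source showing release that accumulates between stimuli.
* ``minis`` — spontaneous miniature events at a Poisson rate.
* ``bursty`` — a synchronous input contaminated by gap-junction bursts,
  with a paired sweep set at the 0 mV chloride reversal potential.

The numeric defaults are generator choices (the latency scales respect the
tens-to-hundreds-of-milliseconds duration of asynchronous release, and the
glycine-faster-than-GABA kinetic ordering); they define reproducible
synthetic conditions, not measured values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .synth_ephys import (
    GLYCINE_QUANTUM,
    AcquisitionSpec,
    LatencyModel,
    MiniModel,
    ReleaseModel,
    SweepSet,
    inject_gap_bursts_paired,
    simulate_evoked,
    simulate_minis,
)

TRAIN_STIMULI = tuple(0.05 + 0.02 * k for k in range(10))  # 50 Hz x 10

SYNC_LATENCY = LatencyModel(mode="synchronous", mu_sync_ms=1.0, sigma_sync_ms=0.3)
ASYNC_LATENCY = LatencyModel(mode="asynchronous", tau_async_ms=50.0,
                             async_delay_ms=2.0)
TRAIN_ASYNC_LATENCY = LatencyModel(mode="asynchronous", tau_async_ms=150.0,
                                   async_delay_ms=2.0)

SYNC_RELEASE = ReleaseModel(latency=SYNC_LATENCY, transmitter_mix=0.5,
                            quantal_content=10.0)
ASYNC_RELEASE = ReleaseModel(latency=ASYNC_LATENCY, transmitter_mix=0.0,
                             quantal_content=10.0)
MIXED_SYNC_SOURCE = ReleaseModel(latency=SYNC_LATENCY, transmitter_mix=1.0,
                                 quantal_content=10.0)
MIXED_ASYNC_SOURCE = ReleaseModel(latency=ASYNC_LATENCY, transmitter_mix=0.0,
                                  quantal_content=10.0)
# Deterministic quantal counts: the depressing-train scenario is the
# noiseless reference condition for plasticity recovery, and Poisson count
# fluctuations are themselves a noise source.  The content models a strong
# compound input recruiting many fibers.
TRAIN_SYNC_RELEASE = ReleaseModel(
    latency=LatencyModel(mode="synchronous", mu_sync_ms=0.5, sigma_sync_ms=0.2),
    transmitter_mix=1.0, quantal_content=400.0, train_plasticity=0.8,
    glycine=replace(GLYCINE_QUANTUM, amplitude_cv=0.2),
    count_mode="fixed",
)
TRAIN_ASYNC_RELEASE = ReleaseModel(latency=TRAIN_ASYNC_LATENCY,
                                   transmitter_mix=0.0, quantal_content=40.0)

SINGLE_ACQ = AcquisitionSpec(sweep_duration=0.3, stimulus_times=(0.1,))
ASYNC_ACQ = AcquisitionSpec(sweep_duration=0.8, stimulus_times=(0.1,))
TRAIN_ACQ = AcquisitionSpec(sweep_duration=0.7, stimulus_times=TRAIN_STIMULI)

MINI_MODEL = MiniModel(rate_hz=2.0, amplitude_mean_pa=40.0, amplitude_cv=0.3,
                       transmitter="glycine")

SCENARIOS = ("sync", "async", "mixed", "train", "train_sync", "train_async",
             "minis", "bursty")


def combine_sources(a: SweepSet, b: SweepSet) -> SweepSet:
    """Superpose two simulated inputs converging on the same cell."""
    if a.acquisition != b.acquisition:
        raise ParameterError("sources must share an acquisition spec")
    truth = None
    if a.truth is not None and b.truth is not None:
        truth = (
            pd.concat([a.truth, b.truth], ignore_index=True)
            .sort_values(["trial", "t_event_s"], kind="stable")
            .reset_index(drop=True)
        )
    return SweepSet(a.trials + b.trials, a.acquisition, truth=truth)


def simulate_scenario(
    name: str,
    seed: int = 0,
    n_trials: int = 50,
    noise_sd: float = 2.0,
    duration: float = 60.0,
):
    """Simulate one named scenario.

    Returns a :class:`SweepSet` for the evoked and mini scenarios, and a
    ``(minus60, zero_mv)`` pair for ``bursty``.  ``duration`` applies to the
    ``minis`` scenario only.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(3)]
    if name == "sync":
        return simulate_evoked(SYNC_RELEASE, SINGLE_ACQ, n_trials, seeds[0],
                               noise_sd)
    if name == "async":
        return simulate_evoked(ASYNC_RELEASE, ASYNC_ACQ, n_trials, seeds[0],
                               noise_sd)
    if name == "mixed":
        s = simulate_evoked(MIXED_SYNC_SOURCE, ASYNC_ACQ, n_trials, seeds[0],
                            noise_sd)
        a = simulate_evoked(MIXED_ASYNC_SOURCE, ASYNC_ACQ, n_trials, seeds[1],
                            noise_sd=0.0)
        return combine_sources(s, a)
    if name in ("train", "train_sync"):
        return simulate_evoked(TRAIN_SYNC_RELEASE, TRAIN_ACQ, n_trials,
                               seeds[0], noise_sd)
    if name == "train_async":
        return simulate_evoked(TRAIN_ASYNC_RELEASE, TRAIN_ACQ, n_trials,
                               seeds[0], noise_sd)
    if name == "minis":
        return simulate_minis(MINI_MODEL, GLYCINE_QUANTUM, SINGLE_ACQ,
                              duration=duration, seed=seeds[0],
                              noise_sd=noise_sd)
    if name == "bursty":
        m60 = simulate_evoked(SYNC_RELEASE, SINGLE_ACQ, n_trials, seeds[0],
                              noise_sd)
        zero = simulate_evoked(
            SYNC_RELEASE,
            replace(SINGLE_ACQ, holding_potential=0.0),
            n_trials, seeds[0], noise_sd,
        )
        return inject_gap_bursts_paired(m60, zero, rate_hz=2.0, seed=seeds[2])
    raise ParameterError(f"unknown scenario '{name}'; choose from {SCENARIOS}")
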