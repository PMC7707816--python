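"""Quantal simulation of inhibitory postsynaptic currents (IPSCs).

Simulates voltage-clamp sweeps in which transmitter release is quantal:
each stimulus releases a Poisson number of vesicles, each vesicle produces
a stereotyped current kernel

    q(t) = A_norm * (1 - exp(-t / tau_r)) * exp(-t / tau_d),   t >= 0,

scaled so the kernel peak equals the quantal amplitude.  Release latency is
either synchronous (truncated Gaussian, sub-millisecond jitter) or
asynchronous (exponential tail lasting tens to hundreds of milliseconds),
matching the two release modes that inhibitory inputs exhibit: tight
time-locking when fast synaptotagmins (Syt1/2) are present, prolonged
desynchronized release when they are absent.

Two transmitters with distinct quantal kinetics can be mixed: glycinergic
quanta are faster and larger, GABAergic quanta slower and smaller (the
numeric defaults are generator choices that respect this ordering).
Synaptic current scales with driving force and reverses at 0 mV; currents
from gap-junction-coupled neighbors ("bursts") do not, which is what makes
paired recordings at -60 and 0 mV useful for removing them.

Sign convention: with a high-chloride internal at -60 mV, IPSCs are inward
(negative); analyzers work on magnitudes.

The 4 kHz low-pass (4-pole Butterworth, standing in for an amplifier Bessel
filter) is applied to the noise component only: quantal kernels are already
smooth on that time scale, and this keeps the simulated trace an exact
superposition of kernels plus noise, which downstream tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import GeometryError, ParameterError

TRUTH_COLUMNS = [
    "trial", "stim", "t_event_s", "latency_ms", "amplitude_pa",
    "transmitter", "component",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    sampling_rate: float = 20_000.0  # Hz
    filter_cutoff: float = 4_000.0  # Hz
    sweep_duration: float = 0.5  # s
    holding_potential: float = -60.0  # mV
    reversal_potential: float = 0.0  # mV
    stimulus_times: tuple[float, ...] = (0.05,)  # s
    artifact_blank_ms: float = 0.0

    def __post_init__(self):
        if self.filter_cutoff >= self.sampling_rate / 2:
            raise ParameterError("filter_cutoff must be below Nyquist")
        if any(not 0 <= t < self.sweep_duration for t in self.stimulus_times):
            raise ParameterError("stimulus_times must lie within the sweep")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_duration * self.sampling_rate))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def driving_scale(self) -> float:
        """Synaptic current scale relative to a -60 mV reference holding."""
        return (self.holding_potential - self.reversal_potential) / (-60.0)


@dataclass(frozen=True)
class QuantalModel:
    amplitude_pa: float = 30.0
    amplitude_cv: float = 0.3  # lognormal coefficient of variation
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 15.0

    def __post_init__(self):
        if self.amplitude_pa <= 0:
            raise ParameterError("quantal amplitude must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ParameterError("tau_rise must be smaller than tau_decay")
        if self.amplitude_cv < 0:
            raise ParameterError("amplitude_cv must be >= 0")

    @property
    def peak_time_ms(self) -> float:
        """Analytic kernel peak time t* = tau_r * ln(1 + tau_d / tau_r)."""
        return self.tau_rise_ms * np.log(1.0 + self.tau_decay_ms / self.tau_rise_ms)


# Generator defaults: glycinergic quanta faster and larger than GABAergic.
GABA_QUANTUM = QuantalModel(amplitude_pa=30.0, amplitude_cv=0.3,
                            tau_rise_ms=1.0, tau_decay_ms=15.0)
GLYCINE_QUANTUM = QuantalModel(amplitude_pa=50.0, amplitude_cv=0.3,
                               tau_rise_ms=0.3, tau_decay_ms=5.0)


@dataclass(frozen=True)
class LatencyModel:
    """Release latency relative to the stimulus.

    ``mode='synchronous'``: Gaussian(mu_sync, sigma_sync) truncated at 0.
    ``mode='asynchronous'``: delay + Exponential(tau_async).
    ``mode='mixed'``: each quantum synchronous with probability ``mix_weight``.
    All times in ms.
    """

    mode: str = "synchronous"
    mu_sync_ms: float = 1.0
    sigma_sync_ms: float = 0.3
    tau_async_ms: float = 30.0
    async_delay_ms: float = 1.0
    mix_weight: float | None = None

    def __post_init__(self):
        if self.mode not in ("synchronous", "asynchronous", "mixed"):
            raise ParameterError(f"unknown latency mode '{self.mode}'")
        if self.sigma_sync_ms <= 0 or self.tau_async_ms <= 0:
            raise ParameterError("sigma_sync and tau_async must be positive")
        if self.mode == "mixed":
            if self.mix_weight is None or not 0 <= self.mix_weight <= 1:
                raise ParameterError("mixed mode requires mix_weight in [0, 1]")
        elif self.mix_weight is not None:
            raise ParameterError("mix_weight only valid in mixed mode")

    def sync_fraction(self) -> float:
        if self.mode == "synchronous":
            return 1.0
        if self.mode == "asynchronous":
            return 0.0
        return float(self.mix_weight)


@dataclass(frozen=True)
class ReleaseModel:
    gaba: QuantalModel = GABA_QUANTUM
    glycine: QuantalModel = GLYCINE_QUANTUM
    transmitter_mix: float = 0.0  # fraction of quanta that are glycinergic
    latency: LatencyModel = field(default_factory=LatencyModel)
    quantal_content: float = 10.0  # mean quanta per stimulus
    train_plasticity: float = 1.0  # per-stimulus multiplicative factor f
    async_facilitation: float = 1.0  # extra per-stimulus factor, async only
    count_mode: str = "poisson"  # 'poisson' | 'fixed'

    def __post_init__(self):
        if not 0 <= self.transmitter_mix <= 1:
            raise ParameterError("transmitter_mix must lie in [0, 1]")
        if self.quantal_content < 0:
            raise ParameterError("quantal_content must be >= 0")
        if self.train_plasticity <= 0 or self.async_facilitation <= 0:
            raise ParameterError("plasticity factors must be positive")
        if self.count_mode not in ("poisson", "fixed"):
            raise ParameterError("count_mode must be 'poisson' or 'fixed'")

    def quantum(self, transmitter: str) -> QuantalModel:
        return self.glycine if transmitter == "glycine" else self.gaba


@dataclass(frozen=True)
class MiniModel:
    rate_hz: float = 2.0
    amplitude_mean_pa: float = 40.0
    amplitude_cv: float = 0.3
    transmitter: str = "glycine"

    def __post_init__(self):
        if self.rate_hz < 0:
            raise ParameterError("mini rate must be >= 0")


@dataclass
class SweepSet:
    """A block of current sweeps plus acquisition metadata and, when
    synthetic, the per-quantum ground truth."""

    trials: np.ndarray  # (n_trials, n_samples), pA
    acquisition: AcquisitionSpec
    truth: pd.DataFrame | None = None
    burst_truth: pd.DataFrame | None = None

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=np.float64))
        if self.trials.shape[1] != self.acquisition.n_samples:
            raise ParameterError(
                f"trials have {self.trials.shape[1]} samples, acquisition "
                f"implies {self.acquisition.n_samples}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.acquisition.time

    def average(self) -> np.ndarray:
        return self.trials.mean(axis=0)


def quantal_waveform(model: QuantalModel, acquisition: AcquisitionSpec) -> np.ndarray:
    """Sampled quantal kernel, peak-normalized to ``model.amplitude_pa``.

    Length covers the peak plus five decay time constants.
    """
    dt_ms = acquisition.dt * 1e3
    t_star = model.peak_time_ms
    n = int(np.ceil((t_star + 5.0 * model.tau_decay_ms) / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    q = (1.0 - np.exp(-t / model.tau_rise_ms)) * np.exp(-t / model.tau_decay_ms)
    peak = (1.0 - np.exp(-t_star / model.tau_rise_ms)) * np.exp(
        -t_star / model.tau_decay_ms
    )
    return model.amplitude_pa * q / peak


def _lognormal_amplitudes(rng, mean, cv, n):
    if cv == 0 or n == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _truncated_gaussian(rng, mu, sigma, n):
    out = rng.normal(mu, sigma, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out < 0
    return out


def filtered_noise_sd(raw_sd: float, acquisition: AcquisitionSpec) -> float:
    """Stationary SD of white noise of SD ``raw_sd`` after the 4-pole
    Butterworth low-pass (computed from the filter's power transfer)."""
    sos = _noise_filter(acquisition)
    w, h = signal.sosfreqz(sos, worN=4096)
    power_gain = np.trapezoid(np.abs(h) ** 2, w) / np.pi
    return float(raw_sd * np.sqrt(power_gain))


def _noise_filter(acquisition: AcquisitionSpec):
    return signal.butter(
        4, acquisition.filter_cutoff, btype="low", fs=acquisition.sampling_rate,
        output="sos",
    )


def _make_noise(rng, acquisition, noise_sd, shape):
    if noise_sd <= 0:
        return np.zeros(shape)
    white = rng.normal(0.0, noise_sd, size=shape)
    return signal.sosfilt(_noise_filter(acquisition), white, axis=-1)


def _add_kernel(trace, kernel, t_event_s, acquisition, amp_scale):
    i0 = int(round(t_event_s * acquisition.sampling_rate))
    if i0 >= trace.shape[-1]:
        return
    n = min(len(kernel), trace.shape[-1] - i0)
    trace[i0 : i0 + n] += amp_scale * kernel[:n]


def _blank_artifacts(trials, acquisition):
    if acquisition.artifact_blank_ms <= 0:
        return
    w = int(round(acquisition.artifact_blank_ms * 1e-3 * acquisition.sampling_rate))
    for t_s in acquisition.stimulus_times:
        i0 = int(round(t_s * acquisition.sampling_rate))
        trials[:, i0 : i0 + w] = 0.0


def _draw_count(rng, mean, mode):
    if mode == "fixed":
        return int(round(mean))
    return int(rng.poisson(mean))


def simulate_evoked(
    release: ReleaseModel,
    acquisition: AcquisitionSpec,
    n_trials: int = 20,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> SweepSet:
    """Simulate evoked IPSC sweeps for every stimulus in the acquisition.

    For stimulus ``k`` (1-based) the expected quantal count is
    ``quantal_content * f**(k-1)`` (times ``async_facilitation**(k-1)`` for
    the asynchronous component).  Asynchronous latencies are drawn per
    stimulus and may extend past later stimuli, so asynchronous release
    accumulates across a train: the per-stimulus exponential release rates
    sum.  Synaptic current scales with driving force and vanishes at the
    0 mV reversal potential.  ``noise_sd`` is the white-noise SD before the
    low-pass filter (see :func:`filtered_noise_sd` for the post-filter SD).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = acquisition.n_samples
    trials = np.zeros((n_trials, n))
    kernels = {
        "gaba": quantal_waveform(release.gaba, acquisition),
        "glycine": quantal_waveform(release.glycine, acquisition),
    }
    # kernels are peak-normalized to the model amplitude; per-quantum
    # amplitudes below are drawn in pA and applied as a scale on a
    # unit-peak version of the kernel
    unit_kernels = {
        k: v / release.quantum(k).amplitude_pa for k, v in kernels.items()
    }
    lat = release.latency
    w_sync = lat.sync_fraction()
    scale = acquisition.driving_scale
    rows = []
    for trial in range(n_trials):
        for k, t_stim in enumerate(acquisition.stimulus_times):
            mean_k = release.quantal_content * release.train_plasticity**k
            for component, w in (("sync", w_sync), ("async", 1.0 - w_sync)):
                mean_c = mean_k * w
                if component == "async":
                    mean_c *= release.async_facilitation**k
                if mean_c <= 0:
                    continue
                count = _draw_count(rng, mean_c, release.count_mode)
                if count == 0:
                    continue
                if component == "sync":
                    latencies = _truncated_gaussian(
                        rng, lat.mu_sync_ms, lat.sigma_sync_ms, count
                    )
                else:
                    latencies = lat.async_delay_ms + rng.exponential(
                        lat.tau_async_ms, size=count
                    )
                transmitters = np.where(
                    rng.random(count) < release.transmitter_mix, "glycine", "gaba"
                )
                for lat_ms, tr in zip(latencies, transmitters):
                    qm = release.quantum(tr)
                    amp = _lognormal_amplitudes(
                        rng, qm.amplitude_pa, qm.amplitude_cv, 1
                    )[0]
                    t_event = t_stim + lat_ms * 1e-3
                    if t_event >= acquisition.sweep_duration:
                        continue  # geometry warning case: quantum off-sweep
                    _add_kernel(
                        trials[trial], unit_kernels[tr], t_event, acquisition,
                        amp_scale=-scale * amp,
                    )
                    rows.append(
                        (trial, k, t_event, lat_ms, amp, tr, component)
                    )
    trials += _make_noise(rng, acquisition, noise_sd, trials.shape)
    _blank_artifacts(trials, acquisition)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SweepSet(trials, acquisition, truth=truth)


def render_truth(
    truth: pd.DataFrame,
    acquisition: AcquisitionSpec,
    release: ReleaseModel,
    transmitters: tuple[str, ...] = ("gaba", "glycine"),
    n_trials: int | None = None,
) -> SweepSet:
    """Re-render noiseless sweeps from a ground-truth event table, keeping
    only the listed transmitters.

    This is the in-silico analogue of a receptor antagonist: the same
    release events, with one transmitter class silenced.
    """
    if n_trials is None:
        n_trials = int(truth["trial"].max()) + 1 if len(truth) else 1
    trials = np.zeros((n_trials, acquisition.n_samples))
    unit_kernels = {
        tr: quantal_waveform(release.quantum(tr), acquisition)
        / release.quantum(tr).amplitude_pa
        for tr in ("gaba", "glycine")
    }
    scale = acquisition.driving_scale
    for row in truth.itertuples(index=False):
        if row.transmitter not in transmitters:
            continue
        _add_kernel(
            trials[int(row.trial)], unit_kernels[row.transmitter],
            row.t_event_s, acquisition, amp_scale=-scale * row.amplitude_pa,
        )
    _blank_artifacts(trials, acquisition)
    return SweepSet(trials, acquisition, truth=truth)


def simulate_minis(
    mini: MiniModel,
    quantal: QuantalModel,
    acquisition: AcquisitionSpec,
    duration: float | None = None,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> SweepSet:
    """One continuous sweep of miniature IPSCs at a homogeneous Poisson rate.

    ``quantal`` sets the event kinetics; amplitudes come from the mini
    model's lognormal distribution.
    """
    if duration is None:
        duration = acquisition.sweep_duration
    if duration <= 0:
        raise ParameterError("duration must be positive")
    acq = replace(acquisition, sweep_duration=duration, stimulus_times=())
    rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(mini.rate_hz * duration))
    times = np.sort(rng.uniform(0.0, duration, size=n_events))
    amps = _lognormal_amplitudes(rng, mini.amplitude_mean_pa, mini.amplitude_cv,
                                 n_events)
    trace = np.zeros(acq.n_samples)
    unit_kernel = quantal_waveform(quantal, acq) / quantal.amplitude_pa
    scale = acq.driving_scale
    for t_ev, a in zip(times, amps):
        _add_kernel(trace, unit_kernel, t_ev, acq, amp_scale=-scale * a)
    trace += _make_noise(rng, acq, noise_sd, trace.shape)
    truth = pd.DataFrame(
        {
            "trial": np.zeros(n_events, dtype=int),
            "stim": np.full(n_events, -1),
            "t_event_s": times,
            "latency_ms": np.full(n_events, np.nan),
            "amplitude_pa": amps,
            "transmitter": mini.transmitter,
            "component": "mini",
        },
        columns=TRUTH_COLUMNS,
    )
    return SweepSet(trace[None, :], acq, truth=truth)


def gap_burst_template(
    acquisition: AcquisitionSpec,
    n_spikelets: int = 3,
    spacing_ms: float = 2.0,
    spikelet_sigma_ms: float = 0.3,
    amplitude_pa: float = 80.0,
) -> np.ndarray:
    """Burst of biphasic spikelets from an electrically coupled neighbor.

    Each spikelet is a Gaussian-derivative biphasic transient; successive
    spikelets shrink slightly.  The shape is configurable; analyzers only
    rely on its consistency and its fast time course relative to IPSCs.
    """
    dt_ms = acquisition.dt * 1e3
    dur_ms = (n_spikelets - 1) * spacing_ms + 8 * spikelet_sigma_ms
    t = np.arange(int(np.ceil(dur_ms / dt_ms))) * dt_ms
    out = np.zeros_like(t)
    for i in range(n_spikelets):
        t0 = i * spacing_ms + 4 * spikelet_sigma_ms
        x = (t - t0) / spikelet_sigma_ms
        out += (0.85**i) * (-x) * np.exp(-0.5 * x * x)
    peak = np.max(np.abs(out))
    return amplitude_pa * out / peak


def inject_gap_bursts(
    sweeps: SweepSet,
    template: np.ndarray | None = None,
    rate_hz: float = 1.0,
    seed: int = 0,
    times_per_trial: list[np.ndarray] | None = None,
) -> SweepSet:
    """Add gap-junction bursts at Poisson times to every trial.

    Bursts do not scale with holding potential.  Pass ``times_per_trial``
    (e.g. from a previous call's ``burst_truth``) to inject the identical
    bursts into a paired sweep set recorded at a different potential.
    """
    acq = sweeps.acquisition
    if template is None:
        template = gap_burst_template(acq)
    if len(template) >= acq.n_samples:
        raise ParameterError("burst template must be shorter than the sweep")
    rng = np.random.default_rng(seed)
    trials = sweeps.trials.copy()
    rows = []
    for i in range(sweeps.n_trials):
        if times_per_trial is not None:
            times = np.asarray(times_per_trial[i], dtype=float)
        else:
            n_b = int(rng.poisson(rate_hz * acq.sweep_duration))
            times = np.sort(
                rng.uniform(0.0, acq.sweep_duration - len(template) * acq.dt, n_b)
            )
        for t_b in times:
            _add_kernel(trials[i], template, t_b, acq, amp_scale=1.0)
            rows.append((i, t_b))
    burst_truth = pd.DataFrame(rows, columns=["trial", "t_burst_s"])
    return SweepSet(trials, acq, truth=sweeps.truth, burst_truth=burst_truth)


def inject_gap_bursts_paired(
    sweeps_m60: SweepSet,
    sweeps_0mv: SweepSet,
    template: np.ndarray | None = None,
    rate_hz: float = 1.0,
    seed: int = 0,
) -> tuple[SweepSet, SweepSet]:
    """Inject identical bursts into paired -60 mV / 0 mV sweep sets."""
    out60 = inject_gap_bursts(sweeps_m60, template, rate_hz, seed)
    times = [
        out60.burst_truth.loc[out60.burst_truth["trial"] == i, "t_burst_s"].to_numpy()
        for i in range(sweeps_0mv.n_trials)
    ]
    out0 = inject_gap_bursts(sweeps_0mv, template, rate_hz, seed,
                             times_per_trial=times)
    return out60, out0
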