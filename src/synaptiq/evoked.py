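"""Kinetic analysis of evoked IPSCs.

Implements the standard voltage-clamp measurements for evoked inhibitory
currents:

* **jitter** — the standard deviation (n−1) across trials of the per-trial
  peak-current time; the classic fingerprint separating synchronous
  (sub-millisecond) from asynchronous (tens of milliseconds) release;
* **half-rise** — time from stimulus to 50% of peak on the trial-averaged
  trace (linear interpolation between samples);
* **decay τ** — single-exponential least-squares fit from the peak of the
  average trace down to 10% of peak;
* **charge** — trapezoidal integral of the baseline-subtracted current
  magnitude over the response window (pA·s = pC);
* **pharmacological component subtraction** — mean(control) − mean(drug)
  isolates the drug-sensitive component, yielding glycine/GABA amplitude
  and charge ratios;
* **gap-junction burst handling** — rejection of contaminated trials by
  template correlation, or scaled subtraction of the 0 mV average;
* **train analysis** — per-stimulus charge (normalized to stimulus 1) and
  the decay of the last IPSC for 50 Hz stimulus trains.

All analyses operate on the magnitude of baseline-subtracted current; the
sign convention (inward negative at −60 mV) is resolved from the holding
and reversal potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .errors import (
    EmptyResultError,
    FitError,
    IncompatibleSweepsError,
    NormalizationError,
    ParameterError,
)
from .synth_ephys import AcquisitionSpec, SweepSet

BASELINE_MS = 10.0  # pre-stimulus window used for baseline and noise SD


@dataclass
class KineticsResult:
    jitter_ms: float | None
    half_rise_ms: float | None
    decay_tau_ms: float | None
    peak_amplitude_pa: float
    peak_time_ms: float
    charge_pc: float
    n_trials: int
    responded: bool = True


@dataclass
class ComponentResult:
    glycine: KineticsResult
    gaba: KineticsResult
    amplitude_ratio: float  # glycine / GABA
    charge_ratio: float  # glycine / GABA


@dataclass
class TrainResult:
    charges_pc: np.ndarray  # per-stimulus
    normalized_charge: np.ndarray  # charges / charges[0]
    last_ipsc_decay_tau_ms: float | None
    isi_ms: float


def response_sign(acquisition: AcquisitionSpec) -> float:
    """+1 factor that makes the synaptic response positive-going."""
    return -1.0 if acquisition.holding_potential < acquisition.reversal_potential else 1.0


def _baseline_window(acquisition, stim_time):
    i1 = int(round(stim_time * acquisition.sampling_rate))
    i0 = max(0, i1 - int(round(BASELINE_MS * 1e-3 * acquisition.sampling_rate)))
    if i1 <= i0:
        i0, i1 = 0, max(1, i1)
    return i0, i1


def _rectified(trials, acquisition, stim_time):
    """Baseline-subtracted, positive-going response per trial."""
    i0, i1 = _baseline_window(acquisition, stim_time)
    baseline = trials[:, i0:i1].mean(axis=1, keepdims=True)
    return response_sign(acquisition) * (trials - baseline)


def _boxcar(x, width_samples):
    if width_samples <= 1:
        return x
    k = np.ones(width_samples) / width_samples
    if x.ndim == 1:
        return np.convolve(x, k, mode="same")
    return np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), -1, x)


def fit_decay_tau(
    t_ms: np.ndarray, y: np.ndarray, tail_fraction: float = 0.1
) -> float:
    """Single-exponential decay constant of ``y`` (positive, starting at its
    peak sample), fit from the peak to the first crossing of
    ``tail_fraction`` of peak (or the end of the data).

    The offset is fixed at zero: the input is expected to be
    baseline-subtracted.  Returns τ in the units of ``t_ms``.
    """
    if len(y) < 4:
        raise FitError("decay fit needs at least 4 samples", {"n": len(y)})
    peak = y[0]
    below = np.nonzero(y < tail_fraction * peak)[0]
    end = int(below[0]) + 1 if len(below) else len(y)
    end = max(end, 4)
    tt, yy = t_ms[:end] - t_ms[0], y[:end]
    tau0 = max((tt[-1] - tt[0]) / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tt, yy, p0=(peak, tau0),
            bounds=((0, 1e-6), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError("decay fit did not converge",
                       {"n": end, "peak": float(peak)}) from exc
    return float(popt[1])


def _interp_crossing(t, y, level, stop):
    """First upward crossing of ``level`` in y[:stop+1], linearly interpolated."""
    for i in range(1, stop + 1):
        if y[i] >= level > y[i - 1]:
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return t[i - 1] + frac * (t[i] - t[i - 1])
    return t[0]


def compute_kinetics(
    sweeps: SweepSet,
    window_ms: tuple[float, float] = (0.0, 100.0),
    stim_index: int = 0,
    smooth_ms: float = 0.5,
    no_response_k: float = 5.0,
) -> KineticsResult:
    """Jitter, half-rise, decay τ, peak and charge for one stimulus.

    ``window_ms`` is the response window relative to the stimulus.  Jitter
    needs at least two trials and is otherwise reported missing.  If the
    average peak does not exceed ``no_response_k`` baseline-noise SDs the
    result is flagged non-responding and rise/decay are withheld (the
    default of 5 SDs accounts for the peak being a maximum over many
    correlated samples, which noise alone pushes past 3 SDs).
    """
    acq = sweeps.acquisition
    if not acq.stimulus_times:
        raise ParameterError("sweep set has no stimulus times")
    t_stim = acq.stimulus_times[stim_index]
    fs = acq.sampling_rate
    resp = _rectified(sweeps.trials, acq, t_stim)
    w0 = int(round((t_stim + window_ms[0] * 1e-3) * fs))
    w1 = min(acq.n_samples, int(round((t_stim + window_ms[1] * 1e-3) * fs)))
    if w1 - w0 < 4:
        raise ParameterError("response window too short")

    # per-trial peak times on lightly smoothed trials -> jitter
    jitter = None
    if sweeps.n_trials >= 2:
        sm = _boxcar(resp, int(round(smooth_ms * 1e-3 * fs)))
        peak_idx = np.argmax(sm[:, w0:w1], axis=1) + w0
        peak_t_ms = (peak_idx / fs - t_stim) * 1e3
        jitter = float(np.std(peak_t_ms, ddof=1))

    avg = resp.mean(axis=0)
    seg = avg[w0:w1]
    ip = int(np.argmax(seg)) + w0
    peak_amp = float(avg[ip])
    peak_time_ms = (ip / fs - t_stim) * 1e3
    t_ms = (np.arange(acq.n_samples) / fs - t_stim) * 1e3

    i0, i1 = _baseline_window(acq, t_stim)
    noise_sd = float(avg[i0:i1].std())
    charge = float(np.trapezoid(seg, dx=1.0 / fs))  # pA*s = pC
    responded = peak_amp > no_response_k * noise_sd

    half_rise = decay_tau = None
    if responded:
        stim_i = int(round(t_stim * fs))
        half_rise = float(
            _interp_crossing(t_ms[stim_i:], avg[stim_i:], 0.5 * peak_amp,
                             ip - stim_i)
        )
        decay_tau = fit_decay_tau(t_ms[ip:w1], avg[ip:w1])
    return KineticsResult(
        jitter_ms=jitter,
        half_rise_ms=half_rise,
        decay_tau_ms=decay_tau,
        peak_amplitude_pa=peak_amp,
        peak_time_ms=peak_time_ms,
        charge_pc=charge,
        n_trials=sweeps.n_trials,
        responded=responded,
    )


def _check_compatible(a: AcquisitionSpec, b: AcquisitionSpec):
    if a.sampling_rate != b.sampling_rate or a.stimulus_times != b.stimulus_times:
        raise IncompatibleSweepsError(
            "sweep sets differ in sampling rate or stimulus times"
        )


def _average_sweepset(trace: np.ndarray, acq: AcquisitionSpec) -> SweepSet:
    return SweepSet(trace[None, :], acq)


def subtract_components(
    control: SweepSet,
    after_drug: SweepSet,
    window_ms: tuple[float, float] = (0.0, 100.0),
    drug_sensitive: str = "glycine",
    **kinetics_kwargs,
) -> tuple[np.ndarray, ComponentResult]:
    """Isolate a drug-sensitive IPSC component by trace subtraction.

    The drug-sensitive trace is ``mean(control) − mean(after_drug)`` (e.g.
    strychnine leaves GABA, so the difference is the glycinergic component).
    Kinetics are computed on the difference and on the residual average; a
    component failing the no-response test contributes amplitude and charge
    0, so an absent glycinergic component yields ratio 0.
    """
    _check_compatible(control.acquisition, after_drug.acquisition)
    if drug_sensitive not in ("glycine", "gaba"):
        raise ParameterError("drug_sensitive must be 'glycine' or 'gaba'")
    acq = control.acquisition
    diff = control.average() - after_drug.average()
    comp = {
        drug_sensitive: compute_kinetics(
            _average_sweepset(diff, acq), window_ms, **kinetics_kwargs
        ),
        ("gaba" if drug_sensitive == "glycine" else "glycine"): compute_kinetics(
            _average_sweepset(after_drug.average(), acq), window_ms,
            **kinetics_kwargs
        ),
    }

    def eff(k: KineticsResult, attr):
        return getattr(k, attr) if k.responded else 0.0

    g_amp, g_q = eff(comp["glycine"], "peak_amplitude_pa"), eff(comp["glycine"], "charge_pc")
    b_amp, b_q = eff(comp["gaba"], "peak_amplitude_pa"), eff(comp["gaba"], "charge_pc")
    amp_ratio = g_amp / b_amp if b_amp > 0 else (0.0 if g_amp == 0 else np.inf)
    q_ratio = g_q / b_q if b_q > 0 else (0.0 if g_q == 0 else np.inf)
    return diff, ComponentResult(
        glycine=comp["glycine"], gaba=comp["gaba"],
        amplitude_ratio=float(amp_ratio), charge_ratio=float(q_ratio),
    )


def estimate_burst_template(
    sweeps_0mv: SweepSet, window_ms: tuple[float, float] = (-2.0, 8.0),
    k: float = 5.0,
) -> np.ndarray:
    """Estimate the gap-junction burst waveform from 0 mV sweeps.

    At 0 mV the synaptic current reverses to zero, so large deflections are
    bursts: per trial, the largest |deflection| above ``k`` robust SDs is
    extracted in a fixed window around its peak, and the aligned extracts
    are averaged.
    """
    acq = sweeps_0mv.acquisition
    fs = acq.sampling_rate
    pre = int(round(-window_ms[0] * 1e-3 * fs))
    post = int(round(window_ms[1] * 1e-3 * fs))
    extracts = []
    for tr in sweeps_0mv.trials:
        x = tr - np.median(tr)
        sd = 1.4826 * np.median(np.abs(x)) + 1e-12
        i = int(np.argmax(np.abs(x)))
        if np.abs(x[i]) < k * sd:
            continue
        if i - pre < 0 or i + post > len(x):
            continue
        seg = x[i - pre : i + post]
        extracts.append(seg * np.sign(x[i]))
    if not extracts:
        raise EmptyResultError("no burst-like deflections found at 0 mV")
    return np.mean(extracts, axis=0)


def _max_normalized_correlation(x: np.ndarray, template: np.ndarray) -> float:
    """Max over lags of the normalized sliding correlation of x with template."""
    t = template - template.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        raise ParameterError("degenerate burst template")
    L = len(t)
    xc = x - x.mean()
    num = signal.correlate(xc, t, mode="valid")
    # sliding L2 norm of x over windows of length L
    c2 = np.convolve(xc * xc, np.ones(L), mode="valid")
    denom = np.sqrt(np.clip(c2, 1e-20, None)) * tn
    return float(np.max(num / denom))


def handle_gap_bursts(
    sweeps_m60: SweepSet,
    sweeps_0mv: SweepSet | None = None,
    mode: str = "reject",
    template: np.ndarray | None = None,
    threshold: float = 0.6,
    synaptic_free_window_ms: tuple[float, float] | None = None,
) -> tuple[SweepSet, dict]:
    """Remove gap-junction burst contamination from −60 mV sweeps.

    ``mode='reject'``: drop trials whose maximum normalized correlation
    with the burst template (supplied, or estimated from the 0 mV sweeps)
    exceeds ``threshold``.  ``mode='subtract'``: scale the averaged 0 mV
    trace by a least-squares fit over a synaptic-free window (default: the
    pre-stimulus period) and subtract it from the −60 mV average, returning
    a single-trace sweep set.
    """
    acq = sweeps_m60.acquisition
    if mode == "reject":
        if template is None:
            if sweeps_0mv is None:
                raise ParameterError("reject mode needs a template or 0 mV sweeps")
            template = estimate_burst_template(sweeps_0mv)
        scores = np.array(
            [_max_normalized_correlation(tr, template) for tr in sweeps_m60.trials]
        )
        keep = scores <= threshold
        if not keep.any():
            raise EmptyResultError("all trials rejected as burst-contaminated")
        cleaned = SweepSet(sweeps_m60.trials[keep], acq, truth=sweeps_m60.truth)
        return cleaned, {
            "mode": "reject",
            "rejected_trials": list(np.nonzero(~keep)[0]),
            "scores": scores,
        }
    if mode == "subtract":
        if sweeps_0mv is None:
            raise ParameterError("subtract mode requires 0 mV sweeps")
        _check_compatible(acq, sweeps_0mv.acquisition)
        avg60 = sweeps_m60.average()
        avg0 = sweeps_0mv.average()
        fs = acq.sampling_rate
        if synaptic_free_window_ms is None:
            first_stim = min(acq.stimulus_times) if acq.stimulus_times else acq.sweep_duration
            w = np.arange(acq.n_samples) < int(round(first_stim * fs))
        else:
            a, b = synaptic_free_window_ms
            idx = np.arange(acq.n_samples) / fs * 1e3
            w = (idx >= a) & (idx < b)
        denom = float(avg0[w] @ avg0[w])
        scale = float(avg60[w] @ avg0[w]) / denom if denom > 0 else 0.0
        cleaned = SweepSet((avg60 - scale * avg0)[None, :], acq,
                           truth=sweeps_m60.truth)
        return cleaned, {"mode": "subtract", "scale": scale}
    raise ParameterError(f"unknown mode '{mode}'")


def analyze_train(
    sweeps: SweepSet,
    tail_window_ms: float | None = None,
    no_response_k: float = 5.0,
) -> TrainResult:
    """Per-stimulus charge and last-IPSC decay for a stimulus train.

    Charge per stimulus is the baseline-subtracted trapezoidal integral of
    the average response over each inter-stimulus window (the last stimulus
    gets one ISI as well), normalized to stimulus 1.  The decay τ of the
    last IPSC is fit on the average trace after the final stimulus over
    ``tail_window_ms`` (default: everything to the end of the sweep).
    """
    acq = sweeps.acquisition
    stims = np.asarray(acq.stimulus_times)
    if len(stims) < 2:
        raise ParameterError("train analysis needs at least 2 stimuli")
    isis = np.diff(stims)
    if not np.allclose(isis, isis[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("inter-stimulus interval must be constant")
    isi = float(isis[0])
    fs = acq.sampling_rate
    resp = _rectified(sweeps.trials, acq, stims[0]).mean(axis=0)

    charges = []
    for t_k in stims:
        a = int(round(t_k * fs))
        b = min(acq.n_samples, int(round((t_k + isi) * fs)))
        charges.append(float(np.trapezoid(resp[a:b], dx=1.0 / fs)))
    charges = np.asarray(charges)

    i0, i1 = _baseline_window(acq, stims[0])
    noise_sd = float(resp[i0:i1].std())
    a = int(round(stims[0] * fs))
    b = int(round((stims[0] + isi) * fs))
    if resp[a:b].max() <= no_response_k * noise_sd or charges[0] <= 0:
        raise NormalizationError("first-stimulus charge at the noise floor")

    # decay of the last IPSC, fit from the post-train peak
    t_last = stims[-1]
    a = int(round(t_last * fs))
    if tail_window_ms is not None:
        b = min(acq.n_samples, a + int(round(tail_window_ms * 1e-3 * fs)))
    else:
        b = acq.n_samples
    seg = resp[a:b]
    t_ms = np.arange(len(seg)) / fs * 1e3
    ip = int(np.argmax(seg))
    try:
        last_tau = fit_decay_tau(t_ms[ip:], seg[ip:])
    except FitError:
        last_tau = None
    return TrainResult(
        charges_pc=charges,
        normalized_charge=charges / charges[0],
        last_ipsc_decay_tau_ms=last_tau,
        isi_ms=isi * 1e3,
    )
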