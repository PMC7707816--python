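import numpy as np
import pytest

from synaptiq import (
    GLYCINE_QUANTUM,
    AcquisitionSpec,
    LatencyModel,
    QuantalModel,
    ReleaseModel,
    SweepSet,
    analyze_train,
    compute_kinetics,
    gap_burst_template,
    handle_gap_bursts,
    inject_gap_bursts_paired,
    quantal_waveform,
    simulate_evoked,
    subtract_components,
)
from synaptiq.errors import (
    EmptyResultError,
    IncompatibleSweepsError,
    NormalizationError,
    ParameterError,
)
from synaptiq.scenarios import TRAIN_ACQ

from conftest import kernel_trace


def sweeps_from_traces(traces, acq):
    return SweepSet(np.asarray(traces), acq)


# --------------------------------------------------------------------------
# compute_kinetics


def test_identical_trials_have_zero_jitter(single_stim_acq):
    kernel = quantal_waveform(GLYCINE_QUANTUM, single_stim_acq)
    trace = -kernel_trace(single_stim_acq, kernel, [0.101])
    sw = sweeps_from_traces([trace, trace, trace], single_stim_acq)
    k = compute_kinetics(sw, window_ms=(0, 50))
    assert k.jitter_ms == pytest.approx(0.0, abs=1e-12)


def test_jitter_is_sample_sd_of_peak_times(single_stim_acq):
    """Kernels placed so per-trial peaks fall 0.2 ms apart -> SD = 0.2 ms."""
    kernel = quantal_waveform(GLYCINE_QUANTUM, single_stim_acq)
    onsets = [0.1100, 0.1102, 0.1104]  # 10.0 / 10.2 / 10.4 ms after stimulus
    sw = sweeps_from_traces(
        [-kernel_trace(single_stim_acq, kernel, [t]) for t in onsets],
        single_stim_acq,
    )
    k = compute_kinetics(sw, window_ms=(0, 50))
    # oracle: hand-computed sample SD with n-1 denominator
    assert k.jitter_ms == pytest.approx(np.std([10.0, 10.2, 10.4], ddof=1),
                                        abs=1e-9)


def test_jitter_invariant_under_common_time_shift(single_stim_acq):
    kernel = quantal_waveform(GLYCINE_QUANTUM, single_stim_acq)
    onsets = [0.110, 0.112, 0.115]
    base = sweeps_from_traces(
        [-kernel_trace(single_stim_acq, kernel, [t]) for t in onsets],
        single_stim_acq,
    )
    shifted = sweeps_from_traces(
        [-kernel_trace(single_stim_acq, kernel, [t + 0.005]) for t in onsets],
        single_stim_acq,
    )
    k0 = compute_kinetics(base, window_ms=(0, 60))
    k1 = compute_kinetics(shifted, window_ms=(0, 60))
    assert k1.jitter_ms == pytest.approx(k0.jitter_ms, abs=1e-9)


def test_decay_tau_recovered_from_pure_exponential(single_stim_acq):
    """Instant rise + exp(-t/20 ms) decay -> fitted tau within 1%."""
    fs = single_stim_acq.sampling_rate
    trace = np.zeros(single_stim_acq.n_samples)
    i0 = int(0.101 * fs)
    t = np.arange(single_stim_acq.n_samples - i0) / fs * 1e3
    trace[i0:] = -100.0 * np.exp(-t / 20.0)
    sw = sweeps_from_traces([trace, trace], single_stim_acq)
    k = compute_kinetics(sw, window_ms=(0, 150))
    assert k.decay_tau_ms == pytest.approx(20.0, rel=0.01)


def test_half_rise_precedes_peak_and_charge_positive(single_stim_acq):
    sw = simulate_evoked(ReleaseModel(quantal_content=20.0), single_stim_acq,
                         n_trials=20, seed=3, noise_sd=1.0)
    k = compute_kinetics(sw, window_ms=(0, 100))
    assert k.responded
    assert 0 < k.half_rise_ms < k.peak_time_ms
    assert k.charge_pc > 0


def test_no_response_flag_on_noise_only(single_stim_acq):
    sw = simulate_evoked(ReleaseModel(quantal_content=0.0), single_stim_acq,
                         n_trials=10, seed=4, noise_sd=2.0)
    k = compute_kinetics(sw, window_ms=(0, 100))
    assert not k.responded
    assert k.decay_tau_ms is None and k.half_rise_ms is None


def test_single_trial_jitter_is_missing(single_stim_acq):
    sw = simulate_evoked(ReleaseModel(quantal_content=10.0), single_stim_acq,
                         n_trials=1, seed=5, noise_sd=0.5)
    assert compute_kinetics(sw, window_ms=(0, 100)).jitter_ms is None


# --------------------------------------------------------------------------
# component subtraction


def test_inert_drug_leaves_no_component(single_stim_acq):
    control = simulate_evoked(ReleaseModel(quantal_content=10.0),
                              single_stim_acq, n_trials=10, seed=6,
                              noise_sd=1.0)
    diff, comp = subtract_components(control, control, window_ms=(0, 100))
    assert np.allclose(diff, 0.0)
    assert not comp.glycine.responded
    assert comp.charge_ratio == 0.0


def test_complete_block_recovers_control_average(single_stim_acq):
    control = simulate_evoked(ReleaseModel(quantal_content=10.0),
                              single_stim_acq, n_trials=10, seed=7,
                              noise_sd=0.0)
    blocked = sweeps_from_traces(np.zeros_like(control.trials),
                                 single_stim_acq)
    diff, _ = subtract_components(control, blocked, window_ms=(0, 100))
    np.testing.assert_allclose(diff, control.average(), atol=1e-12)


def test_charge_additivity_is_exact(single_stim_acq):
    rel_mix = ReleaseModel(transmitter_mix=0.5, quantal_content=15.0)
    control = simulate_evoked(rel_mix, single_stim_acq, n_trials=20, seed=8,
                              noise_sd=1.0)
    rel_g = ReleaseModel(quantal_content=8.0)
    after = simulate_evoked(rel_g, single_stim_acq, n_trials=20, seed=9,
                            noise_sd=1.0)
    diff, comp = subtract_components(control, after, window_ms=(0, 100))
    k_control = compute_kinetics(control, window_ms=(0, 100))
    k_after = compute_kinetics(after, window_ms=(0, 100))
    k_diff = compute_kinetics(SweepSet(diff[None, :], single_stim_acq),
                              window_ms=(0, 100))
    assert k_control.charge_pc == pytest.approx(
        k_after.charge_pc + k_diff.charge_pc, abs=1e-9
    )


def test_mismatched_acquisitions_rejected(single_stim_acq):
    other_acq = AcquisitionSpec(sweep_duration=0.3, stimulus_times=(0.05,))
    a = simulate_evoked(ReleaseModel(), single_stim_acq, n_trials=2, seed=1)
    b = simulate_evoked(ReleaseModel(), other_acq, n_trials=2, seed=1)
    with pytest.raises(IncompatibleSweepsError):
        subtract_components(a, b)


# --------------------------------------------------------------------------
# gap-junction burst handling


def _paired_bursty(n_trials=20, rate_hz=1.0, noise_sd=0.5, seed=11):
    rel = ReleaseModel(quantal_content=10.0)
    acq60 = AcquisitionSpec(sweep_duration=0.3, stimulus_times=(0.1,))
    acq0 = AcquisitionSpec(sweep_duration=0.3, stimulus_times=(0.1,),
                           holding_potential=0.0)
    m60 = simulate_evoked(rel, acq60, n_trials=n_trials, seed=seed,
                          noise_sd=noise_sd)
    zero = simulate_evoked(rel, acq0, n_trials=n_trials, seed=seed,
                           noise_sd=noise_sd)
    return inject_gap_bursts_paired(m60, zero, rate_hz=rate_hz, seed=seed + 1)


def test_clean_sweeps_keep_all_trials_and_zero_scale(single_stim_acq):
    sw = simulate_evoked(ReleaseModel(quantal_content=10.0), single_stim_acq,
                         n_trials=10, seed=12, noise_sd=0.5)
    template = gap_burst_template(single_stim_acq)
    cleaned, log = handle_gap_bursts(sw, mode="reject", template=template)
    assert log["rejected_trials"] == []
    assert cleaned.n_trials == 10
    # subtract mode with a burst-free 0 mV set: fitted scale ~ 0
    zero = SweepSet(
        np.random.default_rng(0).normal(0, 0.5, sw.trials.shape),
        single_stim_acq,
    )
    _, slog = handle_gap_bursts(sw, zero, mode="subtract")
    assert abs(slog["scale"]) < 0.2


def test_noiseless_paired_subtraction_is_exact():
    out60, out0 = _paired_bursty(n_trials=10, rate_hz=2.0, noise_sd=0.0)
    rel = ReleaseModel(quantal_content=10.0)
    acq = out60.acquisition
    synaptic = simulate_evoked(rel, acq, n_trials=10, seed=11, noise_sd=0.0)
    cleaned, log = handle_gap_bursts(out60, out0, mode="subtract")
    assert log["scale"] == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(cleaned.trials[0], synaptic.average(),
                               atol=1e-9)


def test_rejection_drops_contaminated_trials():
    out60, out0 = _paired_bursty(n_trials=30, rate_hz=2.0, noise_sd=0.5)
    cleaned, log = handle_gap_bursts(out60, out0, mode="reject")
    bursty_trials = set(out60.burst_truth["trial"])
    rejected = set(log["rejected_trials"])
    # every rejected trial really contains a burst, and most bursty trials go
    assert rejected <= bursty_trials
    assert len(rejected) >= 0.8 * len(bursty_trials)


def test_subtraction_cleans_synaptic_free_windows():
    """Burst power outside the response window drops >= 90% after scaled
    subtraction of the 0 mV average."""
    out60, out0 = _paired_bursty(n_trials=50, rate_hz=1.0, noise_sd=0.2)
    cleaned, _ = handle_gap_bursts(out60, out0, mode="subtract")
    fs = out60.acquisition.sampling_rate
    pre = slice(0, int(0.09 * fs))  # synaptic-free: before the stimulus
    rms_before = np.sqrt(np.mean(out60.average()[pre] ** 2))
    rms_after = np.sqrt(np.mean(cleaned.trials[0][pre] ** 2))
    assert rms_after <= 0.1 * rms_before


def test_all_trials_rejected_is_an_error(single_stim_acq):
    sw = simulate_evoked(ReleaseModel(quantal_content=0.0), single_stim_acq,
                         n_trials=3, seed=13, noise_sd=0.2)
    template = gap_burst_template(single_stim_acq)
    bursty = sw.trials + kernel_trace(
        single_stim_acq, template, [0.05, 0.2]
    )
    with pytest.raises(EmptyResultError):
        handle_gap_bursts(SweepSet(bursty, single_stim_acq), mode="reject",
                          template=template, threshold=0.0)


# --------------------------------------------------------------------------
# train analysis


def test_identical_fully_decaying_ipscs_normalize_to_one():
    q = QuantalModel(amplitude_pa=50, amplitude_cv=0, tau_rise_ms=0.2,
                     tau_decay_ms=2.0)
    rel = ReleaseModel(
        glycine=q, transmitter_mix=1.0, quantal_content=50.0,
        count_mode="fixed",
        latency=LatencyModel(mode="synchronous", mu_sync_ms=0.5,
                             sigma_sync_ms=1e-6),
    )
    sw = simulate_evoked(rel, TRAIN_ACQ, n_trials=5, seed=14, noise_sd=0.0)
    tr = analyze_train(sw)
    assert np.allclose(tr.normalized_charge, 1.0, rtol=0.02)
    assert tr.last_ipsc_decay_tau_ms == pytest.approx(2.0, rel=0.1)


def test_train_requires_constant_isi_and_response(single_stim_acq):
    with pytest.raises(ParameterError):
        analyze_train(simulate_evoked(ReleaseModel(), single_stim_acq,
                                      n_trials=2, seed=1))
    irregular = AcquisitionSpec(sweep_duration=0.5,
                                stimulus_times=(0.05, 0.07, 0.12))
    sw = simulate_evoked(ReleaseModel(), irregular, n_trials=2, seed=1)
    with pytest.raises(ParameterError):
        analyze_train(sw)
    silent = simulate_evoked(ReleaseModel(quantal_content=0.0), TRAIN_ACQ,
                             n_trials=3, seed=2, noise_sd=1.0)
    with pytest.raises(NormalizationError):
        analyze_train(silent)
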