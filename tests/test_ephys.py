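"""Filtering, spike detection, subthreshold measurement and classification."""

import numpy as np
import pytest
from scipy import signal as sps

from kcmod import (
    LIGHT,
    ODOR,
    CellProfile,
    ClassifierConfig,
    EphysProtocol,
    StimulusResponse,
    bandpass_filter,
    baseline_stats,
    classify_pair,
    classify_population,
    detect_spikes,
    generate_pair_trials,
    generate_trial,
    mean_smoothed_trace,
    peak_response,
)
from kcmod.ephys import ResponseCategory, moving_average
from kcmod.synth import EphysDataset, spike_template

FS = 10_000.0


# ---------------------------------------------------------------------------
# band-pass filter


def test_constant_input_removed():
    out = bandpass_filter(np.full(20_000, -50.0), 100, 1000, FS)
    assert np.abs(out[500:-500]).max() < 1e-6 * 50.0


def _filtfilt_gain(freq_hz: float) -> float:
    # numerically evaluated two-pass magnitude response of the same design
    sos = sps.butter(2, [100, 1000], btype="bandpass", fs=FS, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=FS)
    return float(np.abs(h[0]) ** 2)


@pytest.mark.parametrize("freq", [300.0, 500.0, 700.0])
def test_passband_sinusoid_gain_matches_frequency_response(freq):
    t = np.arange(0, 4.0, 1 / FS)
    out = bandpass_filter(np.sin(2 * np.pi * freq * t), 100, 1000, FS)
    amp = np.abs(out[5000:-5000]).max()
    assert amp == pytest.approx(_filtfilt_gain(freq), rel=0.05)


def test_slow_sinusoid_attenuated_20db():
    t = np.arange(0, 4.0, 1 / FS)
    out = bandpass_filter(np.sin(2 * np.pi * 10.0 * t), 100, 1000, FS)
    assert np.abs(out[5000:-5000]).max() < 0.1  # >= 20 dB down from unit input


def test_band_outside_nyquist_rejected():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros(1000), 100, 6000, FS)
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros(1000), 0, 1000, FS)


# ---------------------------------------------------------------------------
# spike detection


def test_pure_noise_no_detections(config):
    prof = CellProfile("c", "t", {"s": StimulusResponse()}, noise_sd_mv=0.5)
    tr = generate_trial(prof, "s", LIGHT, seed=11)
    assert len(detect_spikes(tr, config).spike_times_s) == 0


def test_known_spikes_recovered_within_1ms(config):
    # 5 template spikes at fixed times over correlated noise
    rng = np.random.default_rng(0)
    prof = CellProfile("c", "t", {"s": StimulusResponse()}, noise_sd_mv=1.0)
    tr = generate_trial(prof, "s", LIGHT, seed=1)
    w, ipeak = spike_template(FS, 20.0)
    truth = [0.3, 0.8, 1.4, 1.9, 2.4]
    for t in truth:
        i0 = int(t * FS) - ipeak
        tr.voltage_mv[i0 : i0 + len(w)] += w.astype(np.float32)
    det = detect_spikes(tr, config).spike_times_s
    assert len(det) == 5
    assert np.abs(det - np.asarray(truth)).max() <= 0.001


def test_dc_offset_leaves_spike_times_unchanged(config, spiking_profile):
    tr = generate_trial(spiking_profile, "s", LIGHT, seed=5)
    t1 = detect_spikes(tr, config).spike_times_s
    tr.voltage_mv = tr.voltage_mv + np.float32(30.0)
    t2 = detect_spikes(tr, config).spike_times_s
    assert np.array_equal(t1, t2)


def test_empty_trace_rejected(config):
    with pytest.raises(ValueError):
        detect_spikes(np.empty(0), config, LIGHT)


# ---------------------------------------------------------------------------
# smoothing and windows


def test_constant_trial_smooths_to_constant():
    out = mean_smoothed_trace([np.full(5000, -50.0)], 0.05, FS)
    assert np.allclose(out, -50.0)


def test_antisymmetric_trials_average_to_zero():
    rng = np.random.default_rng(3)
    v = rng.standard_normal(5000)
    out = mean_smoothed_trace([v, -v], 0.05, FS)
    assert np.allclose(out, 0.0, atol=1e-12)


def test_step_plateau_preserved_by_moving_average():
    # a +4 mV step longer than the window keeps its plateau exactly
    x = np.zeros(8000)
    x[3000:6000] = 4.0
    w = 500
    out = moving_average(x, w)
    assert np.allclose(out[3000 + w : 6000 - w], 4.0)
    # edges are truncated means, not zero-padded artifacts
    assert out[0] == 0.0


def test_unequal_trial_lengths_rejected():
    with pytest.raises(ValueError):
        mean_smoothed_trace([np.zeros(100), np.zeros(101)], 0.05, FS)


def test_baseline_sd_estimates_unit_noise():
    # 10k i.i.d. N(0,1) baseline samples, no smoothing
    protocol = EphysProtocol(
        stimulus_onset_s=1.0, baseline_window_s=1.0, trace_duration_s=1.6,
        response_window_s=(0.0, 0.5),
    )
    rng = np.random.default_rng(8)
    trace = rng.standard_normal(protocol.n_samples)
    _, sd = baseline_stats(trace, protocol)
    assert 0.95 < sd < 1.05


def test_constant_baseline_sd_zero():
    protocol = EphysProtocol()
    mean, sd = baseline_stats(np.zeros(protocol.n_samples), protocol)
    assert sd == 0.0


def test_baseline_before_trace_start_rejected():
    with pytest.raises(ValueError):
        EphysProtocol(stimulus_onset_s=0.0, baseline_window_s=1.0)


# ---------------------------------------------------------------------------
# peak response


def _trace_with_baseline_noise(peak_mv=0.0, sd=1.0, seed=0):
    protocol = LIGHT
    rng = np.random.default_rng(seed)
    trace = np.zeros(protocol.n_samples)
    trace[protocol.baseline_slice] = rng.standard_normal(
        protocol.baseline_slice.stop - protocol.baseline_slice.start
    ) * sd
    bl_mean = trace[protocol.baseline_slice].mean()
    trace[protocol.response_slice] = bl_mean
    mid = (protocol.response_slice.start + protocol.response_slice.stop) // 2
    trace[mid] = bl_mean + peak_mv
    return trace, protocol


def test_flat_response_window_gives_zero_peak():
    trace, protocol = _trace_with_baseline_noise(0.0)
    peak, z = peak_response(trace, protocol)
    assert peak == 0.0 and z == 0.0


def test_positive_peak_and_z():
    trace, protocol = _trace_with_baseline_noise(6.0, seed=2)
    _, sd = baseline_stats(trace, protocol)
    peak, z = peak_response(trace, protocol)
    assert peak == pytest.approx(6.0)
    assert z == pytest.approx(6.0 / sd)


def test_negative_peak_signed():
    trace, protocol = _trace_with_baseline_noise(-5.0, seed=3)
    peak, z = peak_response(trace, protocol)
    assert peak == pytest.approx(-5.0) and z < 0


def test_zero_baseline_sd_rejected():
    protocol = LIGHT
    with pytest.raises(ValueError):
        peak_response(np.zeros(protocol.n_samples), protocol)


# ---------------------------------------------------------------------------
# classification


def test_strong_epsp_called_excitatory(epsp_profile, config):
    trials = generate_pair_trials(epsp_profile(6.0), "s", LIGHT, 6, seed=21)
    call = classify_pair(trials, config)
    assert call.category == ResponseCategory.EXCITATORY
    assert call.z_score >= config.z_threshold
    assert call.evoked_spike_count < config.min_evoked_spikes


def test_ipsp_called_inhibition_only(config):
    prof = CellProfile(
        "c", "t", {"s": StimulusResponse(ipsp_peak_mv=-4.0)}, noise_sd_mv=1.0
    )
    trials = generate_pair_trials(prof, "s", ODOR, 6, seed=22)
    call = classify_pair(trials, config)
    assert call.category == ResponseCategory.INHIBITION_ONLY
    assert call.z_score <= -config.z_threshold


def test_null_called_no_response(null_profile, config):
    trials = generate_pair_trials(null_profile, "s", LIGHT, 6, seed=23)
    call = classify_pair(trials, config)
    assert call.category == ResponseCategory.NO_RESPONSE
    assert abs(call.z_score) < config.z_threshold


def test_spike_takes_precedence_over_excitatory(config):
    # strong spiking AND a large EPSP: Spike wins
    prof = CellProfile(
        "c", "t",
        {"s": StimulusResponse(spike_rate_hz=30.0, epsp_peak_mv=8.0)},
        noise_sd_mv=1.0,
    )
    trials = generate_pair_trials(prof, "s", LIGHT, 6, seed=24)
    call = classify_pair(trials, config)
    assert call.category == ResponseCategory.SPIKE
    assert call.z_score > config.z_threshold  # subthreshold criterion also held


def test_threshold_monotonicity(epsp_profile, config):
    # raising the z threshold can only move calls toward NoResponse
    order = {
        ResponseCategory.NO_RESPONSE: 0,
        ResponseCategory.EXCITATORY: 1,
        ResponseCategory.INHIBITION_ONLY: 1,
        ResponseCategory.SPIKE: 2,
    }
    for amp, seed in [(0.8, 31), (1.2, 32), (1.6, 33), (2.5, 34)]:
        trials = generate_pair_trials(epsp_profile(amp), "s", LIGHT, 6, seed=seed)
        lo = classify_pair(trials, config.with_(z_threshold=3.0))
        hi = classify_pair(trials, config.with_(z_threshold=6.0))
        if hi.category == ResponseCategory.EXCITATORY:
            assert lo.category == ResponseCategory.EXCITATORY
        if lo.category == ResponseCategory.NO_RESPONSE:
            assert hi.category == ResponseCategory.NO_RESPONSE


def test_offset_invariance_of_category(epsp_profile, config):
    trials = generate_pair_trials(epsp_profile(1.3), "s", LIGHT, 6, seed=41)
    base = classify_pair(trials, config)
    for t in trials:
        t.voltage_mv = t.voltage_mv + np.float32(25.0)
    shifted = classify_pair(trials, config)
    assert shifted.category == base.category
    assert shifted.z_score == pytest.approx(base.z_score, rel=1e-4)


def test_trial_order_invariance(epsp_profile, config):
    trials = generate_pair_trials(epsp_profile(1.3), "s", LIGHT, 6, seed=42)
    a = classify_pair(trials, config)
    b = classify_pair(trials[::-1], config)
    assert a.category == b.category and a.z_score == pytest.approx(b.z_score)


def test_classify_population_counts_and_empty(config):
    from kcmod import study_design, generate_population

    profiles, stimuli = study_design(2, 1, 1, 1)
    ds = generate_population(profiles, stimuli, 3, seed=6)
    calls = classify_population(ds, config)
    assert len(calls) == 3 * 2  # (2+1 cells) x 2 stimuli
    assert classify_population(EphysDataset([]), config) == []
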