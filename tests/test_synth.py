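"""Generator contracts: determinism, noise calibration, event rendering."""

import numpy as np
import pytest
from scipy import stats

from kcmod import (
    LIGHT,
    ODOR,
    CellProfile,
    EphysProtocol,
    StimulusResponse,
    generate_pair_trials,
    generate_population,
    generate_trial,
    study_design,
)
from kcmod.synth import psp_kernel


def test_null_profile_trace_is_pure_noise(null_profile):
    tr = generate_trial(null_profile, "s", LIGHT, seed=1)
    assert len(tr.true_spike_times_s) == 0
    assert tr.true_event_peaks_mv == (0.0, 0.0)
    # sample SD close to the configured noise SD (correlated noise: generous band)
    assert 0.7 < tr.voltage_mv.std() < 1.3
    assert abs(tr.voltage_mv.mean() - LIGHT.holding_potential_mv) < 0.5


def test_same_seed_bit_identical(null_profile):
    a = generate_trial(null_profile, "s", LIGHT, seed=42)
    b = generate_trial(null_profile, "s", LIGHT, seed=42)
    assert np.array_equal(a.voltage_mv, b.voltage_mv)


def test_different_seeds_differ(null_profile):
    a = generate_pair_trials(null_profile, "s", LIGHT, 3, seed=1)
    b = generate_pair_trials(null_profile, "s", LIGHT, 3, seed=2)
    assert not np.array_equal(a[0].voltage_mv, b[0].voltage_mv)


def test_epsp_amplitude_matches_analytic_kernel_peak(epsp_profile):
    # near noise-free trial: the response-window max above baseline must equal
    # the kernel's normalized peak
    prof = CellProfile(
        "c", "t", {"s": StimulusResponse(epsp_peak_mv=6.0)}, noise_sd_mv=1e-6
    )
    tr = generate_trial(prof, "s", LIGHT, seed=3)
    baseline = tr.voltage_mv[LIGHT.baseline_slice].mean()
    peak = (tr.voltage_mv[LIGHT.response_slice] - baseline).max()
    assert peak == pytest.approx(6.0, rel=1e-3)
    # and the rendered kernel itself peaks at exactly the requested value
    # discrete sampling sits within one sample of the continuous optimum
    k = psp_kernel(0.010, 0.050, 10_000.0, 6.0)
    assert k.max() == pytest.approx(6.0, rel=1e-5)


def test_pair_trials_metadata_and_count(null_profile):
    trials = generate_pair_trials(null_profile, "s", LIGHT, 6, seed=0)
    assert [t.trial_index for t in trials] == list(range(6))
    assert len({t.cell_id for t in trials}) == 1
    with pytest.raises(ValueError):
        generate_pair_trials(null_profile, "s", LIGHT, 0, seed=0)


def test_spike_counts_within_poisson_bounds():
    # 50 Hz over the 0.5 s light window, 6 trials: mean 150 total spikes
    prof = CellProfile(
        "c", "t", {"s": StimulusResponse(spike_rate_hz=50.0)}, noise_sd_mv=1.0
    )
    trials = generate_pair_trials(prof, "s", LIGHT, 6, seed=7)
    total = sum(len(t.true_spike_times_s) for t in trials)
    lo, hi = stats.poisson.ppf([0.005, 0.995], 150)
    assert lo <= total <= hi


def test_refractory_gap_enforced():
    prof = CellProfile(
        "c", "t", {"s": StimulusResponse(spike_rate_hz=80.0)}, noise_sd_mv=1.0
    )
    for s in range(5):
        tr = generate_trial(prof, "s", LIGHT, seed=s)
        if len(tr.true_spike_times_s) > 1:
            assert np.diff(tr.true_spike_times_s).min() >= 0.005 - 1e-9


@pytest.mark.parametrize(
    "n_cells,n_stimuli,expected",
    [(12, 2, 24), (12, 5, 60), (11, 2, 22), (11, 5, 55), (0, 2, 0)],
)
def test_population_pair_counts(n_cells, n_stimuli, expected):
    resp = {f"s{i}": StimulusResponse() for i in range(n_stimuli)}
    profiles = [CellProfile(f"c{i}", "t", resp) for i in range(n_cells)]
    stimuli = {f"s{i}": LIGHT for i in range(n_stimuli)}
    ds = generate_population(profiles, stimuli, n_trials=2, seed=0)
    assert ds.n_pairs == expected


def test_population_missing_stimulus_rejected():
    profiles = [CellProfile("c", "t", {"a": StimulusResponse()})]
    with pytest.raises(KeyError):
        generate_population(profiles, {"a": LIGHT, "b": LIGHT}, 2, seed=0)


def test_population_deterministic():
    profiles, stimuli = study_design(2, 1, 1, 1)
    d1 = generate_population(profiles, stimuli, 2, seed=5)
    d2 = generate_population(profiles, stimuli, 2, seed=5)
    assert all(
        np.array_equal(a.voltage_mv, b.voltage_mv) for a, b in zip(d1.trials, d2.trials)
    )


def test_invalid_protocols_and_profiles_rejected():
    with pytest.raises(ValueError):
        EphysProtocol(stimulus_onset_s=0.0, baseline_window_s=1.0)
    with pytest.raises(ValueError):
        EphysProtocol(trace_duration_s=-1.0)
    with pytest.raises(ValueError):
        StimulusResponse(epsp_peak_mv=-1.0)
    with pytest.raises(ValueError):
        StimulusResponse(ipsp_peak_mv=0.5)
    with pytest.raises(ValueError):
        CellProfile("c", "t", {}, noise_sd_mv=0.0)


def test_study_design_sizes():
    profiles, stimuli = study_design()
    assert sum(p.cell_type == "gamma_d" for p in profiles) == 12
    assert sum(p.cell_type == "alpha_beta" for p in profiles) == 11
    assert sum(p.modality == "light" for p in stimuli.values()) == 2
    assert sum(p.modality == "odor" for p in stimuli.values()) == 5
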