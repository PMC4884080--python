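"""Synthetic whole-cell recording generator with ground truth.

Each trial is holding potential + temporally correlated (Ornstein-Uhlenbeck)
membrane noise + stimulus-locked events: spikes rendered from a stereotyped
biphasic template at times drawn from a Poisson process with an absolute
refractory gap, and EPSP/IPSP deflections rendered as difference-of-
exponentials kernels scaled to a stated peak.  Every rendered event is
recorded in the trial's ground truth, so detection and classification can be
scored exactly.

The defaults emulate the phenomenology of mushroom-body Kenyon-cell
recordings: ~1 mV correlated noise around a -50 mV hold, fast light-evoked
EPSPs (10 ms rise / 50 ms decay), slow odor-evoked IPSPs (100 ms rise /
500 ms decay), and spikes of a few tens of mV after high-pass filtering.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .protocols import EphysProtocol, LIGHT, ODOR

__all__ = [
    "StimulusResponse",
    "CellProfile",
    "TrialRecording",
    "EphysDataset",
    "generate_trial",
    "generate_pair_trials",
    "generate_population",
    "psp_kernel",
    "spike_template",
    "gamma_d_profile",
    "alpha_beta_profile",
]


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class StimulusResponse:
    """Ground-truth response specification of one cell to one stimulus.

    ``spike_rate_hz`` applies within the response window; PSP peaks are in mV
    relative to baseline (EPSP >= 0, IPSP <= 0). Kernel time constants are
    (rise, decay) in seconds.
    """

    spike_rate_hz: float = 0.0
    spike_amplitude_mv: float = 25.0
    epsp_peak_mv: float = 0.0
    ipsp_peak_mv: float = 0.0
    latency_s: float = 0.02
    epsp_tau_s: Tuple[float, float] = (0.010, 0.050)
    ipsp_tau_s: Tuple[float, float] = (0.100, 0.500)

    def __post_init__(self) -> None:
        if self.spike_rate_hz < 0:
            raise ValueError("spike_rate_hz must be >= 0")
        if self.epsp_peak_mv < 0:
            raise ValueError("epsp_peak_mv must be >= 0")
        if self.ipsp_peak_mv > 0:
            raise ValueError("ipsp_peak_mv must be <= 0")


@dataclass(frozen=True)
class CellProfile:
    """A simulated cell: type label, per-stimulus responses, noise level."""

    cell_id: str
    cell_type: str  # "gamma_d" | "alpha_beta"
    responses: Dict[str, StimulusResponse]
    noise_sd_mv: float = 1.0
    noise_tau_s: float = 0.020

    def __post_init__(self) -> None:
        if self.noise_sd_mv <= 0:
            raise ValueError("noise_sd_mv must be positive")
        if self.noise_tau_s <= 0:
            raise ValueError("noise_tau_s must be positive")

    def response_for(self, stimulus_id: str) -> StimulusResponse:
        try:
            return self.responses[stimulus_id]
        except KeyError:
            raise KeyError(
                f"profile {self.cell_id!r} has no response spec for stimulus "
                f"{stimulus_id!r}"
            ) from None


@dataclass
class TrialRecording:
    """One cell-stimulus trial: voltage samples plus metadata and truth."""

    cell_id: str
    cell_type: str
    stimulus_id: str
    modality: str
    trial_index: int
    voltage_mv: np.ndarray
    protocol: EphysProtocol
    true_spike_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_event_peaks_mv: Tuple[float, float] = (0.0, 0.0)  # (epsp, ipsp)

    @property
    def duration_s(self) -> float:
        return len(self.voltage_mv) / self.protocol.sampling_rate_hz


# ---------------------------------------------------------------------------
# waveform primitives


@functools.lru_cache(maxsize=64)
def _unit_psp_kernel(
    tau_rise_s: float, tau_decay_s: float, sampling_rate_hz: float
) -> np.ndarray:
    if not 0 < tau_rise_s < tau_decay_s:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t_end = tau_decay_s * math.log(1e3) + 5 * tau_rise_s
    t = np.arange(0.0, t_end, 1.0 / sampling_rate_hz)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    # closed-form peak location of the difference of exponentials
    t_peak = (
        tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
        * math.log(tau_decay_s / tau_rise_s)
    )
    k_peak = math.exp(-t_peak / tau_decay_s) - math.exp(-t_peak / tau_rise_s)
    k = k / k_peak
    k.setflags(write=False)
    return k


def psp_kernel(
    tau_rise_s: float, tau_decay_s: float, sampling_rate_hz: float, peak_mv: float
) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to ``peak_mv``.

    k(t) = exp(-t/tau_d) - exp(-t/tau_r), scaled so its maximum equals
    ``peak_mv``; truncated where the decay envelope falls below 1e-3 of peak.
    """
    return peak_mv * _unit_psp_kernel(tau_rise_s, tau_decay_s, sampling_rate_hz)


@functools.lru_cache(maxsize=16)
def _unit_spike_template(sampling_rate_hz: float) -> Tuple[np.ndarray, int]:
    t = np.arange(0.0, 0.012, 1.0 / sampling_rate_hz)
    up = np.exp(-((t - 0.002) / 0.00085) ** 2)
    down = 0.10 * np.exp(-((t - 0.004) / 0.0012) ** 2)
    w = up - down
    w.setflags(write=False)
    return w, int(np.argmax(w))


def spike_template(
    sampling_rate_hz: float, amplitude_mv: float = 25.0
) -> Tuple[np.ndarray, int]:
    """Stereotyped biphasic spike waveform; returns (template, peak index).

    A depolarizing Gaussian lobe of ~2 ms half-width followed by a shallow,
    fast after-hyperpolarization; ``amplitude_mv`` is the positive peak.
    The AHP is kept shallow so the band-passed waveform's rebound lobe stays
    well below the main peak (a few percent), as in real somatic spikes.
    """
    w, ipeak = _unit_spike_template(sampling_rate_hz)
    return amplitude_mv * w, ipeak


def _ou_noise(
    n: int, sd: float, tau_s: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise via its exact AR(1) discretization."""
    rho = math.exp(-1.0 / (fs * tau_s))
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    white = rng.standard_normal(n, dtype=np.float32)
    white *= np.float32(innov_sd)
    b = np.array([1.0], dtype=np.float32)
    a = np.array([1.0, -rho], dtype=np.float32)
    x = lfilter(b, a, white)
    # lfilter starts from 0; superpose the decaying influence of a stationary
    # initial state so the first samples are not biased toward zero variance.
    # The correction is negligible (and numerically subnormal) past ~20 tau.
    x0 = rng.standard_normal() * sd
    m = min(n, int(20 * tau_s * fs) + 1)
    x[:m] += np.float32(x0) * np.exp(
        np.arange(1, m + 1, dtype=np.float32) * np.float32(math.log(rho))
    )
    return x


def _poisson_times_with_refractory(
    rate_hz: float, t0: float, t1: float, refractory_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-count spike times in [t0, t1) with a hard minimum gap.

    The count is drawn Poisson(rate*(t1-t0)); points are placed uniformly in
    the window contracted by (N-1)*refractory and re-expanded, which keeps the
    count distribution exactly Poisson while enforcing the refractory gap.
    """
    T = t1 - t0
    if rate_hz <= 0 or T <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * T)
    n_max = int(T / refractory_s) if refractory_s > 0 else n
    n = min(n, n_max)
    if n == 0:
        return np.empty(0)
    free = T - (n - 1) * refractory_s
    u = np.sort(rng.uniform(0.0, free, size=n))
    return t0 + u + refractory_s * np.arange(n)


# ---------------------------------------------------------------------------
# generation


def generate_trial(
    profile: CellProfile,
    stimulus_id: str,
    protocol: EphysProtocol,
    seed,
    trial_index: int = 0,
) -> TrialRecording:
    """Simulate one trial for ``profile`` under ``protocol``.

    ``seed`` may be an int, a SeedSequence, or a Generator. The voltage is
    holding potential + OU noise + rendered stimulus-locked events; all
    rendered spikes and the PSP peaks are stored as ground truth.
    """
    rng = np.random.default_rng(seed)
    spec = profile.response_for(stimulus_id)
    fs = protocol.sampling_rate_hz
    n = protocol.n_samples
    if n <= 0:
        raise ValueError("trace duration must be positive")

    # traces are stored single-precision: ~0.1 uV quantization, far below any
    # physiological or analysis scale, at half the memory of double
    v = np.full(n, protocol.holding_potential_mv, dtype=np.float32)
    v += _ou_noise(n, profile.noise_sd_mv, profile.noise_tau_s, fs, rng)

    onset = protocol.stimulus_onset_s
    rw_lo, rw_hi = protocol.response_window_s

    # subthreshold events: one kernel each, stimulus-locked at onset+latency
    for peak, taus in (
        (spec.epsp_peak_mv, spec.epsp_tau_s),
        (spec.ipsp_peak_mv, spec.ipsp_tau_s),
    ):
        if peak != 0.0:
            k = psp_kernel(taus[0], taus[1], fs, peak)
            if len(k) > n:
                raise ValueError("PSP kernel longer than trace")
            i0 = int(round((onset + spec.latency_s) * fs))
            seg = min(len(k), n - i0)
            if seg <= 0:
                raise ValueError("event latency places kernel outside trace")
            v[i0 : i0 + seg] += k[:seg].astype(np.float32)

    # spikes: Poisson within the response window, biphasic template
    spike_times = _poisson_times_with_refractory(
        spec.spike_rate_hz, onset + rw_lo, onset + rw_hi, 0.005, rng
    )
    if len(spike_times):
        w, ipeak = spike_template(fs, spec.spike_amplitude_mv)
        kept = []
        w32 = w.astype(np.float32)
        for t in spike_times:
            i0 = int(round(t * fs)) - ipeak
            if i0 < 0 or i0 + len(w) > n:
                continue
            v[i0 : i0 + len(w)] += w32
            kept.append((i0 + ipeak) / fs)
        spike_times = np.asarray(kept)

    return TrialRecording(
        cell_id=profile.cell_id,
        cell_type=profile.cell_type,
        stimulus_id=stimulus_id,
        modality=protocol.modality,
        trial_index=trial_index,
        voltage_mv=v,
        protocol=protocol,
        true_spike_times_s=spike_times,
        true_event_peaks_mv=(spec.epsp_peak_mv, spec.ipsp_peak_mv),
    )


def generate_pair_trials(
    profile: CellProfile,
    stimulus_id: str,
    protocol: EphysProtocol,
    n_trials: int = 6,
    seed=0,
) -> List[TrialRecording]:
    """Simulate ``n_trials`` repeats of one cell-stimulus pair (default 6)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    return [
        generate_trial(profile, stimulus_id, protocol, child, trial_index=i)
        for i, child in enumerate(children)
    ]


class EphysDataset:
    """A population of trials grouped by cell-stimulus pair."""

    def __init__(self, trials: Sequence[TrialRecording]):
        self.trials = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def pairs(self) -> Dict[Tuple[str, str], List[TrialRecording]]:
        out: Dict[Tuple[str, str], List[TrialRecording]] = {}
        for tr in self.trials:
            out.setdefault((tr.cell_id, tr.stimulus_id), []).append(tr)
        for v in out.values():
            v.sort(key=lambda t: t.trial_index)
        return out

    @property
    def n_pairs(self) -> int:
        return len(self.pairs())


def generate_population(
    profiles: Sequence[CellProfile],
    stimuli: Dict[str, EphysProtocol],
    n_trials: int = 6,
    seed=0,
) -> EphysDataset:
    """Simulate every profile against every stimulus.

    ``stimuli`` maps stimulus id to its protocol (so light and odor stimuli
    can coexist in one population). Each profile must carry a response spec
    for each stimulus. Pair count = n_profiles x n_stimuli.
    """
    for p in profiles:
        for s in stimuli:
            p.response_for(s)  # raises KeyError with context if missing
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trials: List[TrialRecording] = []
    keys = [(p, s) for p in profiles for s in sorted(stimuli)]
    for (p, s), child in zip(keys, ss.spawn(max(len(keys), 1))):
        trials.extend(generate_pair_trials(p, s, stimuli[s], n_trials, child))
    return EphysDataset(trials)


# ---------------------------------------------------------------------------
# canonical study profiles


def _light_stims() -> List[str]:
    return ["blue", "green"]


def _odor_stims() -> List[str]:
    return ["OCT", "MCH", "HEP", "BZA", "PAA"]


def gamma_d_profile(cell_id: str, noise_sd_mv: float = 1.0) -> CellProfile:
    """Visually tuned profile: light evokes spikes and fast EPSPs, odors evoke
    slow inhibition."""
    resp: Dict[str, StimulusResponse] = {}
    for s in _light_stims():
        resp[s] = StimulusResponse(spike_rate_hz=20.0, epsp_peak_mv=8.0)
    for s in _odor_stims():
        resp[s] = StimulusResponse(ipsp_peak_mv=-4.0)
    return CellProfile(cell_id, "gamma_d", resp, noise_sd_mv=noise_sd_mv)


def alpha_beta_profile(cell_id: str, noise_sd_mv: float = 1.0) -> CellProfile:
    """Olfactory profile: odors evoke spikes and EPSPs, light evokes nothing."""
    resp: Dict[str, StimulusResponse] = {}
    for s in _light_stims():
        resp[s] = StimulusResponse()
    for s in _odor_stims():
        resp[s] = StimulusResponse(spike_rate_hz=8.0, epsp_peak_mv=6.0)
    return CellProfile(cell_id, "alpha_beta", resp, noise_sd_mv=noise_sd_mv)


def study_design(
    n_gamma_d: int = 12,
    n_alpha_beta: int = 11,
    n_light: int = 2,
    n_odor: int = 5,
    noise_sd_mv: float = 1.0,
) -> Tuple[List[CellProfile], Dict[str, EphysProtocol]]:
    """Profiles and stimulus map at the study's design sizes.

    Defaults give 12 and 11 cells with 2 light and 5 odor stimuli, i.e.
    24/22 light-cell pairs and 60/55 odor-cell pairs.
    """
    light = _light_stims()[:n_light]
    odor = _odor_stims()[:n_odor]
    profiles = [
        gamma_d_profile(f"gd_{i:02d}", noise_sd_mv) for i in range(n_gamma_d)
    ] + [alpha_beta_profile(f"ab_{i:02d}", noise_sd_mv) for i in range(n_alpha_beta)]
    # restrict each profile's response dict to the selected stimuli
    keep = set(light) | set(odor)
    profiles = [
        CellProfile(
            p.cell_id,
            p.cell_type,
            {k: v for k, v in p.responses.items() if k in keep},
            p.noise_sd_mv,
            p.noise_tau_s,
        )
        for p in profiles
    ]
    stimuli = {s: LIGHT for s in light}
    stimuli.update({s: ODOR for s in odor})
    return profiles, stimuli
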