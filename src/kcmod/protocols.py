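"""Acquisition protocols and classifier configuration.

These dataclasses hold every protocol constant used downstream: sampling
rate, stimulus timing, the per-modality response and baseline windows, the
band of the spike-isolation filter, the smoothing window and the z-criterion
for subthreshold responses.  Nothing else in the package hard-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Tuple

__all__ = ["EphysProtocol", "ClassifierConfig", "LIGHT", "ODOR"]


@dataclass(frozen=True)
class EphysProtocol:
    """Timing and acquisition constants for one recording modality.

    Windows are expressed relative to stimulus onset: ``response_window_s``
    is (start, end) after onset, ``baseline_window_s`` is the length of the
    pre-onset stretch over which baseline fluctuations are measured.
    ``acquisition_lowpass_hz`` documents the hardware anti-alias filter; it
    is metadata only and is never applied in software.
    """

    sampling_rate_hz: float = 10_000.0
    acquisition_lowpass_hz: float = 5_000.0
    stimulus_onset_s: float = 1.2
    stimulus_duration_s: float = 1.0
    response_window_s: Tuple[float, float] = (0.0, 0.5)
    baseline_window_s: float = 1.0
    trace_duration_s: float = 3.0
    holding_potential_mv: float = -50.0
    modality: str = "light"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.stimulus_duration_s <= 0:
            raise ValueError("stimulus_duration_s must be positive")
        if self.baseline_window_s <= 0:
            raise ValueError("baseline_window_s must be positive")
        if self.stimulus_onset_s < 0:
            raise ValueError("stimulus_onset_s must be non-negative")
        lo, hi = self.response_window_s
        if not hi > lo:
            raise ValueError("response window must have positive length")
        if self.baseline_window_s > self.stimulus_onset_s + 1e-12:
            raise ValueError(
                "baseline window (%.3f s) does not fit before stimulus onset at "
                "%.3f s" % (self.baseline_window_s, self.stimulus_onset_s)
            )
        if self.stimulus_onset_s + hi > self.trace_duration_s + 1e-12:
            raise ValueError("response window extends past end of trace")

    # -- derived sample indices -------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round(self.trace_duration_s * self.sampling_rate_hz))

    @property
    def onset_index(self) -> int:
        return int(round(self.stimulus_onset_s * self.sampling_rate_hz))

    @property
    def baseline_slice(self) -> slice:
        start = self.onset_index - int(round(self.baseline_window_s * self.sampling_rate_hz))
        return slice(start, self.onset_index)

    @property
    def response_slice(self) -> slice:
        lo, hi = self.response_window_s
        fs = self.sampling_rate_hz
        return slice(
            self.onset_index + int(round(lo * fs)),
            self.onset_index + int(round(hi * fs)) + 1,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["response_window_s"] = list(self.response_window_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EphysProtocol":
        d = dict(d)
        d["response_window_s"] = tuple(d["response_window_s"])
        return cls(**d)


#: Visual stimulation protocol: 1 s pre-onset baseline, 0–0.5 s response window.
LIGHT = EphysProtocol(
    stimulus_onset_s=1.2,
    response_window_s=(0.0, 0.5),
    baseline_window_s=1.0,
    trace_duration_s=3.0,
    modality="light",
)

#: Odor stimulation protocol: 3 s pre-onset baseline, 0.2–3 s response window.
ODOR = EphysProtocol(
    stimulus_onset_s=3.2,
    response_window_s=(0.2, 3.0),
    baseline_window_s=3.0,
    trace_duration_s=6.5,
    modality="odor",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the response classifier.

    ``spike_threshold_sd`` scales a robust estimate (1.4826 x MAD) of the
    band-passed trace's noise to an amplitude threshold; ``z_threshold`` is
    the subthreshold criterion in baseline standard deviations.  The evoked
    spiking ('Spike' category) rule: trial-summed response-window spike count
    must exceed the upper ``1 - spike_rate_alpha`` Poisson bound of the
    baseline rate scaled to the window, and be at least ``min_evoked_spikes``.
    """

    bandpass_low_hz: float = 100.0
    bandpass_high_hz: float = 1000.0
    spike_threshold_sd: float = 5.0
    spike_refractory_s: float = 0.005
    smoothing_window_s: float = 0.05
    z_threshold: float = 4.2
    min_evoked_spikes: int = 2
    spike_rate_alpha: float = 0.01
    sidelobe_window_s: float = 0.010
    sidelobe_ratio: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.smoothing_window_s <= 0:
            raise ValueError("smoothing_window_s must be positive")
        if self.spike_threshold_sd <= 0:
            raise ValueError("spike_threshold_sd must be positive")
        if not 0 < self.spike_rate_alpha < 1:
            raise ValueError("spike_rate_alpha must be in (0,1)")

    def with_(self, **kw) -> "ClassifierConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        return cls(**d)
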