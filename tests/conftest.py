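import numpy as np
import pytest

from kcmod import ClassifierConfig, LIGHT, ODOR, CellProfile, StimulusResponse


@pytest.fixture(scope="session")
def config() -> ClassifierConfig:
    return ClassifierConfig()


@pytest.fixture
def null_profile() -> CellProfile:
    return CellProfile("null", "none", {"s": StimulusResponse()}, noise_sd_mv=1.0)


@pytest.fixture
def epsp_profile():
    def make(peak_mv: float, **kw) -> CellProfile:
        return CellProfile(
            "cell", "type", {"s": StimulusResponse(epsp_peak_mv=peak_mv, **kw)}, noise_sd_mv=1.0
        )

    return make


@pytest.fixture
def spiking_profile() -> CellProfile:
    return CellProfile(
        "cell", "type",
        {"s": StimulusResponse(spike_rate_hz=20.0, spike_amplitude_mv=20.0)},
        noise_sd_mv=1.0,
    )
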