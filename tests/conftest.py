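import numpy as np
import pytest

from pcvalve import (AcquisitionParams, ValveModel, generate_diastolic_waveform,
                     synthesize_pc_series)


@pytest.fixture
def valve29():
    """Normal 29 mm valve: AOA 2.7 cm^2, Cc 0.62, A_eff 1.674 cm^2."""
    return ValveModel.from_size(29, 0)


@pytest.fixture
def waveform90():
    """Half-sine filling waveform, 90 mL at 70 bpm, default filling fraction."""
    return generate_diastolic_waveform(90.0, 70.0)


@pytest.fixture
def clean_params():
    """Noise-free acquisition with a vanishing temporal window."""
    return AcquisitionParams(noise_sd_cm_s=0.0, temporal_window_ms=1e-9)


@pytest.fixture
def clean_series(waveform90, valve29, clean_params):
    """Noise-free default-geometry series of the 29 mm valve at 90 mL."""
    return synthesize_pc_series(waveform90, valve29, clean_params)


@pytest.fixture
def uniform_series_factory():
    """Factory for noise-free top-hat ('uniform jet') series on a fine grid."""

    def make(valve, waveform, frame_interval_ms=10.0):
        params = AcquisitionParams(
            pixel_spacing_mm=(0.6, 0.45),
            grid_size=(128, 144),
            frame_interval_ms=frame_interval_ms,
            temporal_window_ms=1e-9,
            noise_sd_cm_s=0.0,
            venc_cm_s=800.0,  # above every uniform-jet peak: no wrapping
        )
        return synthesize_pc_series(waveform, valve, params, edge_mm=0.0, skirt=0.0)

    return make
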