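from dataclasses import replace

import numpy as np
import pytest

import actometry as am


@pytest.fixture
def meta():
    return am.AnimalMeta(subject_id="wt01", group="Wt", body_weight_g=16.9, age_days=36)


@pytest.fixture
def motionless_config():
    """Twitcher-weight animal, no tremor, never moving, noise-free sensors."""
    return replace(
        am.PRESETS["Twi"],
        tremor=am.TremorModel(mode="none"),
        locomotion=am.LocomotionModel(
            speed_mean=0.0, speed_sd=0.0, pause_prob=1.0, pause_dwell_s=1e9
        ),
        sensor_noise_sd_gf=0.0,
    )


@pytest.fixture
def stationary_tremor_config():
    """Broadband tremor on an otherwise stationary animal (spectral tests)."""
    return replace(
        am.PRESETS["Twi"],
        locomotion=am.LocomotionModel(
            speed_mean=0.0, speed_sd=0.0, pause_prob=1.0, pause_dwell_s=1e9
        ),
    )


def make_recording(forces, meta, sample_rate=100.0):
    return am.Recording(forces=np.asarray(forces, float), sample_rate=sample_rate, meta=meta)


@pytest.fixture
def tone_recording(meta):
    """60-s recording: constant body weight plus an exact-bin 12.0 Hz tone."""
    t = np.arange(6000) / 100.0
    fz = meta.body_weight_g * (1.0 + 0.02 * np.sqrt(2) * np.sin(2 * np.pi * 12.0 * t))
    forces = np.tile((fz / 4.0)[:, None], (1, 4))
    return make_recording(forces, meta)
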