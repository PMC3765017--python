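"""Synthetic force-plate recordings with the structure of the study groups.

No raw recordings of the original cohorts exist in machine-readable form,
so every stage of the pipeline is exercised on simulated sessions whose
statistical structure mirrors the phenotypes the instrument was built to
measure:

* untreated wildtype (Wt): low-frequency (< 8 Hz) movement-related force
  oscillation only, no tremor;
* twitcher (Twi): broadband high-frequency tremor — Gaussian noise
  band-passed symmetrically around a 15.8 Hz center;
* harmaline-treated wildtype (WtH): the classic narrow-band near-12-Hz
  olivocerebellar tremor — a phase-jittered sinusoid at 12.2 Hz;
* harmaline on a twitcher or BMT background (TwiH, BmtTwiH): a blunted
  response — the broadband tremor plus the narrow-band component
  attenuated to 10% of the wildtype harmaline amplitude;
* BMT groups: broadband spectra shifted toward higher frequencies
  relative to their untransplanted counterparts.

A session is built in five steps: (1) draw a body weight from the group
distribution; (2) simulate a bounded random-walk center-of-pressure path
inside the 200-mm sensing square, with pauses, reflecting at the walls;
(3) build Fz = weight x (1 + tremor + ...) plus white sensor noise;
(4) distribute Fz onto the four corner load cells with bilinear weights
consistent with the path (so the moment computation recovers the path
exactly in the noise-free case); (5) quantize to 12-bit counts through
the calibration.  Everything is deterministic given a seed.

Tremor amplitude is parameterized as RMS percent of body weight, so the
percent-body-weight normalization of the spectral pipeline makes spectra
comparable across the very different group weight distributions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.fft import irfft, rfft, rfftfreq

from .io import AnimalMeta, Calibration, PlateGeometry, Recording

__all__ = [
    "TremorModel",
    "LocomotionModel",
    "PhenotypeConfig",
    "PRESETS",
    "simulate_recording",
    "simulate_cohort",
    "save_config",
    "load_config",
    "preset_path",
    "config_to_dict",
    "config_from_dict",
]

DEFAULT_DURATION_S = 360.0
DEFAULT_SAMPLE_RATE = 100.0
#: COP excursion bound (mm): the animal's center of force stays a little
#: inside the 100-mm half-side because its body has extent.
WALL_MM = 95.0


@dataclass(frozen=True)
class TremorModel:
    """Oscillatory component of Fz.

    ``mode``: one of ``none | narrowband | broadband | blunted``.
    ``f0``/``half_width`` define the band (Hz): for narrowband, the
    carrier frequency and approximate half-linewidth of the phase-jittered
    sinusoid; for broadband, a brick-wall band [f0-hw, f0+hw] applied to
    white Gaussian noise.  ``amplitude_pct`` is the RMS amplitude as a
    percent of body weight.  ``blunted`` superimposes the broadband model
    and a narrowband component at ``narrow_f0`` attenuated by
    ``narrow_attenuation`` (a modeling knob, not a biological constant).
    """

    mode: str = "none"
    f0: float = 15.8
    half_width: float = 3.0
    amplitude_pct: float = 0.0
    narrow_f0: float = 12.2
    narrow_amplitude_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "narrowband", "broadband", "blunted"):
            raise ValueError(f"unknown tremor mode {self.mode!r}")
        if self.mode != "none" and not 2.5 < self.f0 < 30.0:
            raise ValueError("tremor center frequency must lie in (2.5, 30) Hz")
        if self.amplitude_pct < 0 or self.narrow_amplitude_pct < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")


@dataclass(frozen=True)
class LocomotionModel:
    """Random-walk model of the animal's movement on the plate.

    Speeds (mm/s) are drawn per 0.5-s block from a truncated normal;
    heading diffuses per sample.  Pausing is a two-state Markov chain at
    the block level: ``pause_prob`` is the per-second probability of
    entering a pause, ``pause_dwell_s`` the mean pause duration.
    """

    speed_mean: float = 30.0
    speed_sd: float = 10.0
    pause_prob: float = 0.1
    pause_dwell_s: float = 2.0
    heading_sd: float = 0.2  # rad per sample

    def __post_init__(self) -> None:
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be in [0, 1]")
        if self.speed_mean < 0 or self.speed_sd < 0 or self.pause_dwell_s < 0:
            raise ValueError("locomotion parameters must be non-negative")


@dataclass(frozen=True)
class PhenotypeConfig:
    """Everything needed to simulate one group's recordings."""

    group: str
    weight_mean_g: float
    weight_sd_g: float
    tremor: TremorModel = field(default_factory=TremorModel)
    locomotion: LocomotionModel = field(default_factory=LocomotionModel)
    sensor_noise_sd_gf: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weight_mean_g <= 0 or self.weight_sd_g < 0:
            raise ValueError("weight distribution must be positive")
        if self.sensor_noise_sd_gf < 0:
            raise ValueError("sensor noise sd must be non-negative")


# Group presets.  Weights for Wt/Twi are the printed 36-day colony means;
# BMT weights and all locomotion/tremor amplitudes are modeling choices
# documented in the methods note.
PRESETS: dict[str, PhenotypeConfig] = {
    "Wt": PhenotypeConfig(
        group="Wt",
        weight_mean_g=16.9,
        weight_sd_g=1.8,
        tremor=TremorModel(mode="broadband", f0=5.0, half_width=2.5, amplitude_pct=1.0),
        locomotion=LocomotionModel(speed_mean=40.0, speed_sd=15.0, pause_prob=0.05, pause_dwell_s=2.0),
    ),
    "Twi": PhenotypeConfig(
        group="Twi",
        weight_mean_g=10.4,
        weight_sd_g=1.6,
        tremor=TremorModel(mode="broadband", f0=15.8, half_width=3.0, amplitude_pct=2.0),
        locomotion=LocomotionModel(speed_mean=15.0, speed_sd=8.0, pause_prob=0.25, pause_dwell_s=4.0),
    ),
    "BmtWt": PhenotypeConfig(
        group="BmtWt",
        weight_mean_g=15.5,
        weight_sd_g=1.8,
        tremor=TremorModel(mode="broadband", f0=12.0, half_width=4.0, amplitude_pct=1.8),
        locomotion=LocomotionModel(speed_mean=25.0, speed_sd=10.0, pause_prob=0.15, pause_dwell_s=3.0),
    ),
    "BmtTwi": PhenotypeConfig(
        group="BmtTwi",
        weight_mean_g=10.0,
        weight_sd_g=1.6,
        tremor=TremorModel(mode="broadband", f0=14.0, half_width=5.0, amplitude_pct=2.2),
        locomotion=LocomotionModel(speed_mean=12.0, speed_sd=6.0, pause_prob=0.3, pause_dwell_s=4.0),
    ),
    "WtH": PhenotypeConfig(
        group="WtH",
        weight_mean_g=16.9,
        weight_sd_g=1.8,
        tremor=TremorModel(mode="narrowband", f0=12.2, half_width=0.25, amplitude_pct=4.0),
        locomotion=LocomotionModel(speed_mean=10.0, speed_sd=5.0, pause_prob=0.4, pause_dwell_s=5.0),
    ),
    "TwiH": PhenotypeConfig(
        group="TwiH",
        weight_mean_g=10.4,
        weight_sd_g=1.6,
        tremor=TremorModel(
            mode="blunted", f0=15.8, half_width=3.0, amplitude_pct=2.0,
            narrow_f0=12.2, narrow_amplitude_pct=0.4,
        ),
        locomotion=LocomotionModel(speed_mean=10.0, speed_sd=5.0, pause_prob=0.4, pause_dwell_s=5.0),
    ),
    "BmtWtH": PhenotypeConfig(
        group="BmtWtH",
        weight_mean_g=15.5,
        weight_sd_g=1.8,
        tremor=TremorModel(
            mode="blunted", f0=12.5, half_width=3.5, amplitude_pct=1.8,
            narrow_f0=12.2, narrow_amplitude_pct=0.4,
        ),
        locomotion=LocomotionModel(speed_mean=12.0, speed_sd=6.0, pause_prob=0.35, pause_dwell_s=4.0),
    ),
    "BmtTwiH": PhenotypeConfig(
        group="BmtTwiH",
        weight_mean_g=10.0,
        weight_sd_g=1.6,
        tremor=TremorModel(
            mode="blunted", f0=14.0, half_width=5.0, amplitude_pct=2.2,
            narrow_f0=12.2, narrow_amplitude_pct=0.4,
        ),
        locomotion=LocomotionModel(speed_mean=10.0, speed_sd=5.0, pause_prob=0.4, pause_dwell_s=5.0),
    ),
}


def config_to_dict(config: PhenotypeConfig) -> dict:
    return {
        "group": config.group,
        "weight_mean_g": config.weight_mean_g,
        "weight_sd_g": config.weight_sd_g,
        "sensor_noise_sd_gf": config.sensor_noise_sd_gf,
        "seed": config.seed,
        "tremor": asdict(config.tremor),
        "locomotion": asdict(config.locomotion),
    }


def config_from_dict(data: dict) -> PhenotypeConfig:
    return PhenotypeConfig(
        group=data["group"],
        weight_mean_g=float(data["weight_mean_g"]),
        weight_sd_g=float(data["weight_sd_g"]),
        sensor_noise_sd_gf=float(data.get("sensor_noise_sd_gf", 0.1)),
        seed=data.get("seed"),
        tremor=TremorModel(**data.get("tremor", {})),
        locomotion=LocomotionModel(**data.get("locomotion", {})),
    )


def save_config(config: PhenotypeConfig, path: str | Path) -> Path:
    """Write a phenotype preset as a YAML config file."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> PhenotypeConfig:
    """Read a phenotype preset from a YAML config file."""
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


#: Directory of shipped per-group preset config files (wt.yaml, twi.yaml, ...).
PRESET_DIR = Path(__file__).parent / "presets"


def preset_path(group: str) -> Path:
    """Path of the shipped YAML preset for a group label."""
    if group not in PRESETS:
        raise KeyError(f"unknown group {group!r}")
    return PRESET_DIR / f"{group.lower()}.yaml"


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return x
    return x / rms


def _narrowband_tone(
    n: int, fs: float, f0: float, half_width: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase-jittered sinusoid with approximate Lorentzian half-linewidth."""
    t = np.arange(n) / fs
    # phase-diffusion step variance giving FWHM ~ 2 * half_width
    sigma2 = 2.0 * np.pi * max(2.0 * half_width, 1e-9) / fs
    jitter = np.cumsum(rng.normal(0.0, np.sqrt(sigma2), n))
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * f0 * t + jitter)


def _bandlimited_noise(
    n: int, fs: float, f0: float, half_width: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise brick-wall band-passed to [f0-hw, f0+hw]."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    freqs = rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    spec[~keep] = 0.0
    return _unit_rms(irfft(spec, n))


def _tremor_signal(
    model: TremorModel, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Tremor component in units of fraction-of-body-weight."""
    if model.mode == "none" or (
        model.amplitude_pct == 0 and model.narrow_amplitude_pct == 0
    ):
        return np.zeros(n)
    amp = model.amplitude_pct / 100.0
    if model.mode == "narrowband":
        return amp * _unit_rms(_narrowband_tone(n, fs, model.f0, model.half_width, rng))
    if model.mode == "broadband":
        return amp * _bandlimited_noise(n, fs, model.f0, model.half_width, rng)
    # blunted: broadband plus attenuated narrowband
    broad = amp * _bandlimited_noise(n, fs, model.f0, model.half_width, rng)
    narrow = (model.narrow_amplitude_pct / 100.0) * _unit_rms(
        _narrowband_tone(n, fs, model.narrow_f0, 0.25, rng)
    )
    return broad + narrow


def _fold(p: np.ndarray, bound: float) -> np.ndarray:
    """Reflect an unbounded path into [-bound, bound] (billiard walls)."""
    period = 4.0 * bound
    return np.abs(((p + bound) % period) - 2.0 * bound) - bound


def _cop_path(
    model: LocomotionModel, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Bounded random-walk COP path (n, 2) in mm."""
    block = int(round(0.5 * fs))
    n_blocks = int(np.ceil(n / block))
    # block-level pause Markov chain
    p_enter = min(1.0, model.pause_prob * 0.5)
    p_exit = 1.0 if model.pause_dwell_s == 0 else min(1.0, 0.5 / model.pause_dwell_s)
    moving = np.empty(n_blocks, dtype=bool)
    state = rng.random() > model.pause_prob  # stationary-ish initial state
    for b in range(n_blocks):
        if state:
            state = rng.random() >= p_enter
        else:
            state = rng.random() < p_exit
        moving[b] = state
    speeds = np.clip(rng.normal(model.speed_mean, model.speed_sd, n_blocks), 0.0, None)
    speeds[~moving] = 0.0
    speed_per_sample = np.repeat(speeds, block)[:n]
    heading = np.cumsum(rng.normal(0.0, model.heading_sd, n))
    heading += rng.uniform(0.0, 2.0 * np.pi)
    step = speed_per_sample / fs
    dxy = np.column_stack([step * np.cos(heading), step * np.sin(heading)])
    start = rng.uniform(-WALL_MM / 2.0, WALL_MM / 2.0, size=2)
    path = start + np.cumsum(dxy, axis=0)
    return _fold(path, WALL_MM)


def _bilinear_weights(path: np.ndarray, geometry: PlateGeometry) -> np.ndarray:
    """Corner weights (n, 4) whose moments reproduce the path exactly.

    For a corner at (s_x L, s_y L): w = (1 + s_x x/L)(1 + s_y y/L)/4, the
    unique bilinear interpolant; weights are non-negative inside the plate
    and sum to one.
    """
    L = geometry.half_side_mm
    pos = geometry.positions_array() / L  # signs (+-1, +-1)
    x, y = path[:, 0] / L, path[:, 1] / L
    w = (1.0 + np.outer(x, pos[:, 0])) * (1.0 + np.outer(y, pos[:, 1])) / 4.0
    return w


def simulate_recording(
    config: PhenotypeConfig,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    calibration: Calibration | None = None,
    geometry: PlateGeometry | None = None,
    subject_id: str | None = None,
    age_days: float | None = 36.0,
    return_truth: bool = False,
):
    """Simulate one session as a calibrated, quantized Recording.

    With ``return_truth=True`` also returns a dict carrying the generator's
    ground truth (pre-quantization): ``weight_g``, ``cop_mm`` (n, 2),
    ``fz_gf`` (n,), ``tremor`` (fraction of body weight) and the
    noise-free per-channel forces ``channels_gf`` — the oracles for
    parameter-recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if calibration is None:
        calibration = Calibration()
    if geometry is None:
        geometry = PlateGeometry()
    n = int(round(duration_s * sample_rate))
    if n <= 0:
        raise ValueError("duration must cover at least one sample")

    weight = float(np.clip(rng.normal(config.weight_mean_g, config.weight_sd_g), 1.0, None))
    path = _cop_path(config.locomotion, n, sample_rate, rng)
    tremor = _tremor_signal(config.tremor, n, sample_rate, rng)
    fz = weight * (1.0 + tremor)

    w = _bilinear_weights(path, geometry)
    channels = w * fz[:, None]
    noisy = channels + rng.normal(0.0, config.sensor_noise_sd_gf, channels.shape)

    counts = calibration.force_to_counts(noisy)
    forces = calibration.counts_to_force(counts)

    meta = AnimalMeta(
        subject_id=subject_id or f"{config.group}-sim",
        group=config.group,
        body_weight_g=weight,
        age_days=age_days,
    )
    rec = Recording(
        forces=forces,
        sample_rate=sample_rate,
        meta=meta,
        geometry=geometry,
        calibration=calibration,
    )
    if not return_truth:
        return rec
    truth = {
        "weight_g": weight,
        "cop_mm": path,
        "fz_gf": fz,
        "tremor": tremor,
        "channels_gf": channels,
        "channels_noisy_gf": noisy,
    }
    return rec, truth


def simulate_cohort(
    configs: list[PhenotypeConfig] | dict[str, PhenotypeConfig],
    n_per_group: int,
    master_seed: int,
    **kwargs,
) -> list[Recording]:
    """Simulate ``n_per_group`` animals per config, reproducibly.

    Per-animal generators are spawned from a single ``SeedSequence`` so the
    cohort is bit-identical for a given master seed; subject ids are
    ``<group><index>``.  Extra keyword arguments pass through to
    :func:`simulate_recording`.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if isinstance(configs, dict):
        configs = list(configs.values())
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(configs) * n_per_group)
    recordings: list[Recording] = []
    k = 0
    for config in configs:
        for i in range(n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            recordings.append(
                simulate_recording(
                    config,
                    rng=rng,
                    subject_id=f"{config.group}{i + 1:02d}",
                    **kwargs,
                )
            )
    return recordings
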