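"""Recording I/O, instrument calibration and plate geometry.

A force-plate actometer supports a rigid load plate on four strain-gauge
load cells, one at each corner of the sensing square.  The acquisition
chain digitizes each cell to 12-bit integer counts; an affine per-channel
calibration (gain in gram-force per count, offset in counts) maps counts
back to force.  Recordings are stored as a versioned delimited-text format:
``#``-prefixed header lines carrying acquisition and animal metadata,
followed by one whitespace-separated row of four integer counts per sample.
The format is lossless for in-range integer counts and diff-able, so small
fixtures can live in version control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "ADC_MAX",
    "FormatError",
    "Calibration",
    "PlateGeometry",
    "AnimalMeta",
    "Recording",
    "read_recording",
    "write_recording",
    "write_metrics_table",
    "METRICS_COLUMNS",
]

#: Study-group labels: untreated wildtype and twitcher, their bone-marrow
#: transplanted counterparts, and each of the four with harmaline.
GROUPS = ("Wt", "Twi", "BmtWt", "BmtTwi", "WtH", "TwiH", "BmtWtH", "BmtTwiH")

#: Largest representable count of the 12-bit digitizer.
ADC_MAX = 4095

N_CHANNELS = 4

_FORMAT_MAGIC = "actometry-recording"
_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when a recording file violates the documented dialect."""


@dataclass(frozen=True)
class Calibration:
    """Affine count-to-force map for the four load-cell channels.

    ``force = gain * (count - offset)`` per channel.  The default gain of
    0.2 gram-force per count matches the instrument's stated force
    resolution; offsets default to zero (pre-balanced channels).
    """

    gains: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    force_resolution: float = 0.2  # gram-force per count

    def __post_init__(self) -> None:
        if len(self.gains) != N_CHANNELS or len(self.offsets) != N_CHANNELS:
            raise ValueError("calibration needs exactly 4 gains and 4 offsets")
        if any(g <= 0 for g in self.gains):
            raise ValueError("gains must be positive")
        if self.force_resolution <= 0:
            raise ValueError("force_resolution must be positive")

    def counts_to_force(self, counts: np.ndarray) -> np.ndarray:
        """Map integer counts (n, 4) to gram-force."""
        counts = np.asarray(counts, dtype=float)
        return (counts - np.asarray(self.offsets)) * np.asarray(self.gains)

    def force_to_counts(self, forces: np.ndarray) -> np.ndarray:
        """Quantize gram-force (n, 4) to the nearest integer count.

        Counts are clipped to the 12-bit range [0, 4095]; forces outside
        that range saturate exactly as the physical digitizer would.
        """
        forces = np.asarray(forces, dtype=float)
        counts = np.rint(forces / np.asarray(self.gains) + np.asarray(self.offsets))
        return np.clip(counts, 0, ADC_MAX).astype(np.int64)


@dataclass(frozen=True)
class PlateGeometry:
    """Sensing-square geometry with a transducer at each corner.

    Positions are (x, y) in mm with the origin at the plate center.  The
    default channel order is counter-clockwise from the lower-left corner:
    (-L, -L), (+L, -L), (+L, +L), (-L, +L) with L = side/2.
    """

    side_mm: float = 200.0
    transducer_positions: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("side_mm must be positive")
        if self.transducer_positions is None:
            L = self.side_mm / 2.0
            object.__setattr__(
                self,
                "transducer_positions",
                ((-L, -L), (L, -L), (L, L), (-L, L)),
            )
        if len(self.transducer_positions) != N_CHANNELS:
            raise ValueError("exactly four transducer positions required")

    @property
    def half_side_mm(self) -> float:
        return self.side_mm / 2.0

    def positions_array(self) -> np.ndarray:
        return np.asarray(self.transducer_positions, dtype=float)


@dataclass(frozen=True)
class AnimalMeta:
    """Per-animal metadata attached to a recording."""

    subject_id: str
    group: str
    body_weight_g: float
    age_days: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.body_weight_g > 0:
            raise ValueError("body_weight_g must be positive")


@dataclass(frozen=True)
class Recording:
    """A calibrated 4-channel force time series for one session.

    ``forces`` is an (n_samples, 4) array in gram-force, one column per
    load cell in the geometry's channel order.
    """

    forces: np.ndarray
    sample_rate: float
    meta: AnimalMeta
    geometry: PlateGeometry = PlateGeometry()
    calibration: Calibration = Calibration()

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        if forces.ndim != 2 or forces.shape[1] != N_CHANNELS:
            raise ValueError("forces must be an (n_samples, 4) array")
        if forces.shape[0] == 0:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(forces)):
            raise ValueError("forces must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "forces", forces)

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def with_meta(self, meta: AnimalMeta) -> "Recording":
        return replace(self, meta=meta)


def _format_floats(values: Iterable[float]) -> str:
    return ",".join(repr(float(v)) for v in values)


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording in the versioned text dialect.

    Forces are converted back to integer counts through the recording's
    calibration; the file is lossless iff the forces lie on the
    calibration's quantization grid (as they do for anything produced by
    :func:`read_recording` or the simulator).
    """
    path = Path(path)
    counts = recording.calibration.force_to_counts(recording.forces)
    meta = recording.meta
    header = [
        f"# {_FORMAT_MAGIC} {_FORMAT_VERSION}",
        f"# sample_rate_hz={recording.sample_rate!r}",
        f"# n_channels={N_CHANNELS}",
        f"# gains={_format_floats(recording.calibration.gains)}",
        f"# offsets={_format_floats(recording.calibration.offsets)}",
        f"# force_resolution={recording.calibration.force_resolution!r}",
        f"# side_mm={recording.geometry.side_mm!r}",
        f"# subject_id={meta.subject_id}",
        f"# group={meta.group}",
        f"# body_weight_g={meta.body_weight_g!r}",
    ]
    if meta.age_days is not None:
        header.append(f"# age_days={meta.age_days!r}")
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, counts, fmt="%d", delimiter="\t")
    return path


def _parse_header(lines: list[str]) -> dict[str, str]:
    if not lines or not lines[0].startswith(f"# {_FORMAT_MAGIC}"):
        raise FormatError("missing recording format magic line")
    version = lines[0].split()[-1]
    if version != str(_FORMAT_VERSION):
        raise FormatError(f"unsupported format version {version}")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        body = line[1:].strip()
        if "=" in body:
            key, _, value = body.partition("=")
            fields[key.strip()] = value.strip()
    return fields


def read_recording(
    path: str | Path,
    calibration: Calibration | None = None,
    meta: AnimalMeta | None = None,
) -> Recording:
    """Read a recording file, mapping counts to gram-force.

    Header metadata is used unless overridden by the ``calibration`` /
    ``meta`` arguments.  Counts must be integers in [0, 4095] with exactly
    four columns per row.
    """
    path = Path(path)
    header_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line.rstrip("\n"))
            else:
                break
    fields = _parse_header(header_lines)

    if int(fields.get("n_channels", N_CHANNELS)) != N_CHANNELS:
        raise FormatError("recording must have exactly 4 channels")

    try:
        counts = np.loadtxt(path, comments="#", dtype=np.int64, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"malformed count data: {exc}") from exc
    if counts.size == 0:
        raise FormatError("recording contains no samples")
    if counts.shape[1] != N_CHANNELS:
        raise FormatError(
            f"expected {N_CHANNELS} count columns, found {counts.shape[1]}"
        )
    if counts.min() < 0 or counts.max() > ADC_MAX:
        raise FormatError("counts outside the 12-bit range [0, 4095]")

    if calibration is None:
        try:
            gains = tuple(float(x) for x in fields["gains"].split(","))
            offsets = tuple(float(x) for x in fields["offsets"].split(","))
            calibration = Calibration(
                gains=gains,  # type: ignore[arg-type]
                offsets=offsets,  # type: ignore[arg-type]
                force_resolution=float(fields.get("force_resolution", 0.2)),
            )
        except KeyError:
            calibration = Calibration()
    if meta is None:
        try:
            meta = AnimalMeta(
                subject_id=fields["subject_id"],
                group=fields["group"],
                body_weight_g=float(fields["body_weight_g"]),
                age_days=float(fields["age_days"]) if "age_days" in fields else None,
            )
        except KeyError as exc:
            raise FormatError(f"missing metadata field {exc} and no meta given") from exc

    geometry = PlateGeometry(side_mm=float(fields.get("side_mm", 200.0)))
    sample_rate = float(fields.get("sample_rate_hz", 100.0))
    forces = calibration.counts_to_force(counts)
    return Recording(
        forces=forces,
        sample_rate=sample_rate,
        meta=meta,
        geometry=geometry,
        calibration=calibration,
    )


#: Stable column order of the per-animal metrics table.
METRICS_COLUMNS = (
    "subject_id",
    "group",
    "body_weight_g",
    "peak_power",
    "freq_at_peak_hz",
    "center_frequency_hz",
    "bandwidth_hz",
    "band_power_13_20",
    "distance_mm",
    "low_mobility_bouts",
    "session_duration_s",
)


def write_metrics_table(
    records: Sequence[Mapping[str, object]] | pd.DataFrame, path: str | Path
) -> Path:
    """Write one TSV row per animal with a stable, documented column order.

    Missing columns are emitted as empty fields; duplicate subject ids are
    rejected (each animal contributes exactly one session row).
    """
    path = Path(path)
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        df = pd.DataFrame(columns=list(METRICS_COLUMNS))
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    for col in METRICS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(METRICS_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)
    return path
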