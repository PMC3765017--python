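"""Averaged power spectra and tremor metrics from net vertical force.

The tremor-carrying signal is Fz, the net vertical force: the sum of the
four load-cell channels at each 0.01-s instant.  Fz is expressed as a
percent of the animal's body weight so spectra are comparable across
groups with very different weights, cut into consecutive non-overlapping
5.00-s segments (500 samples at 100 samples/s), each segment mean-removed,
Hanning-windowed and Fourier transformed, and the per-segment power
spectra averaged (a Welch-style estimate on a 0.2 Hz bin grid).  The
averaged spectrum is restricted to 2.5-30.0 Hz, the band where rodent
tremor and movement-related force oscillation live, and summarized by
five scalars:

* peak power and the frequency at peak power;
* the half-power bandwidth (distance between the outermost frequencies
  where power falls to half its maximum, with linear interpolation
  between bins);
* the center frequency (midpoint of the two half-power crossings);
* the integrated power between 13 and 20 Hz (trapezoid rule), the
  summary band for broadband high-frequency tremor.

Spectrum scaling: one-sided squared magnitude compensated for the window
power loss, i.e. ``P[k] = c_k |FFT(w x)[k]|^2 / (N * sum(w^2))`` with
``c_k = 2`` except at DC and Nyquist.  With this scaling the total
one-sided power of a mean-removed segment estimates the signal variance
(Parseval consistency), and power carries units of %-body-weight² per
0.2-Hz bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import windows

from .io import AnimalMeta, Recording

__all__ = [
    "RESTRICTED_BAND",
    "TREMOR_BAND",
    "DegenerateSpectrumError",
    "FzSeries",
    "PowerSpectrum",
    "SpectralMetrics",
    "net_force",
    "normalize_to_body_weight",
    "segment_series",
    "segment_spectrum",
    "average_spectra",
    "spectral_metrics",
    "analyze_recording",
    "write_spectrum",
]

#: Frequency band (Hz) retained in the averaged spectrum.
RESTRICTED_BAND = (2.5, 30.0)
#: Integration band (Hz) summarizing broadband high-frequency tremor.
TREMOR_BAND = (13.0, 20.0)

SEGMENT_SECONDS = 5.0
ANALYZED_SECONDS = 60.0


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum carries no power and metrics are undefined."""


@dataclass(frozen=True)
class FzSeries:
    """Net vertical force normalized to percent of body weight."""

    values: np.ndarray
    sample_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("Fz values must be finite")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PowerSpectrum:
    """Power versus frequency on a uniform bin grid.

    ``power`` has units of the squared signal per bin; ``band`` records
    the closed frequency interval the grid was restricted to.
    """

    frequencies: np.ndarray
    power: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be 1-D and aligned")
        if f.size >= 2 and not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class SpectralMetrics:
    """The five scalar tremor descriptors of an averaged spectrum."""

    peak_power: float
    freq_at_peak_hz: float
    center_frequency_hz: float
    bandwidth_hz: float
    band_power_13_20: float


def net_force(recording: Recording) -> np.ndarray:
    """Net vertical force Fz (gram-force): the sum of the four channels."""
    return recording.forces.sum(axis=1)


def normalize_to_body_weight(fz: np.ndarray, meta: AnimalMeta) -> FzSeries:
    """Express Fz as a percent of body weight (a motionless animal = 100%)."""
    if not meta.body_weight_g > 0:
        raise ValueError("body weight must be positive to normalize")
    values = 100.0 * np.asarray(fz, dtype=float) / meta.body_weight_g
    return FzSeries(values=values, sample_rate=100.0, subject_id=meta.subject_id)


def segment_series(
    fz: FzSeries,
    segment_seconds: float = SEGMENT_SECONDS,
    analyzed_seconds: float = ANALYZED_SECONDS,
) -> np.ndarray:
    """Cut the first ``analyzed_seconds`` into consecutive segments.

    Returns an (n_segments, segment_samples) array; trailing samples that
    do not fill a whole segment are discarded.  The defaults give the
    canonical 12 segments of 500 samples from the first minute.
    """
    seg_len = int(round(segment_seconds * fz.sample_rate))
    if seg_len < 2:
        raise ValueError("segment too short")
    n_available = fz.values.size
    n_analyzed = min(n_available, int(round(analyzed_seconds * fz.sample_rate)))
    n_segments = n_analyzed // seg_len
    if n_segments == 0:
        raise ValueError(
            f"series of {n_available} samples is shorter than one "
            f"{seg_len}-sample segment"
        )
    used = fz.values[: n_segments * seg_len]
    return used.reshape(n_segments, seg_len)


def _hann(n: int) -> np.ndarray:
    # Periodic window: the appropriate choice for spectral estimation.
    return windows.hann(n, sym=False)


def segment_spectrum(segment: np.ndarray, sample_rate: float = 100.0) -> PowerSpectrum:
    """One-sided power spectrum of a single mean-removed, windowed segment.

    Scaling follows the module docstring: total one-sided power estimates
    the segment variance.  The full band up to Nyquist is returned; band
    restriction happens in :func:`average_spectra`.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("segment must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    n = x.size
    x = x - x.mean()
    w = _hann(n)
    spec = rfft(w * x)
    power = np.abs(spec) ** 2 / (n * np.sum(w**2))
    # One-sided doubling; DC always single, Nyquist single when n is even.
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale
    freqs = rfftfreq(n, d=1.0 / sample_rate)
    return PowerSpectrum(frequencies=freqs, power=power, band=(0.0, sample_rate / 2.0))


def average_spectra(
    spectra: list[PowerSpectrum] | tuple[PowerSpectrum, ...],
    band: tuple[float, float] = RESTRICTED_BAND,
) -> PowerSpectrum:
    """Bin-wise mean of per-segment spectra, restricted to ``band`` (closed)."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum to average")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0):
            raise ValueError("spectra are on mismatched frequency grids")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    lo, hi = band
    keep = (f0 >= lo - 1e-9) & (f0 <= hi + 1e-9)
    return PowerSpectrum(frequencies=f0[keep], power=mean_power[keep], band=band)


def _half_power_crossings(freqs: np.ndarray, power: np.ndarray) -> tuple[float, float]:
    """Outermost frequencies where power crosses half the maximum.

    Crossings are located by linear interpolation between adjacent bins;
    when the spectrum is still above half power at a band edge, the edge
    itself is the crossing.
    """
    half = power.max() / 2.0
    above = np.flatnonzero(power >= half)
    i_lo, i_hi = above[0], above[-1]
    if i_lo == 0:
        lower = float(freqs[0])
    else:
        p0, p1 = power[i_lo - 1], power[i_lo]
        lower = float(freqs[i_lo - 1] + (half - p0) / (p1 - p0) * (freqs[i_lo] - freqs[i_lo - 1]))
    if i_hi == power.size - 1:
        upper = float(freqs[-1])
    else:
        p0, p1 = power[i_hi], power[i_hi + 1]
        upper = float(freqs[i_hi] + (p0 - half) / (p0 - p1) * (freqs[i_hi + 1] - freqs[i_hi]))
    return lower, upper


def _band_integral(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> float:
    """Trapezoidal area under the spectrum over a closed band.

    Band endpoints that fall between bins are filled in by linear
    interpolation so the integral covers exactly [lo, hi].
    """
    lo, hi = band
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inside = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inside, [hi]))
    vals = np.interp(grid, freqs, power)
    return float(np.trapezoid(vals, grid))


#: Power below this is indistinguishable from double-precision rounding of
#: a constant ~100 %-body-weight signal and treated as "no oscillation".
POWER_FLOOR = 1e-24


def spectral_metrics(
    spectrum: PowerSpectrum, tremor_band: tuple[float, float] = TREMOR_BAND
) -> SpectralMetrics:
    """Compute the five tremor descriptors of an averaged restricted spectrum.

    Peak ties are broken toward the lowest frequency (argmax convention);
    a spectrum with no power above the floating-point floor has no
    half-power geometry and raises :class:`DegenerateSpectrumError`.
    """
    f, p = spectrum.frequencies, spectrum.power
    if f.size == 0:
        raise DegenerateSpectrumError("empty spectrum")
    if not p.max() > POWER_FLOOR:
        raise DegenerateSpectrumError("spectrum carries no power; metrics undefined")
    i_peak = int(np.argmax(p))
    lower, upper = _half_power_crossings(f, p)
    return SpectralMetrics(
        peak_power=float(p[i_peak]),
        freq_at_peak_hz=float(f[i_peak]),
        center_frequency_hz=(lower + upper) / 2.0,
        bandwidth_hz=upper - lower,
        band_power_13_20=_band_integral(f, p, tremor_band),
    )


def analyze_recording(
    recording: Recording,
    analyzed_seconds: float = ANALYZED_SECONDS,
    segment_seconds: float = SEGMENT_SECONDS,
    band: tuple[float, float] = RESTRICTED_BAND,
    tremor_band: tuple[float, float] = TREMOR_BAND,
) -> tuple[PowerSpectrum, SpectralMetrics]:
    """Full spectral pipeline for one animal.

    Composes net force -> body-weight normalization -> segmentation of the
    first ``analyzed_seconds`` (movement is maximal early in a session) ->
    per-segment spectra -> averaging with band restriction -> metrics.
    """
    fz = normalize_to_body_weight(net_force(recording), recording.meta)
    fz = FzSeries(fz.values, recording.sample_rate, recording.meta.subject_id)
    segments = segment_series(fz, segment_seconds, analyzed_seconds)
    spectra = [segment_spectrum(seg, recording.sample_rate) for seg in segments]
    avg = average_spectra(spectra, band)
    return avg, spectral_metrics(avg, tremor_band)


def write_spectrum(spectrum: PowerSpectrum, path) -> None:
    """Write a two-column (Hz, power) delimited-text spectrum."""
    data = np.column_stack([spectrum.frequencies, spectrum.power])
    header = (
        "frequency_hz\tpower\n"
        f"band: [{spectrum.band[0]}, {spectrum.band[1]}] Hz; "
        "power units: (%body weight)^2 per bin"
    )
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header)
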