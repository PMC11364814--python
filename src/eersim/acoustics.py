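"""Time- and frequency-domain characterization of the detector output.

Covers the desk-side of the bandwidth characterization experiment: the
optoacoustic point-source N-wave emitted by an impulsively heated absorber,
zero-phase band-pass filtering of recorded traces, one-sided power spectra,
threshold-crossing detection bandwidth, and the bandwidth/aperture-limited
resolution estimates.

Units: time in ns, frequency in MHz, distance in mm, speed of sound in
mm/us (default 1.5, water / soft tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "PressureTrace",
    "PowerSpectrum",
    "SourceModel",
    "oa_point_trace",
    "bandpass",
    "power_spectrum",
    "bandwidth_at_fraction",
    "resolution_estimates",
    "FWHM_SIGMA",
]

FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma of a Gaussian


@dataclass(frozen=True)
class PressureTrace:
    """Uniformly sampled detector output."""

    t0: float  # start time, ns
    dt: float  # sample interval, ns
    samples: np.ndarray
    unit: str = "Pa"

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if s.ndim != 1 or s.size < 16:
            raise ValueError("need a 1-D trace of at least 16 samples")
        object.__setattr__(self, "samples", s)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def sample_rate_mhz(self) -> float:
        return 1e3 / self.dt


@dataclass(frozen=True)
class PowerSpectrum:
    frequencies: np.ndarray  # MHz, ascending, >= 0
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be matching 1-D arrays")
        if f[0] < 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be ascending and start >= 0")
        if np.any(p < 0):
            raise ValueError("power must be >= 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class SourceModel:
    """Optoacoustic source: excitation pulse FWHM (ns), speed of sound (mm/us)."""

    kind: str = "point"
    pulse_width: float = 1.2
    speed_of_sound: float = 1.5
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "cylinder"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.pulse_width <= 0 or self.speed_of_sound <= 0:
            raise ValueError("pulse_width and speed_of_sound must be > 0")


def gaussian_derivative(t: np.ndarray, t_center: float, sigma: float, peak: float) -> np.ndarray:
    """Bipolar N-shaped pulse: derivative of a Gaussian, |extremum| = peak."""
    x = (t - t_center) / sigma
    return peak * math.sqrt(math.e) * (-x) * np.exp(-0.5 * x * x)


def oa_point_trace(
    source: SourceModel, distance: float, dt: float, n: int, t0: float = 0.0
) -> PressureTrace:
    """Far-field N-wave of a point absorber at `distance` mm.

    Temporal derivative of a Gaussian with the source's excitation FWHM,
    centered at the acoustic arrival time distance/c, peak amplitude
    proportional to 1/distance (spherical spreading).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    t_center = distance / source.speed_of_sound * 1e3  # us -> ns
    margin = 5.0 * source.pulse_width
    if t_center - margin < t0 or t_center + margin > t0 + n * dt:
        raise ValueError(
            f"trace window [{t0}, {t0 + n * dt}] ns does not contain the pulse at "
            f"{t_center:.1f} +/- {margin:.1f} ns; increase n"
        )
    t = t0 + dt * np.arange(n)
    sigma = source.pulse_width / FWHM_SIGMA
    samples = gaussian_derivative(t, t_center, sigma, source.amplitude / distance)
    return PressureTrace(t0=t0, dt=dt, samples=samples, unit="Pa")


def bandpass(trace: PressureTrace, f_lo: float, f_hi: float, order: int = 4) -> PressureTrace:
    """Zero-phase Butterworth band-pass (forward-backward), DC removed."""
    nyquist = trace.sample_rate_mhz / 2.0
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi >= nyquist:
        raise ValueError(f"f_hi = {f_hi} MHz must be below the Nyquist frequency {nyquist} MHz")
    x = trace.samples - np.mean(trace.samples)
    if f_lo > 0:
        sos = butter(order, [f_lo / nyquist, f_hi / nyquist], btype="bandpass", output="sos")
    else:
        sos = butter(order, f_hi / nyquist, btype="lowpass", output="sos")
    y = sosfiltfilt(sos, x)
    return replace(trace, samples=y)


def power_spectrum(
    trace: PressureTrace, zero_pad_to: Optional[int] = None, normalize: bool = True
) -> PowerSpectrum:
    """One-sided magnitude-squared spectrum, optionally peak-normalized."""
    n = trace.samples.size
    n_fft = n if zero_pad_to is None else int(zero_pad_to)
    if n_fft < n:
        raise ValueError("zero_pad_to must be >= trace length")
    if not np.any(trace.samples):
        raise ValueError("empty signal: all samples are zero")
    spec = np.abs(np.fft.rfft(trace.samples, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, trace.dt * 1e-3)  # dt ns -> us gives MHz
    if normalize:
        spec = spec / np.max(spec)
    return PowerSpectrum(frequencies=freqs, power=spec)


def bandwidth_at_fraction(ps: PowerSpectrum, fraction: float) -> float:
    """Detection bandwidth: highest frequency where power crosses fraction*max.

    The search runs downward from the top of the grid and the crossing is
    linearly interpolated, following the convention of quoting the upper
    threshold crossing of the power spectrum as the single bandwidth
    number (the lower edge is fixed by the acquisition high-pass).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    p = ps.power / np.max(ps.power)
    f = ps.frequencies
    above = np.nonzero(p >= fraction)[0]
    if above.size == 0:
        raise ValueError("power never reaches the requested fraction")
    i = above[-1]
    if i == p.size - 1:
        return float(f[-1])
    # interpolate between the last above-threshold sample and the next one
    return float(f[i] + (p[i] - fraction) / (p[i] - p[i + 1]) * (f[i + 1] - f[i]))


def resolution_estimates(
    bandwidth: float,
    aperture: float,
    c: float = 1.5,
    k_ax: float = 0.88,
    k_lat: float = 1.25,
) -> dict:
    """Bandwidth-limited axial and aperture-limited lateral resolution (um).

    axial = k_ax * c / bandwidth, lateral = k_lat * aperture. The
    proportionality constants are conventions, not physics, and are
    returned with the estimates.
    """
    if bandwidth <= 0 or aperture <= 0 or c <= 0:
        raise ValueError("bandwidth, aperture and c must be > 0")
    axial_um = k_ax * c / bandwidth * 1e3  # mm -> um
    lateral_um = k_lat * aperture
    return {"axial_um": axial_um, "lateral_um": lateral_um, "k_ax": k_ax, "k_lat": k_lat}
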