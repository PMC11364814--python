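"""Coupled-mode transfer-matrix optics for fiber Bragg grating etalons.

The embedded etalon resonator (EER) is a stack of photonic elements written
into the core of a single-mode fiber: a long Bragg-grating mirror on the
interrogation side, a discrete pi phase shift, a short residual grating
("spacer") and, after coating, a metallic terminator at the polished facet.
This module simulates the complex amplitude reflectance of such stacks with
the standard 2x2 transfer-matrix method of coupled-mode theory and extracts
resonance and stop-band metrics from the resulting spectra.

Conventions
-----------
* Wavelengths in nm, physical lengths in mm, coupling coefficients in mm^-1.
* Fields are ordered (forward, backward); each element matrix maps the
  fields on its tip side to the fields on its input (interrogation) side,
  so a stack matrix is the ordered product of element matrices from the
  input toward the tip.
* Detuning delta = 2*pi*n_eff*(1/lambda - 1/lambda_B); the slowly varying
  envelope representation absorbs the common carrier phase, which is valid
  because all grating sections of one device share a single inscription
  period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GratingSection",
    "PhaseShiftElement",
    "BareSection",
    "MirrorTerminator",
    "EtalonStack",
    "ReflectionSpectrum",
    "ResonanceFeature",
    "section_transfer_matrix",
    "element_transfer_matrix",
    "stack_matrix",
    "stack_reflectance",
    "find_resonance",
    "stopband_width",
    "default_wavelength_grid",
    "NM_PER_MM",
]

NM_PER_MM = 1.0e6  # nm per mm


# ---------------------------------------------------------------------------
# element types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingSection:
    """Uniform Bragg grating section.

    Parameters
    ----------
    length : float
        Physical length in mm (> 0).
    kappa : float
        Coupling coefficient between forward and backward modes, mm^-1.
    bragg_wavelength : float
        Bragg wavelength lambda_B = 2 * n_eff * period, in nm.
    n_eff : float
        Effective refractive index of the guided mode.
    loss : float
        Optional field amplitude loss rate in mm^-1 (default 0).
    """

    length: float
    kappa: float = 1.4
    bragg_wavelength: float = 1549.0
    n_eff: float = 1.447
    loss: float = 0.0

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"grating length must be > 0, got {self.length}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 1000.0 < self.bragg_wavelength < 2000.0:
            raise ValueError(
                f"bragg_wavelength {self.bragg_wavelength} nm outside (1000, 2000)"
            )
        if not 1.0 < self.n_eff < 2.0:
            raise ValueError(f"n_eff {self.n_eff} outside (1, 2)")
        if self.loss < 0:
            raise ValueError("loss must be >= 0")


@dataclass(frozen=True)
class PhaseShiftElement:
    """Discrete phase discontinuity in the grating (phase in radians, [0, 2*pi))."""

    phase: float = math.pi

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase < 2.0 * math.pi:
            raise ValueError(f"phase {self.phase} outside [0, 2*pi)")


@dataclass(frozen=True)
class BareSection:
    """Unpatterned fiber section (pure propagation)."""

    length: float
    n_eff: float = 1.447

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("bare section length must be >= 0")


@dataclass(frozen=True)
class MirrorTerminator:
    """Complex-amplitude reflector at the fiber tip (silver coating or bare facet)."""

    amplitude_reflectance: float = 0.98
    phase: float = math.pi

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_reflectance <= 1.0:
            raise ValueError("amplitude_reflectance must be in [0, 1]")

    @property
    def rho(self) -> complex:
        return self.amplitude_reflectance * np.exp(1j * self.phase)


Element = Union[GratingSection, PhaseShiftElement, BareSection]


@dataclass(frozen=True)
class EtalonStack:
    """Ordered photonic elements from the interrogation side toward the tip."""

    elements: tuple
    terminator: Optional[MirrorTerminator] = None

    def __init__(self, elements: Sequence[Element], terminator: Optional[MirrorTerminator] = None):
        if len(elements) == 0:
            raise ValueError("stack needs at least one element")
        object.__setattr__(self, "elements", tuple(elements))
        object.__setattr__(self, "terminator", terminator)

    @property
    def reference_bragg(self) -> float:
        """Reference Bragg wavelength (nm) for the envelope representation."""
        for el in self.elements:
            if isinstance(el, GratingSection):
                return el.bragg_wavelength
        return 1549.0

    @property
    def total_length(self) -> float:
        return sum(getattr(el, "length", 0.0) for el in self.elements)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReflectionSpectrum:
    """Wavelength grid (nm) with complex amplitude reflectance."""

    wavelengths: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        amp = np.asarray(self.amplitude)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelengths must be a 1-D array")
        if amp.shape != wl.shape:
            raise ValueError("amplitude and wavelengths must have the same length")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "amplitude", np.asarray(amp, dtype=complex))

    @property
    def reflectivity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    @classmethod
    def from_reflectivity(
        cls, wavelengths: np.ndarray, reflectivity: np.ndarray, phase: Optional[np.ndarray] = None
    ) -> "ReflectionSpectrum":
        """Build a spectrum from measured |r|^2 (phase optional, default 0)."""
        reflectivity = np.asarray(reflectivity, dtype=float)
        if np.any(reflectivity < 0):
            raise ValueError("reflectivity must be >= 0")
        amp = np.sqrt(reflectivity).astype(complex)
        if phase is not None:
            amp = amp * np.exp(1j * np.asarray(phase, dtype=float))
        return cls(np.asarray(wavelengths, dtype=float), amp)


@dataclass(frozen=True)
class ResonanceFeature:
    """Resonant dip parameters: center/fwhm in nm, dimensionless depth and Q."""

    center: float
    fwhm: float
    depth: float
    q_factor: float

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if abs(self.q_factor - self.center / self.fwhm) > 1e-12 * self.q_factor:
            raise ValueError("q_factor must equal center / fwhm")


def default_wavelength_grid(
    center: float = 1549.0, half_span: float = 1.5, points: int = 4096
) -> np.ndarray:
    """Default simulation grid: center +/- half_span nm, `points` samples."""
    return np.linspace(center - half_span, center + half_span, points)


# ---------------------------------------------------------------------------
# transfer matrices
# ---------------------------------------------------------------------------


def _sinhc(x: np.ndarray) -> np.ndarray:
    """sinh(x)/x, continuous through x = 0 (6th-order series near the origin)."""
    x = np.asarray(x, dtype=complex)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 0.0, x)
    out = np.empty_like(x)
    with np.errstate(over="raise"):
        out[~small] = np.sinh(xs[~small]) / xs[~small]
    x2 = x[small] ** 2
    out[small] = 1.0 + x2 / 6.0 + x2**2 / 120.0 + x2**3 / 5040.0
    return out


def section_transfer_matrix(section: GratingSection, wavelength) -> np.ndarray:
    """Transfer matrix of a uniform grating section.

    With detuning delta = 2*pi*n_eff*(1/lambda - 1/lambda_B) and
    gamma = sqrt(kappa^2 - delta^2) the matrix is::

        F11 = cosh(gL) - i (d/g) sinh(gL)      F12 = -i (k/g) sinh(gL)
        F21 = +i (k/g) sinh(gL)                F22 = cosh(gL) + i (d/g) sinh(gL)

    which is unimodular (det F = 1) for loss-free sections. gamma -> 0 is
    evaluated by a series limit, and the branch of the square root is
    irrelevant because cosh and sinh(x)/x are even.

    `wavelength` (nm) may be a scalar or an array; the result has shape
    (..., 2, 2).
    """
    wl = np.asarray(wavelength, dtype=float)
    if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
        raise ValueError("wavelength must be finite and > 0")
    wl_mm = wl * 1e-6
    lb_mm = section.bragg_wavelength * 1e-6
    delta = 2.0 * np.pi * section.n_eff * (1.0 / wl_mm - 1.0 / lb_mm)
    dhat = delta - 1j * section.loss  # complex detuning carries the loss
    gamma = np.sqrt(section.kappa**2 - dhat.astype(complex) ** 2)
    gl = gamma * section.length
    c = np.cosh(gl)
    s_over_g = _sinhc(gl) * section.length  # sinh(gL)/gamma
    f11 = c - 1j * dhat * s_over_g
    f12 = -1j * section.kappa * s_over_g
    f21 = 1j * section.kappa * s_over_g
    f22 = c + 1j * dhat * s_over_g
    out = np.empty(wl.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = f11
    out[..., 0, 1] = f12
    out[..., 1, 0] = f21
    out[..., 1, 1] = f22
    return out


def _phase_matrix(phase: float, shape) -> np.ndarray:
    out = np.zeros(shape + (2, 2), dtype=complex)
    out[..., 0, 0] = np.exp(-1j * phase / 2.0)
    out[..., 1, 1] = np.exp(+1j * phase / 2.0)
    return out


def _bare_matrix(section: BareSection, wavelength, reference_bragg: float) -> np.ndarray:
    wl = np.asarray(wavelength, dtype=float)
    delta = 2.0 * np.pi * section.n_eff * (1.0 / (wl * 1e-6) - 1.0 / (reference_bragg * 1e-6))
    out = np.zeros(wl.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = np.exp(-1j * delta * section.length)
    out[..., 1, 1] = np.exp(+1j * delta * section.length)
    return out


def element_transfer_matrix(element: Element, wavelength, reference_bragg: float = 1549.0) -> np.ndarray:
    """Transfer matrix of any stack element at the given wavelength(s)."""
    wl = np.asarray(wavelength, dtype=float)
    if isinstance(element, GratingSection):
        return section_transfer_matrix(element, wl)
    if isinstance(element, PhaseShiftElement):
        return _phase_matrix(element.phase, wl.shape)
    if isinstance(element, BareSection):
        return _bare_matrix(element, wl, reference_bragg)
    raise TypeError(f"unknown element type: {type(element).__name__}")


def stack_matrix(stack: EtalonStack, wavelengths) -> np.ndarray:
    """Ordered product of element matrices from input to tip, shape (..., 2, 2)."""
    wl = np.asarray(wavelengths, dtype=float)
    ref = stack.reference_bragg
    m = element_transfer_matrix(stack.elements[0], wl, ref)
    for el in stack.elements[1:]:
        m = m @ element_transfer_matrix(el, wl, ref)
    return m


def stack_reflectance(stack: EtalonStack, wavelengths) -> ReflectionSpectrum:
    """Complex amplitude reflectance of a stack over a wavelength grid.

    With terminator amplitude rho at the tip, the boundary condition
    b_tip = rho * a_tip gives r = (M21 + M22*rho) / (M11 + M12*rho);
    an uncoated stack uses rho = 0.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid needs >= 2 points")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly ascending")
    m = stack_matrix(stack, wl)
    rho = stack.terminator.rho if stack.terminator is not None else 0.0
    denom = m[..., 0, 0] + m[..., 0, 1] * rho
    bad = np.abs(denom) < 1e-300
    if np.any(bad):
        raise FloatingPointError(
            f"degenerate transfer matrix at wavelength {wl[np.argmax(bad)]:.6f} nm"
        )
    r = (m[..., 1, 0] + m[..., 1, 1] * rho) / denom
    return ReflectionSpectrum(wl, r)


# ---------------------------------------------------------------------------
# spectrum metrics
# ---------------------------------------------------------------------------


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three points."""
    d1 = (y[1] - y[0]) / (x[1] - x[0])
    d2 = (y[2] - y[1]) / (x[2] - x[1])
    curv = (d2 - d1) / (x[2] - x[0]) * 2.0
    if curv == 0:
        return float(x[1])
    slope_mid = (y[2] - y[0]) / (x[2] - x[0])
    return float(x[1] - slope_mid / curv)


def _cross(x0, x1, y0, y1, level) -> float:
    """Linear interpolation of the x where y crosses `level` between two samples."""
    if y1 == y0:
        return float(x0)
    return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def find_resonance(spectrum: ReflectionSpectrum, window: tuple) -> ResonanceFeature:
    """Locate the resonant dip inside `window` = (lambda_lo, lambda_hi) nm.

    The center is the reflectivity minimum with parabolic sub-grid
    refinement; the width is measured at half depth between the local
    baseline (the lower of the two flanking maxima) and the minimum, with
    linear interpolation at the crossings.
    """
    lo, hi = window
    wl = spectrum.wavelengths
    if lo < wl[0] or hi > wl[-1] or lo >= hi:
        raise ValueError("window must lie within the wavelength grid")
    mask = (wl >= lo) & (wl <= hi)
    w = wl[mask]
    r = spectrum.reflectivity[mask]
    if w.size < 3:
        raise ValueError("window contains too few grid points")
    imin = int(np.argmin(r))
    if imin == 0 or imin == r.size - 1:
        raise ValueError("no resonance in window: minimum lies on the window edge")
    center = _parabolic_vertex(w[imin - 1 : imin + 2], r[imin - 1 : imin + 2])
    center = float(np.clip(center, w[imin - 1], w[imin + 1]))
    rmin = float(r[imin])
    left_base = float(np.max(r[: imin + 1]))
    right_base = float(np.max(r[imin:]))
    baseline = min(left_base, right_base)
    if baseline <= rmin:
        raise ValueError("no resonance in window: dip has no depth")
    half = 0.5 * (baseline + rmin)
    i = imin
    while i > 0 and r[i] < half:
        i -= 1
    if r[i] < half:
        raise ValueError("no resonance in window: left flank does not reach half depth")
    lam_lo = _cross(w[i], w[i + 1], r[i], r[i + 1], half)
    j = imin
    while j < r.size - 1 and r[j] < half:
        j += 1
    if r[j] < half:
        raise ValueError("no resonance in window: right flank does not reach half depth")
    lam_hi = _cross(w[j - 1], w[j], r[j - 1], r[j], half)
    fwhm = lam_hi - lam_lo
    depth = 1.0 - rmin / baseline
    return ResonanceFeature(center=center, fwhm=fwhm, depth=depth, q_factor=center / fwhm)


def stopband_width(spectrum: ReflectionSpectrum) -> float:
    """Full width (nm) of the main reflection band at half of peak reflectivity.

    The band is the contiguous above-half region containing the peak; the
    central pi-shift dip splits that region into two lobes of comparable
    height, which are bridged (merged) before taking the outer half-maximum
    crossings. Side lobes, which stay well below the band plateau, are not
    part of the band. The grid must contain the whole band (reflectivity
    below half maximum at both ends).
    """
    wl = spectrum.wavelengths
    r = spectrum.reflectivity
    rmax = float(np.max(r))
    half = 0.5 * rmax
    if r[0] >= half or r[-1] >= half:
        raise ValueError("reflection band not fully contained in the wavelength grid")
    # contiguous runs of samples at or above half maximum
    above = r >= half
    runs = []
    i = 0
    n = r.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    ipk = int(np.argmax(r))
    k = next(idx for idx, (a, b) in enumerate(runs) if a <= ipk <= b)
    lo_run, hi_run = runs[k]
    # bridge the central resonance dip: merge adjacent runs whose own peak
    # reaches the band plateau (side lobes do not)
    plateau = 0.8 * rmax
    kk = k
    while kk + 1 < len(runs) and np.max(r[runs[kk + 1][0] : runs[kk + 1][1] + 1]) >= plateau:
        hi_run = runs[kk + 1][1]
        kk += 1
    kk = k
    while kk - 1 >= 0 and np.max(r[runs[kk - 1][0] : runs[kk - 1][1] + 1]) >= plateau:
        lo_run = runs[kk - 1][0]
        kk -= 1
    left = _cross(wl[lo_run - 1], wl[lo_run], r[lo_run - 1], r[lo_run], half)
    right = _cross(wl[hi_run], wl[hi_run + 1], r[hi_run], r[hi_run + 1], half)
    return right - left


def canonical_eer(
    spacer_length: float,
    mirror_length: float = 2.0,
    kappa: float = 1.4,
    bragg: float = 1549.0,
    n_eff: float = 1.447,
    terminator: Optional[MirrorTerminator] = MirrorTerminator(),
) -> EtalonStack:
    """Canonical EER: 2 mm mirror grating, pi shift, spacer grating, terminator.

    A zero spacer length degenerates to mirror + pi shift + terminator.
    """
    if spacer_length < 0:
        raise ValueError("spacer length must be >= 0")
    elements: List[Element] = [
        GratingSection(mirror_length, kappa, bragg, n_eff),
        PhaseShiftElement(math.pi),
    ]
    if spacer_length > 0:
        elements.append(GratingSection(spacer_length, kappa, bragg, n_eff))
    return EtalonStack(elements, terminator)
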