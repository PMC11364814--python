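"""Ultrasound-to-voltage transduction model and NEP arithmetic.

An incoming pressure wave at the coated facet perturbs the refractive index
of the tip-side of the cavity, shifting the optical resonance; a laser
locked to the steepest flank of the resonant dip converts that shift into
reflected-intensity (and hence photodetector voltage) modulation. This
module computes the intracavity field distribution (whose value at the
facet measures how exposed the resonant energy is to the ultrasound),
selects the working point, evaluates the small-signal responsivity, and
performs the noise-equivalent-pressure bookkeeping including the
band-sectioned NEP extrapolation used when a calibrated hydrophone covers
only part of the detection bandwidth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from eersim.grating import (
    BareSection,
    EtalonStack,
    GratingSection,
    PhaseShiftElement,
    ReflectionSpectrum,
    ResonanceFeature,
    element_transfer_matrix,
    find_resonance,
    stack_matrix,
    stack_reflectance,
)

__all__ = [
    "FieldProfile",
    "ResponsivityModel",
    "NEPReport",
    "intracavity_field",
    "working_point",
    "small_signal_sensitivity",
    "nep_report",
    "nep_extrapolate",
    "laser_exposure",
]


@dataclass(frozen=True)
class FieldProfile:
    """Axial optical intensity |a|^2 + |b|^2, normalized to unit input power."""

    positions: np.ndarray  # mm from the stack input
    intensity: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if p.shape != i.shape or p.ndim != 1:
            raise ValueError("positions and intensity must be matching 1-D arrays")
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be ascending")
        if np.any(i < -1e-12):
            raise ValueError("intensity must be >= 0")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "intensity", i)

    @property
    def facet_intensity(self) -> float:
        """Intensity exposed to ultrasound at the sensing facet (last position)."""
        return float(self.intensity[-1])


@dataclass(frozen=True)
class ResponsivityModel:
    """Transduction constants.

    dn_dp : index change per unit pressure (1/Pa); default 1e-10, the
        order of magnitude of the silica elasto-optic response.
    interrogation_power : optical power in mW.
    detector_gain : photodetector responsivity in mV per mW of reflected
        optical power.
    penetration_depth : axial extent (mm) over which the incoming pressure
        wave perturbs the index, measured from the facet. Default 0.075 mm,
        half an acoustic period at the 10-30 MHz calibration band center
        (c = 1.5 mm/us, 20 MHz). ``None`` perturbs the whole region
        tip-ward of the pi shift instead.
    """

    dn_dp: float = 1e-10
    interrogation_power: float = 7.9  # mW, 9 dBm
    detector_gain: float = 1.0
    penetration_depth: Optional[float] = 0.075

    def __post_init__(self) -> None:
        if self.interrogation_power <= 0:
            raise ValueError("interrogation_power must be > 0")
        if self.detector_gain <= 0:
            raise ValueError("detector_gain must be > 0")


@dataclass(frozen=True)
class NEPReport:
    sensitivity: float  # mV/kPa
    noise_rms: float  # mV
    nep: float  # Pa
    band: Tuple[float, float]  # MHz
    nepd: float  # mPa / sqrt(Hz)


# ---------------------------------------------------------------------------
# intracavity field
# ---------------------------------------------------------------------------


def _partial_element(element, length: float):
    if isinstance(element, GratingSection):
        return replace(element, length=length) if length > 0 else None
    if isinstance(element, BareSection):
        return BareSection(length, element.n_eff) if length > 0 else None
    raise TypeError


def intracavity_field(stack: EtalonStack, wavelength: float, resolution: float = 200.0) -> FieldProfile:
    """Forward+backward optical intensity along the stack at one wavelength.

    Fields are propagated element by element from the terminator boundary
    condition b_tip = rho * a_tip, scaled so the input forward power is 1.
    `resolution` is the sampling density in points per mm.
    """
    if stack.terminator is None:
        raise ValueError("intracavity_field requires a terminated stack")
    ref = stack.reference_bragg
    m = stack_matrix(stack, float(wavelength))
    rho = stack.terminator.rho
    denom = m[0, 0] + m[0, 1] * rho
    if abs(denom) < 1e-300:
        raise FloatingPointError(f"degenerate transfer matrix at wavelength {wavelength} nm")
    scale = 1.0 / denom
    tip_fields = np.array([scale, scale * rho])  # (a, b) at the tip, unit input

    # suffix[k] maps tip fields to the input side of element k
    n_el = len(stack.elements)
    suffix = [None] * (n_el + 1)
    suffix[n_el] = np.eye(2, dtype=complex)
    for k in range(n_el - 1, -1, -1):
        suffix[k] = element_transfer_matrix(stack.elements[k], float(wavelength), ref) @ suffix[k + 1]

    positions: List[float] = []
    intensities: List[float] = []
    z0 = 0.0
    for k, el in enumerate(stack.elements):
        length = getattr(el, "length", 0.0)
        if length == 0.0:
            continue
        n_pts = max(int(math.ceil(length * resolution)), 2)
        local = np.linspace(0.0, length, n_pts, endpoint=False)
        for ell in local:
            part = _partial_element(el, length - ell)
            mat = element_transfer_matrix(part, float(wavelength), ref) if part else np.eye(2, dtype=complex)
            fields = mat @ (suffix[k + 1] @ tip_fields)
            positions.append(z0 + ell)
            intensities.append(float(np.abs(fields[0]) ** 2 + np.abs(fields[1]) ** 2))
        z0 += length
    positions.append(z0)  # the facet itself
    intensities.append(float(np.abs(tip_fields[0]) ** 2 + np.abs(tip_fields[1]) ** 2))
    return FieldProfile(np.asarray(positions), np.asarray(intensities))


def facet_exposure(stack: EtalonStack, wavelength: float, resolution: float = 500.0) -> float:
    """Facet intensity normalized to unit stored intracavity energy (mm^-1).

    Measures how exposed the resonant optical energy is to ultrasound at
    the sensing facet, independently of the Q-dependent resonant buildup;
    this is the quantity whose decrease with spacer length tracks the
    Q-normalized sensitivity trend.
    """
    profile = intracavity_field(stack, wavelength, resolution)
    energy = float(np.trapezoid(profile.intensity, profile.positions))
    if energy <= 0:
        raise ValueError("stack stores no optical energy at this wavelength")
    return profile.facet_intensity / energy


# ---------------------------------------------------------------------------
# working point and sensitivity
# ---------------------------------------------------------------------------


def working_point(spectrum: ReflectionSpectrum, resonance: ResonanceFeature) -> Tuple[float, float]:
    """Wavelength of maximum |dR/dlambda| on the dip flanks, and the signed slope.

    Centered finite differences with parabolic sub-grid refinement of
    |slope|; on an exact two-flank tie the shorter-wavelength flank wins.
    """
    wl = spectrum.wavelengths
    r = spectrum.reflectivity
    lo = resonance.center - 2.0 * resonance.fwhm
    hi = resonance.center + 2.0 * resonance.fwhm
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 5:
        mask = np.ones_like(wl, dtype=bool)
    w = wl[mask]
    rr = r[mask]
    slope = np.gradient(rr, w)
    mag = np.abs(slope)
    if float(np.max(mag)) < 1e-6:
        raise ValueError("flat spectrum: no usable slope in the resonance region")

    def refine(idx: int) -> Tuple[float, float]:
        if idx == 0 or idx == mag.size - 1:
            return float(w[idx]), float(slope[idx])
        x = w[idx - 1 : idx + 2]
        y = mag[idx - 1 : idx + 2]
        d1 = (y[1] - y[0]) / (x[1] - x[0])
        d2 = (y[2] - y[1]) / (x[2] - x[1])
        curv = 2.0 * (d2 - d1) / (x[2] - x[0])
        if curv >= 0:
            return float(w[idx]), float(slope[idx])
        xv = x[1] - ((y[2] - y[0]) / (x[2] - x[0])) / curv
        xv = float(np.clip(xv, x[0], x[2]))
        sv = float(np.interp(xv, w, slope))
        return xv, sv

    center = resonance.center
    left = mag.copy()
    left[w >= center] = -np.inf
    right = mag.copy()
    right[w <= center] = -np.inf
    candidates = []
    for side in (left, right):
        if np.any(np.isfinite(side)):
            i = int(np.argmax(side))
            x, s = refine(i)
            candidates.append((abs(s), -x, x, s))  # tie -> shorter wavelength
    if not candidates:
        raise ValueError("flat spectrum: no flank found")
    best = max(candidates)
    return best[2], best[3]


def _apply_dn(el, dn: float):
    if isinstance(el, GratingSection):
        # the inscription period is fixed, so lambda_B = 2 n Lambda scales with n
        scale = 1.0 + dn / el.n_eff
        return replace(el, n_eff=el.n_eff + dn, bragg_wavelength=el.bragg_wavelength * scale)
    if isinstance(el, BareSection):
        return BareSection(el.length, el.n_eff + dn)
    return el


def _perturbed_stack(stack: EtalonStack, dn: float, penetration_depth: Optional[float]) -> EtalonStack:
    """Index change dn applied to the acoustically loaded part of the stack.

    With a finite penetration depth the perturbation covers the last
    `penetration_depth` mm before the facet (elements are split where the
    boundary falls inside them). With ``penetration_depth=None`` every
    element tip-ward of the pi shift is perturbed uniformly.
    """
    if penetration_depth is None:
        idx = next(
            (k for k, el in enumerate(stack.elements) if isinstance(el, PhaseShiftElement)), None
        )
        if idx is None:
            raise ValueError("stack has no phase-shift element marking the cavity")
        new_elements = list(stack.elements)
        for k in range(idx + 1, len(new_elements)):
            new_elements[k] = _apply_dn(new_elements[k], dn)
        return EtalonStack(new_elements, stack.terminator)

    new_elements = []
    remaining = penetration_depth  # unperturbed->perturbed boundary, from the tip
    for el in reversed(stack.elements):
        length = getattr(el, "length", 0.0)
        if remaining <= 0 or length == 0.0:
            new_elements.append(_apply_dn(el, dn) if remaining > 0 else el)
            continue
        if length <= remaining:
            new_elements.append(_apply_dn(el, dn))
            remaining -= length
        else:
            inner = replace(el, length=length - remaining) if isinstance(el, GratingSection) else BareSection(length - remaining, el.n_eff)
            outer = replace(el, length=remaining) if isinstance(el, GratingSection) else BareSection(remaining, el.n_eff)
            new_elements.append(_apply_dn(outer, dn))
            new_elements.append(inner)
            remaining = 0.0
    return EtalonStack(list(reversed(new_elements)), stack.terminator)


def _zoom_resonance(stack: EtalonStack, center: float, halfwidth: float, points: int = 4001):
    wl = np.linspace(center - halfwidth, center + halfwidth, points)
    sp = stack_reflectance(stack, wl)
    return sp, find_resonance(sp, (wl[1], wl[-2]))


def resonance_pressure_shift(
    stack: EtalonStack,
    model: ResponsivityModel,
    pressure: float = 1e4,
    rel_tol: float = 1e-3,
    max_halvings: int = 12,
) -> float:
    """d(lambda)/dp in nm/Pa, evaluated in the small-signal (linear) limit.

    Central difference of the resonance center under +/- p, with p halved
    until the estimate is stable to `rel_tol`.
    """
    coarse = stack_reflectance(stack, np.linspace(stack.reference_bragg - 1.5, stack.reference_bragg + 1.5, 4096))
    res0 = find_resonance(coarse, (coarse.wavelengths[1], coarse.wavelengths[-2]))
    halfwidth = max(10.0 * res0.fwhm, 2e-3)
    _, res = _zoom_resonance(stack, res0.center, halfwidth)

    def shift_at(p: float) -> float:
        dn = model.dn_dp * p
        depth = model.penetration_depth
        _, rp = _zoom_resonance(_perturbed_stack(stack, +dn, depth), res.center, halfwidth)
        _, rm = _zoom_resonance(_perturbed_stack(stack, -dn, depth), res.center, halfwidth)
        return (rp.center - rm.center) / (2.0 * p)

    if model.dn_dp == 0:
        return 0.0
    est = shift_at(pressure)
    for _ in range(max_halvings):
        pressure *= 0.5
        new = shift_at(pressure)
        if est != 0 and abs(new - est) <= rel_tol * abs(est):
            return new
        est = new
    return est


def small_signal_sensitivity(
    stack: EtalonStack,
    model: ResponsivityModel,
    pressure: float = 1e4,
) -> float:
    """Small-signal responsivity in mV/kPa.

    sensitivity = |dR/dlambda at the working point| * |dlambda/dp|
                  * interrogation_power * detector_gain,
    strictly proportional to the interrogation power (the linear regime of
    intensity interrogation).
    """
    coarse = stack_reflectance(
        stack, np.linspace(stack.reference_bragg - 1.5, stack.reference_bragg + 1.5, 4096)
    )
    res0 = find_resonance(coarse, (coarse.wavelengths[1], coarse.wavelengths[-2]))
    halfwidth = max(10.0 * res0.fwhm, 2e-3)
    zoom, res = _zoom_resonance(stack, res0.center, halfwidth)
    _, slope = working_point(zoom, res)
    dldp = resonance_pressure_shift(stack, model, pressure=pressure)
    # (1/nm) * (nm/Pa) -> 1/Pa of relative reflected power; *1000 -> per kPa
    return abs(slope) * abs(dldp) * 1e3 * model.interrogation_power * model.detector_gain


# ---------------------------------------------------------------------------
# NEP bookkeeping
# ---------------------------------------------------------------------------


def nep_report(sensitivity: float, noise_rms: float, band: Tuple[float, float]) -> NEPReport:
    """NEP (Pa) and NEPD (mPa/sqrt(Hz)) from sensitivity (mV/kPa) and noise (mV)."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ValueError("band must satisfy 0 <= f_lo < f_hi (MHz)")
    nep_pa = noise_rms / sensitivity * 1e3  # mV / (mV/kPa) = kPa -> Pa
    bw_hz = (f_hi - f_lo) * 1e6
    nepd = nep_pa / math.sqrt(bw_hz) * 1e3  # Pa/sqrt(Hz) -> mPa/sqrt(Hz)
    return NEPReport(sensitivity=sensitivity, noise_rms=noise_rms, nep=nep_pa, band=(f_lo, f_hi), nepd=nepd)


def nep_extrapolate(
    sensor_spectrum,
    calibrated_band: Tuple[float, float],
    calibrated_nep: float,
) -> List[Tuple[float, float, float]]:
    """Per-band NEP table from a calibrated sub-band.

    The detection band is partitioned into contiguous sections of the
    calibrated band's width, anchored at the spectrum's lower edge (a
    trailing partial section is dropped). Assuming a spectrally flat point
    source and a common noise floor, a section with k times the
    band-integrated response of the calibrated band has NEP/k:

        NEP_k = calibrated_nep * I_cal / I_k

    Returns a list of (f_lo, f_hi, NEP); a dead section gets +inf.
    """
    f = np.asarray(sensor_spectrum.frequencies, dtype=float)
    p = np.asarray(sensor_spectrum.power, dtype=float)
    c_lo, c_hi = calibrated_band
    if c_lo < f[0] - 1e-9 or c_hi > f[-1] + 1e-9:
        raise ValueError("spectrum does not cover the calibrated band")
    width = c_hi - c_lo

    def integrate(lo: float, hi: float) -> float:
        grid = np.linspace(lo, hi, 257)
        return float(np.trapezoid(np.interp(grid, f, p), grid))

    i_cal = integrate(c_lo, c_hi)
    if i_cal <= 0:
        raise ValueError("calibrated band has zero integrated response")
    table = []
    lo = f[0]
    while lo + width <= f[-1] + 1e-9:
        hi = min(lo + width, f[-1])
        i_k = integrate(lo, hi)
        nep = calibrated_nep * i_cal / i_k if i_k > 0 else float("inf")
        table.append((float(lo), float(hi), float(nep)))
        lo += width
    return table


def laser_exposure(
    average_power_mw: float, repetition_rate_khz: float, spot_diameter_mm: float
) -> Tuple[float, float]:
    """Per-pulse fluence (mJ/cm^2) and average irradiance (W/cm^2) of the
    illumination spot, for comparison against laser-safety limits."""
    if average_power_mw <= 0 or repetition_rate_khz <= 0 or spot_diameter_mm <= 0:
        raise ValueError("power, repetition rate and spot diameter must be > 0")
    area_cm2 = math.pi * (spot_diameter_mm / 2.0 / 10.0) ** 2
    pulse_energy_mj = average_power_mw * 1e-3 / (repetition_rate_khz * 1e3) * 1e3
    fluence = pulse_energy_mj / area_cm2
    irradiance = average_power_mw * 1e-3 / area_cm2
    return fluence, irradiance
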