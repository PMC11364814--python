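"""Spacer-length estimation by spectral fitting.

During the first fabrication step one distributed reflector of a pi-shifted
FBG is polished away. The grating is invisible under a microscope, so the
remaining spacer length is inferred by comparing the continuously recorded
reflection spectrum against transfer-matrix simulations in which only the
spacer length varies; the unpolished mirror grating is held fixed. The
estimate is the spacer length whose simulated spectrum differs least from
the measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from eersim.grating import (
    EtalonStack,
    GratingSection,
    MirrorTerminator,
    PhaseShiftElement,
    ReflectionSpectrum,
    stack_reflectance,
)

__all__ = [
    "FitConfig",
    "SpacerFitResult",
    "MonitorRecord",
    "EtalonTemplate",
    "fresnel_terminator",
    "spectrum_mismatch",
    "fit_spacer_length",
    "polishing_monitor",
]


def fresnel_terminator(n_eff: float = 1.447) -> MirrorTerminator:
    """Reflectance of the bare polished silica/air facet (before coating)."""
    r = (n_eff - 1.0) / (n_eff + 1.0)
    return MirrorTerminator(amplitude_reflectance=r, phase=0.0)


@dataclass(frozen=True)
class EtalonTemplate:
    """All device parameters except the free spacer length.

    `build(spacer_length)` assembles the trial stack: fixed mirror grating,
    pi shift, spacer grating of the trial length, terminator. A zero trial
    length omits the spacer section.
    """

    mirror: GratingSection = GratingSection(2.0, 1.4, 1549.0, 1.447)
    phase: float = math.pi
    spacer_kappa: float = 1.4
    terminator: Optional[MirrorTerminator] = field(default_factory=fresnel_terminator)

    def build(self, spacer_length: float) -> EtalonStack:
        elements = [self.mirror, PhaseShiftElement(self.phase)]
        if spacer_length > 0:
            elements.append(
                GratingSection(
                    spacer_length,
                    self.spacer_kappa,
                    self.mirror.bragg_wavelength,
                    self.mirror.n_eff,
                )
            )
        return EtalonStack(elements, self.terminator)


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for the 1-D spacer-length fit.

    Defaults: 10 um coarse grid over [0, 1.5] mm, followed by bounded local
    minimization on the bracketing interval.
    """

    length_bounds: tuple = (0.0, 1.5)
    coarse_step: float = 0.010
    refine: bool = True
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if not (0 <= lo < hi):
            raise ValueError("length_bounds must satisfy 0 <= min < max")
        if not (0 < self.coarse_step <= hi - lo):
            raise ValueError("coarse_step must be in (0, max - min]")
        if self.normalization not in ("minmax", "none"):
            raise ValueError(f"unknown normalization mode {self.normalization!r}")


@dataclass(frozen=True)
class SpacerFitResult:
    spacer_length: float  # mm
    mismatch: float  # objective at the optimum
    curve: np.ndarray  # (n, 2) sampled (length, mismatch) pairs
    converged: bool


@dataclass(frozen=True)
class MonitorRecord:
    """One polishing-monitor step: the fit plus stop/plausibility flags."""

    result: SpacerFitResult
    stop: bool = False
    warning: Optional[str] = None


def _normalize(r: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return r
    lo, hi = float(np.min(r)), float(np.max(r))
    if hi == lo:
        return np.zeros_like(r)
    return (r - lo) / (hi - lo)


def spectrum_mismatch(
    observed: ReflectionSpectrum,
    simulated: ReflectionSpectrum,
    normalization: str = "minmax",
) -> float:
    """Mean squared difference of min-max-normalized reflectivities.

    The simulated spectrum is linearly resampled onto the observed grid.
    Min-max normalization makes the metric invariant to detector gain and
    offset, which the swept-laser readout does not calibrate.
    """
    wo = observed.wavelengths
    ws = simulated.wavelengths
    if wo[-1] < ws[0] or ws[-1] < wo[0]:
        raise ValueError("observed and simulated wavelength ranges do not overlap")
    rs = np.interp(wo, ws, simulated.reflectivity)
    a = _normalize(observed.reflectivity, normalization)
    b = _normalize(rs, normalization)
    return float(np.mean((a - b) ** 2))


def fit_spacer_length(
    observed: ReflectionSpectrum,
    template: EtalonTemplate,
    config: FitConfig = FitConfig(),
) -> SpacerFitResult:
    """Estimate the spacer length from one measured reflection spectrum.

    Coarse grid scan over `config.length_bounds`, then bounded local
    minimization (Brent, golden-section bracketing) on the interval around
    the best grid point. Deterministic; grid ties break toward the smaller
    length, which is the conservative choice when deciding whether to keep
    polishing.
    """
    lo, hi = config.length_bounds
    wl = observed.wavelengths

    def objective(length: float) -> float:
        sim = stack_reflectance(template.build(length), wl)
        return spectrum_mismatch(observed, sim, config.normalization)

    grid = np.arange(lo, hi + 0.5 * config.coarse_step, config.coarse_step)
    grid = grid[grid <= hi]
    values = np.array([objective(length) for length in grid])
    curve = np.column_stack([grid, values])
    spread = float(np.max(values) - np.min(values))
    if spread < 1e-14:
        return SpacerFitResult(
            spacer_length=float(grid[0]), mismatch=float(values[0]), curve=curve, converged=False
        )
    ibest = int(np.argmin(values))  # first occurrence -> smaller length on ties
    best_l, best_v = float(grid[ibest]), float(values[ibest])
    if config.refine:
        blo = max(lo, best_l - config.coarse_step)
        bhi = min(hi, best_l + config.coarse_step)
        res = minimize_scalar(objective, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-6})
        if res.fun <= best_v:
            best_l, best_v = float(res.x), float(res.fun)
    return SpacerFitResult(spacer_length=best_l, mismatch=best_v, curve=curve, converged=True)


def polishing_monitor(
    spectra_stream: Sequence[ReflectionSpectrum],
    template: EtalonTemplate,
    config: FitConfig = FitConfig(),
    target_length: float = 0.1,
    warm_halfwidth: float = 0.2,
) -> List[MonitorRecord]:
    """Fit a time-ordered stream of spectra recorded during polishing.

    Each fit after the first is warm-started: bounds are narrowed to
    +/- `warm_halfwidth` (mm) around the previous estimate. A record's
    `stop` flag is raised at the first estimate at or below
    `target_length`; an estimate that *increases* by more than two coarse
    steps triggers a warning, since polishing only removes material.
    """
    records: List[MonitorRecord] = []
    previous: Optional[float] = None
    stopped = False
    for spectrum in spectra_stream:
        cfg = config
        if previous is not None:
            lo = max(config.length_bounds[0], previous - warm_halfwidth)
            hi = min(config.length_bounds[1], previous + warm_halfwidth)
            if hi - lo > config.coarse_step:
                cfg = FitConfig(
                    length_bounds=(lo, hi),
                    coarse_step=config.coarse_step,
                    refine=config.refine,
                    normalization=config.normalization,
                )
        result = fit_spacer_length(spectrum, template, cfg)
        note = None
        if previous is not None and result.spacer_length > previous + 2 * config.coarse_step:
            note = (
                f"estimate increased from {previous:.4f} to {result.spacer_length:.4f} mm; "
                "polishing only removes material"
            )
            warnings.warn(note)
        stop = (not stopped) and result.spacer_length <= target_length
        stopped = stopped or stop
        records.append(MonitorRecord(result=result, stop=stop, warning=note))
        previous = result.spacer_length
    return records
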