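"""Seeded synthetic fixtures emulating the laboratory inputs.

Everything downstream of the physical hardware is emulated here: noisy
swept-laser reflection spectra of partially polished devices, band-limited
optoacoustic point-source traces, polishing-time spectrum streams and
suture phantoms. Noise is additive Gaussian on reflectivity, scaled
relative to the spectrum peak and clipped to [0, 1]; every stochastic path
takes an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from eersim.grating import (
    EtalonStack,
    GratingSection,
    MirrorTerminator,
    ReflectionSpectrum,
    default_wavelength_grid,
    stack_reflectance,
)
from eersim.spacerfit import EtalonTemplate, fresnel_terminator

__all__ = [
    "FixtureConfig",
    "canonical_template",
    "make_spectrum_fixture",
    "make_polishing_stream",
    "make_suture_phantom",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Default device parameters and noise levels of the synthetic suite.

    The device defaults are the fabricated sensor's: kappa = 1.4 mm^-1,
    2 mm mirror grating, Bragg wavelength 1549 nm, and a 10.1 um mode-field
    diameter; n_eff = 1.447 is standard single-mode silica at 1550 nm.
    """

    seed: int = 0
    spectral_noise: float = 0.01  # relative to peak reflectivity
    trace_noise: float = 0.0  # Pa RMS
    kappa: float = 1.4
    mirror_length: float = 2.0
    bragg: float = 1549.0
    n_eff: float = 1.447
    mfd: float = 10.1  # um
    grid_points: int = 4096
    grid_half_span: float = 1.5  # nm

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.spectral_noise < 0 or self.trace_noise < 0:
            raise ValueError("noise levels must be >= 0")


def canonical_template(config: FixtureConfig = FixtureConfig(), coated: bool = False) -> EtalonTemplate:
    """Device template with the fixture parameters.

    ``coated=False`` (during polishing, step 1) terminates the stack with
    the bare-facet Fresnel reflection; ``coated=True`` adds the silver
    mirror of the finished sensor.
    """
    terminator = MirrorTerminator() if coated else fresnel_terminator(config.n_eff)
    return EtalonTemplate(
        mirror=GratingSection(config.mirror_length, config.kappa, config.bragg, config.n_eff),
        phase=math.pi,
        spacer_kappa=config.kappa,
        terminator=terminator,
    )


def make_spectrum_fixture(
    true_spacer: float,
    config: FixtureConfig = FixtureConfig(),
    coated: bool = False,
) -> Tuple[ReflectionSpectrum, dict]:
    """Noisy reflection spectrum of a device with known spacer length.

    Returns the spectrum and a ground-truth record (true length, seed and
    device parameters) for self-evaluation of the fitting pipeline.
    """
    if true_spacer < 0:
        raise ValueError("true_spacer must be >= 0")
    template = canonical_template(config, coated=coated)
    wl = default_wavelength_grid(config.bragg, config.grid_half_span, config.grid_points)
    clean = stack_reflectance(template.build(true_spacer), wl)
    r = clean.reflectivity
    if config.spectral_noise > 0:
        rng = np.random.default_rng(config.seed)
        r = r + config.spectral_noise * float(np.max(r)) * rng.standard_normal(r.shape)
        r = np.clip(r, 0.0, 1.0)
    truth = {
        "true_spacer_mm": float(true_spacer),
        "seed": int(config.seed),
        "spectral_noise": float(config.spectral_noise),
        "kappa_per_mm": float(config.kappa),
        "mirror_length_mm": float(config.mirror_length),
        "bragg_nm": float(config.bragg),
        "n_eff": float(config.n_eff),
        "coated": bool(coated),
    }
    return ReflectionSpectrum.from_reflectivity(wl, r), truth


def make_polishing_stream(
    start: float,
    end: float,
    steps: int,
    config: FixtureConfig = FixtureConfig(),
) -> Tuple[List[ReflectionSpectrum], np.ndarray]:
    """Spectra of a polishing run: spacer decreasing uniformly start -> end (mm).

    Returns the time-ordered spectra and the true spacer lengths. Each step
    derives its own child seed from ``config.seed`` so replicate streams
    are reproducible yet per-step independent.
    """
    if not (start > end >= 0):
        raise ValueError("need start > end >= 0")
    if steps < 2:
        raise ValueError("need at least 2 steps")
    lengths = np.linspace(start, end, steps)
    seeds = np.random.SeedSequence(config.seed).generate_state(steps) % (2**31)
    spectra = []
    for length, seed in zip(lengths, seeds):
        cfg = FixtureConfig(
            seed=int(seed),
            spectral_noise=config.spectral_noise,
            trace_noise=config.trace_noise,
            kappa=config.kappa,
            mirror_length=config.mirror_length,
            bragg=config.bragg,
            n_eff=config.n_eff,
            mfd=config.mfd,
            grid_points=config.grid_points,
            grid_half_span=config.grid_half_span,
        )
        spectrum, _ = make_spectrum_fixture(float(length), cfg)
        spectra.append(spectrum)
    return spectra, lengths


def make_suture_phantom(
    depths_mm: Tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5),
    sutures_per_layer: Tuple[int, ...] = (3, 3, 2, 2, 2),
    diameters_um: Tuple[float, float] = (30.0, 39.0),
    length_mm: float = 0.4,
    pitch_um: float = 10.0,
    seed: int = 0,
):
    """Suture phantom: 12 sutures in 5 depth layers, 30-39 um diameters.

    Sutures run along y and are offset in x within each layer; each suture
    is discretized as a dense line of point sources at `pitch_um` spacing.
    Returns a :class:`eersim.imaging.Phantom`.
    """
    from eersim.imaging import Phantom, PointSource

    rng = np.random.default_rng(seed)
    sources = []
    n_y = max(int(round(length_mm * 1000 / pitch_um)), 1)
    ys = (np.arange(n_y) - (n_y - 1) / 2) * pitch_um * 1e-3
    for depth, n_sutures in zip(depths_mm, sutures_per_layer):
        xs = np.linspace(-0.25, 0.25, n_sutures + 2)[1:-1]
        xs = xs + rng.uniform(-0.02, 0.02, size=n_sutures)
        for x in xs:
            d = float(rng.uniform(*diameters_um))
            for y in ys:
                sources.append(PointSource(position=(float(x), float(y), float(depth)), diameter=d, amplitude=1.0))
    return Phantom(sources=tuple(sources), kind="suture")
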