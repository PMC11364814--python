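import math

import numpy as np
import pytest

from eersim.grating import (
    EtalonStack,
    GratingSection,
    MirrorTerminator,
    PhaseShiftElement,
    default_wavelength_grid,
    stack_reflectance,
)


@pytest.fixture(scope="session")
def intact_pfbg():
    """Intact device before polishing: 2 + 2 mm pi-shifted grating, no coating."""
    return EtalonStack(
        [GratingSection(2.0), PhaseShiftElement(math.pi), GratingSection(2.0)]
    )


@pytest.fixture(scope="session")
def intact_spectrum(intact_pfbg):
    return stack_reflectance(intact_pfbg, default_wavelength_grid())


@pytest.fixture(scope="session")
def coupled_mode_oracle():
    """Brute-force reflectance by numerical integration of the coupled-mode ODEs.

    Integrates d/dz (a, b) = Q(z) (a, b) with Q = [[-i d, -i k], [i k, i d]]
    section by section with a stiff-tolerance RK integrator, inserting the
    discrete phase-shift matrices between sections, and applies the same
    terminator boundary condition as the transfer-matrix path. Independent
    of the closed-form cosh/sinh matrices under test.
    """
    from scipy.integrate import solve_ivp

    from eersim.grating import BareSection

    def reflectivity(stack: EtalonStack, wavelengths):
        ref = stack.reference_bragg
        out = []
        for wl in np.atleast_1d(wavelengths):
            m = np.eye(2, dtype=complex)
            for el in stack.elements:
                if isinstance(el, PhaseShiftElement):
                    f = np.diag([np.exp(-1j * el.phase / 2), np.exp(1j * el.phase / 2)])
                else:
                    if isinstance(el, (GratingSection, BareSection)):
                        n_eff = el.n_eff
                        kappa = getattr(el, "kappa", 0.0)
                        lb = getattr(el, "bragg_wavelength", ref)
                        delta = 2 * np.pi * n_eff * (1 / (wl * 1e-6) - 1 / (lb * 1e-6))
                    else:
                        raise TypeError(type(el))
                    q = np.array([[-1j * delta, -1j * kappa], [1j * kappa, 1j * delta]])

                    def rhs(_z, y):
                        return (q @ y.reshape(2, 2)).ravel()

                    sol = solve_ivp(
                        rhs,
                        (0.0, el.length),
                        np.eye(2, dtype=complex).ravel(),
                        rtol=1e-10,
                        atol=1e-12,
                        method="DOP853",
                    )
                    f = sol.y[:, -1].reshape(2, 2)
                m = m @ f
            rho = stack.terminator.rho if stack.terminator is not None else 0.0
            r = (m[1, 0] + m[1, 1] * rho) / (m[0, 0] + m[0, 1] * rho)
            out.append(abs(r) ** 2)
        return np.array(out)

    return reflectivity
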