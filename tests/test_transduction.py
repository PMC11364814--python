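"""Intracavity field, working point, responsivity and NEP bookkeeping."""

import math

import numpy as np
import pytest

from eersim.acoustics import PowerSpectrum
from eersim.grating import (
    EtalonStack,
    GratingSection,
    MirrorTerminator,
    ReflectionSpectrum,
    ResonanceFeature,
    canonical_eer,
    default_wavelength_grid,
    find_resonance,
    stack_reflectance,
)
from eersim.transduction import (
    ResponsivityModel,
    facet_exposure,
    intracavity_field,
    laser_exposure,
    nep_extrapolate,
    nep_report,
    small_signal_sensitivity,
    working_point,
)


def eer_resonance(spacer, **kwargs):
    """Stack, spectrum and the etalon dip nearest the Bragg wavelength."""
    stack = canonical_eer(spacer, **kwargs)
    wl = default_wavelength_grid()
    sp = stack_reflectance(stack, wl)
    return stack, sp, find_resonance(sp, (1548.6, 1549.45))


class TestIntracavityField:
    def test_mirror_only_limit_is_a_uniform_standing_wave(self):
        # no grating screening, perfect mirror: unit forward + unit backward
        stack = EtalonStack([GratingSection(1.0, kappa=0.0)], MirrorTerminator(1.0, math.pi))
        profile = intracavity_field(stack, 1549.0)
        assert np.allclose(profile.intensity, 2.0, atol=1e-9)

    def test_resonant_field_enhancement_at_the_facet(self):
        stack, _, res = eer_resonance(0.45)
        on = intracavity_field(stack, res.center).facet_intensity
        off = intracavity_field(stack, res.center + 0.5).facet_intensity
        assert on > off

    def test_facet_exposure_decreases_with_spacer_length(self):
        # the trend behind choosing the thinnest spacer: less grating between
        # cavity and facet means more of the stored energy meets the ultrasound
        exposures = []
        for spacer in (0.07, 0.45, 1.0):
            stack, _, res = eer_resonance(spacer)
            exposures.append(facet_exposure(stack, res.center))
        assert exposures[0] > exposures[1] > exposures[2]

    def test_exposure_monotone_over_fine_spacer_sweep(self):
        # monotone decreasing above ~0.15 mm, where the spacer grating starts
        # screening the facet from the stored cavity energy
        values = []
        for spacer in np.linspace(0.15, 1.2, 8):
            stack, _, res = eer_resonance(float(spacer))
            values.append(facet_exposure(stack, res.center))
        assert all(b <= a * (1 + 1e-6) for a, b in zip(values, values[1:]))

    def test_requires_terminator(self):
        with pytest.raises(ValueError, match="termin"):
            intracavity_field(canonical_eer(0.45, terminator=None), 1549.0)


class TestWorkingPoint:
    @staticmethod
    def lorentzian(center=1549.0, fwhm=0.02, depth=0.8):
        wl = np.linspace(center - 0.3, center + 0.3, 24001)
        r = 1.0 - depth * (fwhm / 2) ** 2 / ((wl - center) ** 2 + (fwhm / 2) ** 2)
        return ReflectionSpectrum.from_reflectivity(wl, r)

    def test_lorentzian_working_point_offset(self):
        # |dR/dlambda| of a Lorentzian dip peaks at center +/- FWHM/(2 sqrt(3))
        sp = self.lorentzian()
        res = find_resonance(sp, (1548.8, 1549.2))
        wl_wp, slope = working_point(sp, res)
        assert abs(wl_wp - res.center) == pytest.approx(res.fwhm / (2 * math.sqrt(3)), rel=5e-3)
        assert slope != 0

    def test_exact_tie_prefers_shorter_wavelength(self):
        sp = self.lorentzian()  # perfectly symmetric dip
        res = find_resonance(sp, (1548.8, 1549.2))
        wl_wp, _ = working_point(sp, res)
        assert wl_wp < res.center

    def test_higher_q_cavity_has_steeper_working_point(self):
        slopes = []
        for rho in (0.90, 0.99):
            stack, sp, res = eer_resonance(0.45, terminator=MirrorTerminator(rho, math.pi))
            wl = np.linspace(res.center - 10 * res.fwhm, res.center + 10 * res.fwhm, 4001)
            zoom = stack_reflectance(stack, wl)
            zres = find_resonance(zoom, (wl[1], wl[-2]))
            slopes.append(abs(working_point(zoom, zres)[1]))
        assert slopes[1] > slopes[0]

    def test_flat_spectrum_is_an_error(self):
        wl = np.linspace(1548.0, 1550.0, 512)
        sp = ReflectionSpectrum.from_reflectivity(wl, np.full_like(wl, 0.5))
        feature = ResonanceFeature(center=1549.0, fwhm=0.1, depth=0.0, q_factor=15490.0)
        with pytest.raises(ValueError, match="[Ff]lat"):
            working_point(sp, feature)


class TestSensitivity:
    def test_exactly_proportional_to_interrogation_power(self):
        stack = canonical_eer(0.45)
        base = small_signal_sensitivity(stack, ResponsivityModel(interrogation_power=1.0))
        for power in (10.0, 100.0, 1000.0):
            s = small_signal_sensitivity(stack, ResponsivityModel(interrogation_power=power))
            assert s == pytest.approx(base * power, rel=1e-9)

    def test_no_elasto_optic_response_means_no_signal(self):
        assert small_signal_sensitivity(canonical_eer(0.45), ResponsivityModel(dn_dp=0.0)) == 0.0

    def test_q_normalized_sensitivity_tracks_facet_exposure(self):
        # Q-normalized sensitivity and facet exposure decrease together with
        # spacer length: the thinner the polished spacer, the better the
        # ultrasound reaches the resonant field
        ratios, exposures = [], []
        for spacer in (0.07, 0.45, 1.0):
            stack, _, res = eer_resonance(spacer)
            sens = small_signal_sensitivity(stack, ResponsivityModel())
            ratios.append(sens / res.q_factor)
            exposures.append(facet_exposure(stack, res.center))
        assert np.argsort(ratios).tolist() == np.argsort(exposures).tolist()
        assert ratios[0] > ratios[1] > ratios[2]


class TestNEP:
    def test_worked_example_matches_measured_calibration(self):
        # 1.78 mV RMS noise against 145 mV/kPa over the hydrophone band
        rep = nep_report(145.0, 1.78, (10.0, 30.0))
        assert rep.nep == pytest.approx(12.276, abs=0.01)

    def test_nepd_worked_example(self):
        # 11.4 Pa over a 20 MHz band -> ~2.5 mPa/sqrt(Hz)
        sens = 145.0
        rep = nep_report(sens, 11.4 * sens / 1e3, (7.0, 27.0))
        assert rep.nep == pytest.approx(11.4, rel=1e-12)
        assert rep.nepd == pytest.approx(2.55, abs=0.01)

    def test_zero_noise_gives_zero_nep(self):
        assert nep_report(145.0, 0.0, (10.0, 30.0)).nep == 0.0

    def test_unit_round_trip(self):
        rep = nep_report(200.0, 4.0, (0.0, 100.0))
        # mV / (mV/kPa) -> kPa -> Pa and back
        assert rep.nep / 1e3 * rep.sensitivity == pytest.approx(rep.noise_rms, rel=1e-12)
        assert rep.nepd == pytest.approx(rep.nep / math.sqrt(100e6) * 1e3, rel=1e-12)

    def test_zero_sensitivity_is_an_error(self):
        with pytest.raises(ValueError):
            nep_report(0.0, 1.0, (10.0, 30.0))


class TestNEPExtrapolation:
    def test_flat_spectrum_reproduces_calibrated_nep_everywhere(self):
        f = np.linspace(10.0, 170.0, 801)
        ps = PowerSpectrum(f, np.ones_like(f))
        table = nep_extrapolate(ps, (10.0, 30.0), 12.4)
        assert len(table) == 8
        for _, _, nep in table:
            assert nep == pytest.approx(12.4, rel=1e-9)

    def test_double_response_halves_nep(self):
        f = np.linspace(10.0, 50.0, 401)
        p = np.where(f >= 30.0, 2.0, 1.0)
        ps = PowerSpectrum(f, p)
        table = nep_extrapolate(ps, (10.0, 30.0), 12.4)
        assert table[0][2] == pytest.approx(12.4, rel=1e-6)
        assert table[1][2] == pytest.approx(6.2, rel=1e-2)  # step edge is one bin wide

    def test_most_responsive_window_carries_the_peak_nep(self):
        # a band-limited response peaking over 7-27 MHz: that section's NEP
        # is the minimum of the table
        f = np.linspace(7.0, 167.0, 1601)
        p = np.exp(-((f - 17.0) ** 2) / (2 * 25.0**2))
        ps = PowerSpectrum(f, p)
        table = nep_extrapolate(ps, (27.0, 47.0), 20.0)
        best = min(table, key=lambda row: row[2])
        assert (best[0], best[1]) == (7.0, 27.0)

    def test_dead_section_flags_infinity(self):
        f = np.linspace(0.0, 40.0, 401)
        p = np.where(f < 20.0, 1.0, 0.0)  # exactly zero over the second section
        ps = PowerSpectrum(f, p)
        table = nep_extrapolate(ps, (0.0, 20.0), 10.0)
        assert math.isinf(table[1][2])


def test_illumination_exposure_worked_example():
    # 3.2 mW average power at 1.2 kHz into a <1 mm spot
    fluence, irradiance = laser_exposure(3.2, 1.2, 1.0)
    assert fluence == pytest.approx(0.34, abs=0.01)
    assert irradiance == pytest.approx(0.41, abs=0.01)
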