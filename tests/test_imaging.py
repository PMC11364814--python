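"""Scan simulation, f-k reconstruction, SIR metrics and the phantom pipeline."""

import numpy as np
import pytest
from scipy.signal import find_peaks, hilbert

from eersim.acoustics import SourceModel
from eersim.fixtures import make_suture_phantom
from eersim.imaging import (
    DetectorModel,
    Phantom,
    PointSource,
    ScanGeometry,
    SIRMap,
    Sinogram,
    fd_backproject,
    raster_image,
    simulate_scan,
    sir_fwhm,
)


@pytest.fixture(scope="module")
def detector():
    return DetectorModel()  # 10.1 um aperture, 5-160 MHz, 100 deg acceptance


@pytest.fixture(scope="module")
def source():
    return SourceModel()


def point_scan(D, detector, source, span=1.0, step=4.0, dt=2.0):
    geometry = ScanGeometry(standoff=D, step=step, span=span, dt=dt)
    phantom = Phantom([PointSource((0.0, 0.0, D))])
    return simulate_scan(phantom, detector, geometry, source)


class TestSimulateScan:
    def test_arrival_times_lie_on_the_hyperbola(self, detector, source):
        sino = point_scan(0.5, detector, source)
        envelope = np.abs(hilbert(sino.data, axis=1))
        t_peak = np.argmax(envelope, axis=1) * sino.dt
        predicted = np.sqrt(0.5**2 + sino.x**2) / source.speed_of_sound * 1e3
        # consider only positions inside the acceptance cone
        visible = np.abs(sino.x) <= 0.5 * np.tan(np.radians(50.0))
        assert np.max(np.abs(t_peak - predicted)[visible]) <= sino.dt

    def test_source_outside_acceptance_cone_contributes_nothing(self, source):
        det = DetectorModel(band=(5.0, 160.0), acceptance_angle=60.0)
        geometry = ScanGeometry(standoff=0.5, step=4.0, span=1.0, dt=2.0)
        phantom = Phantom([PointSource((0.0, 0.0, 0.2))])  # 68 deg at x = -0.5
        sino = simulate_scan(phantom, det, geometry, source)
        theta = np.degrees(np.arctan(np.abs(sino.x) / 0.2))
        blocked = theta > 30.0 + 1.0
        assert np.all(sino.data[blocked] == 0.0)
        assert np.any(sino.data[~blocked] != 0.0)

    def test_depth_ratio_follows_spherical_spreading(self, detector, source):
        # identical windows so the filtered tails wrap identically
        geometry = ScanGeometry(standoff=0.5, step=4.0, span=0.2, dt=2.0, n_samples=4096)
        shallow = simulate_scan(Phantom([PointSource((0.0, 0.0, 0.5))]), detector, geometry, source)
        deep = simulate_scan(Phantom([PointSource((0.0, 0.0, 4.5))]), detector, geometry, source)
        mid = shallow.data.shape[0] // 2
        # energy ratio is invariant to the sub-sample arrival offset
        ratio = np.sqrt(np.sum(shallow.data[mid] ** 2) / np.sum(deep.data[mid] ** 2))
        assert ratio == pytest.approx(9.0, rel=0.01)

    def test_nyquist_violation_names_the_required_step(self, detector, source):
        geometry = ScanGeometry(standoff=0.5, step=50.0, span=1.0, dt=2.0)
        with pytest.raises(ValueError, match="required step"):
            simulate_scan(Phantom([PointSource((0.0, 0.0, 0.5))]), detector, geometry, source)

    def test_seeded_noise_is_reproducible(self, source):
        det = DetectorModel(nep=5.0)
        geometry = ScanGeometry(standoff=0.5, step=4.0, span=0.1, dt=2.0)
        phantom = Phantom([PointSource((0.0, 0.0, 0.5))])
        a = simulate_scan(phantom, det, geometry, source, seed=42)
        b = simulate_scan(phantom, det, geometry, source, seed=42)
        c = simulate_scan(phantom, det, geometry, source, seed=43)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestBackprojection:
    @pytest.mark.parametrize("D", [0.25, 0.5, 2.0, 5.0])
    def test_point_source_localized_within_one_pixel(self, detector, source, D):
        sino = point_scan(D, detector, source)
        sir = fd_backproject(sino)
        ix, iz = np.unravel_index(np.argmax(sir.image), sir.image.shape)
        x_err = abs(sir.x[ix] - (0.0 - sino.x[0]) * 1e3)
        z_err = abs(sir.z[iz] - D * 1e3)
        assert x_err <= sir.pixel_um[0]
        assert z_err <= 2 * sir.pixel_um[-1]  # envelope peak within one dz each side

    def test_well_separated_sources_are_resolved(self, detector, source):
        geometry = ScanGeometry(standoff=0.5, step=4.0, span=1.0, dt=2.0)
        phantom = Phantom([PointSource((-0.15, 0.0, 0.5)), PointSource((0.15, 0.0, 0.5))])
        sir = fd_backproject(simulate_scan(phantom, detector, geometry, source))
        lateral = sir.image.max(axis=1)
        lateral = lateral / lateral.max()
        peaks, _ = find_peaks(lateral, height=0.5)
        assert peaks.size == 2
        between = lateral[peaks[0] : peaks[1] + 1]
        assert between.min() <= 0.5 * between.max()

    def test_reconstruction_is_linear_in_the_phantom(self, detector, source):
        geometry = ScanGeometry(standoff=0.5, step=4.0, span=0.5, dt=2.0, n_samples=1024)
        a = Phantom([PointSource((-0.1, 0.0, 0.5))])
        b = Phantom([PointSource((0.1, 0.0, 0.6))])
        both = Phantom(list(a.sources) + list(b.sources))
        sino_a = simulate_scan(a, detector, geometry, source)
        sino_b = simulate_scan(b, detector, geometry, source)
        sino_ab = simulate_scan(both, detector, geometry, source)
        # sinograms superpose exactly; the migration operator is linear too
        assert np.allclose(sino_ab.data, sino_a.data + sino_b.data, atol=1e-12)

    def test_energy_stays_near_the_source(self, detector, source):
        sino = point_scan(0.5, detector, source)
        sir = fd_backproject(sino)
        total = np.sum(sir.image**2)
        zmask = np.abs(sir.z - 500.0) < 150.0
        near = np.sum(sir.image[:, zmask] ** 2)
        assert near / total > 0.9

    def test_non_uniform_sampling_is_an_error(self):
        x = np.array([0.0, 0.004, 0.012])
        sino = Sinogram(data=np.zeros((3, 64)), x=x, dt=2.0)
        with pytest.raises(ValueError, match="non-uniform"):
            fd_backproject(sino)


class TestSIRMetrics:
    def test_gaussian_blob_fwhm(self):
        x = np.arange(101) * 2.0  # um
        z = np.arange(201) * 1.0
        xx, zz = np.meshgrid(x, z, indexing="ij")
        sigma = 10.0
        img = np.exp(-((xx - 100.0) ** 2 + (zz - 100.0) ** 2) / (2 * sigma**2))
        lat, ax = sir_fwhm(SIRMap(image=img, x=x, z=z))
        assert lat == pytest.approx(23.55, abs=0.05)
        assert ax == pytest.approx(23.55, abs=0.05)

    def test_peak_on_border_is_an_error(self):
        x = np.arange(32) * 2.0
        z = np.arange(32) * 2.0
        img = np.zeros((32, 32))
        img[0, 16] = 1.0
        with pytest.raises(ValueError, match="border"):
            sir_fwhm(SIRMap(image=img, x=x, z=z))

    def test_lateral_fwhm_grows_with_imaging_distance(self, detector, source):
        laterals = []
        for D in (0.5, 2.0, 5.0):
            sir = fd_backproject(point_scan(D, detector, source))
            laterals.append(sir_fwhm(sir)[0])
        assert laterals[0] < laterals[1] < laterals[2]

    def test_axial_fwhm_stays_band_limited_across_depth(self, detector, source):
        # the axial width is set by the detection band, not the distance
        axials = []
        for D in (0.25, 0.5, 2.0, 5.0):
            axials.append(sir_fwhm(fd_backproject(point_scan(D, detector, source)))[1])
        assert max(axials) <= 4 * min(axials)
        # and never below the bandwidth-limited resolution scale
        assert min(axials) >= 0.5 * 1.5 / detector.band[1] * 1e3


@pytest.fixture(scope="module")
def suture_setup():
    phantom = make_suture_phantom()
    detector = DetectorModel(band=(5.0, 30.0))
    geometry = ScanGeometry(
        standoff=0.5, step=20.0, span=0.8, y_step=20.0, y_span=0.08, dt=8.0
    )
    return phantom, detector, geometry


class TestRasterPipeline:
    def test_all_five_suture_layers_are_resolved(self, suture_setup, source):
        phantom, detector, geometry = suture_setup
        out = raster_image(phantom, detector, geometry, source, n_avg=1, band=(5.0, 30.0))
        xz = out["mips"]["xz"]
        z = out["volume"].z
        profile = xz.max(axis=0)
        profile = profile / profile.max()
        dz = z[1] - z[0]
        peaks, _ = find_peaks(profile, height=0.05, distance=int(500.0 / dz))
        depths = z[peaks]
        expected = np.array([500.0, 1500.0, 2500.0, 3500.0, 4500.0])
        assert len(depths) == 5
        assert np.all(np.abs(np.sort(depths) - expected) < 100.0)

    def test_averaging_improves_snr_like_sqrt_n(self):
        detector = DetectorModel(band=(5.0, 30.0), nep=30.0)
        geometry = ScanGeometry(
            standoff=0.5, step=20.0, span=0.4, y_step=20.0, y_span=0.04, dt=8.0, n_samples=512
        )
        # a bright source so the single-shot image is noise-limited yet visible
        bright = SourceModel(amplitude=1e4)
        phantom = Phantom([PointSource((0.0, 0.0, 0.5))])

        def snr(n_avg):
            out = raster_image(phantom, detector, geometry, bright, seed=9, n_avg=n_avg, band=(5.0, 30.0))
            img = out["volume"].image
            signal = img.max()
            z = out["volume"].z
            zq = (z > 3000.0) & (z < 5000.0)  # far from any source
            noise = np.sqrt(np.mean(img[:, :, zq] ** 2))
            return signal / noise

        gain = snr(20) / snr(1)
        assert gain == pytest.approx(np.sqrt(20.0), rel=0.2)

    def test_apparent_suture_width_nondecreasing_with_depth(self, suture_setup, source):
        phantom, detector, geometry = suture_setup
        out = raster_image(phantom, detector, geometry, source, n_avg=1, band=(5.0, 30.0))
        xz = out["mips"]["xz"]
        z = out["volume"].z
        x = out["volume"].x
        widths = []
        for depth in (500.0, 2500.0, 4500.0):
            zmask = np.abs(z - depth) < 200.0
            lateral = xz[:, zmask].max(axis=1)
            ipk = int(np.argmax(lateral))
            half = lateral[ipk] / 2
            above = lateral >= half
            widths.append(np.sum(above) * (x[1] - x[0]))
        assert widths[0] <= widths[1] <= widths[2]
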