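# Methods

This note documents the models behind `eersim`, their assumptions, the
defaults that matter, and what the synthetic test suite does and does not
demonstrate about real hardware.

## Device model

The sensor is an etalon embedded in the core of a single-mode fiber: a long
(2 mm) uniform Bragg-grating mirror on the interrogation side, a discrete
pi phase shift, a short residual grating ("spacer", tens of micrometers
after polishing) and a thin silver mirror on the polished facet. Incoming
ultrasound perturbs the refractive index near the facet, shifts the optical
resonance, and modulates the reflected power of a laser parked on the
steepest flank of the resonant dip.

### Transfer-matrix optics (`grating`)

Each uniform grating section is described by standard coupled-mode theory.
With detuning `delta = 2*pi*n_eff*(1/lambda - 1/lambda_B)` and
`gamma = sqrt(kappa^2 - delta^2)` the 2x2 field matrix is

    F = [[cosh(gL) - i(d/g)sinh(gL),  -i(k/g)sinh(gL)],
         [+i(k/g)sinh(gL),            cosh(gL) + i(d/g)sinh(gL)]]

mapping (forward, backward) fields on the tip side to the input side; the
stack matrix is the ordered product from input to tip, and a terminator of
complex amplitude `rho` closes the system:
`r = (M21 + M22*rho) / (M11 + M12*rho)`. Numerical points:

* `sinh(gL)/g` is evaluated by a 6th-order series for `|gL| < 1e-4`, so the
  band edge (`gamma -> 0`) is continuous; the branch of the square root is
  irrelevant because both `cosh` and `sinh(x)/x` are even.
* All loss-free matrices are unimodular and flux-conserving (SU(1,1)); a
  lossless stack with `|rho| = 1` reflects unit power at every wavelength.
  Both properties are asserted in tests; the whole path is additionally
  cross-checked against direct numerical integration of the coupled-mode
  ODEs to < 1e-6 in reflectivity.
* The pi shift is `diag(e^{-i pi/2}, e^{+i pi/2})`. Any equivalent global
  phase convention yields the same `|r|^2`.
* Optional loss enters as a complex detuning `delta - i*alpha`.

Defaults: `kappa = 1.4 mm^-1`, `lambda_B = 1549 nm`, mirror length 2 mm,
`n_eff = 1.447` (standard single-mode silica near 1550 nm; the device
vendor does not quote it), silver terminator `|rho| = 0.98`, phase `pi`
(plausible for a ~200 nm silver film at 1550 nm; thickness is the only
published property, so both are configurable), simulation grid
`lambda_B +/- 1.5 nm` with 4096 points.

**Stop-band width.** The quoted "band gap" of the intact device (~1 nm at
`kappa = 1.4 mm^-1`) corresponds to the full width at half of the peak
reflectivity of the *main* reflection band: the above-half region containing
the peak, with the central pi-shift dip bridged by merging the twin band
lobe. Side lobes of the uniform-grating response exceed half maximum (first
lobe reaches ~0.53 of the peak) but never the 0.8-of-peak plateau criterion,
so they are excluded; taking the outermost half-max crossing instead would
give ~1.55 nm and describes the side-lobe envelope, not the band. The
band-edge (`|delta| = kappa`) width is 0.74 nm and is strictly narrower.

**Resonance metrics.** The dip center uses parabolic sub-grid refinement of
the reflectivity minimum; the width is measured at half depth between the
local baseline (the lower of the two flanking maxima inside the window) and
the minimum; `Q = center/width`. With the local-baseline convention a
synthetic Lorentzian's Q is recovered to a few tenths of a percent.

### Spacer-length fitting (`spacerfit`)

During polishing the grating is invisible under a microscope, so the
remaining spacer length is estimated by comparing each recorded spectrum
with simulations in which only the spacer length varies; the unpolished
2 mm mirror, `kappa`, `lambda_B`, `n_eff` and the facet reflectance are
trusted template values. Choices:

* Objective: mean squared difference of min-max-normalized reflectivities,
  robust to the uncalibrated gain and offset of a swept-laser readout.
  Alternative metrics plug in through the `normalization` switch.
* Search: 10 um coarse grid over [0, 1.5] mm, then bounded scalar
  minimization on the bracketing interval (1 nm tolerance). Grid ties break
  toward the smaller length — the conservative direction when the decision
  is whether to keep polishing. Deterministic for fixed inputs.
* Before coating, the facet is terminated by the silica/air Fresnel
  reflection (`|rho| = 0.183`), which the polishing-time template uses.
* The streaming monitor warm-starts each fit within +/-0.2 mm of the
  previous estimate, raises a stop flag at the first estimate at or below
  the target length, and warns if an estimate increases by more than two
  coarse steps (polishing only removes material).

On synthetic spectra with 1% additive noise the worst-case recovery error
over spacer lengths 0.07-1.0 mm is ~6 um, comfortably inside the 50 um
precision quoted for the physical method; noiseless spectra recover to
better than 1 um. Real spectra add systematic effects the fixtures do not
model (polarization structure of the PM fiber, wavelength-sweep jitter,
polishing-angle error), so the synthetic precision is a lower bound on
error, not a claim about hardware.

### Transduction and NEP (`transduction`)

The intracavity field is propagated element-by-element from the terminator
boundary condition at unit input power; its value at the facet measures how
exposed the stored optical energy is to the ultrasound. Because the raw
facet intensity at unit input scales with the resonant buildup (hence Q),
the exposure metric `facet_exposure` normalizes the facet intensity by the
stored intracavity energy. This exposure decreases monotonically with
spacer length above ~0.15 mm — the thicker the residual grating, the more
it screens the facet — and over the fabricated-device range
{0.07, 0.45, 1.0} mm it is strictly decreasing, the trend that motivates
polishing the spacer as thin as possible. Below ~0.15 mm the exposure
levels off and dips slightly: there the spacer grating no longer adds
appreciable reflectance to the silver and the resonant field redistributes
into the long mirror.

Small-signal responsivity: a pressure `p` produces an index change
`dn = dn_dp * p` over an acoustic penetration depth from the facet
(default 0.075 mm — half an acoustic period at the 20 MHz center of the
10-30 MHz calibration band, c = 1.5 mm/us). A uniform perturbation of the
whole tip-side region is available (`penetration_depth=None`) but inverts
the sensitivity-versus-spacer ordering, because the overlap of the
perturbation with the resonant field then *grows* with spacer length; the
penetration-depth model reproduces the observed trend, with Q-normalized
sensitivity tracking the facet exposure. The resonance shift is evaluated
by re-simulation with central differences and pressure-halving until the
estimate is stable to 0.1%; the output
`|dR/dlambda| * |dlambda/dp| * power * gain` is exactly proportional to the
interrogation power (the linear regime of intensity interrogation; noise
saturation at high power is a laser phenomenon outside this model, so
`noise_rms` is an input, never predicted).

Defaults: `dn_dp = 1e-10 /Pa` (order of magnitude of the silica
elasto-optic response; absolute mV/kPa values are model units unless the
user calibrates `detector_gain`), interrogation power 7.9 mW (9 dBm).

NEP bookkeeping: `NEP = noise_rms / sensitivity` (Pa) and
`NEPD = NEP / sqrt(bandwidth)` (mPa Hz^-1/2). The extrapolation method
partitions the detection band into sections as wide as the calibrated
hydrophone band, anchored at the spectrum's lower edge with a trailing
partial section dropped; assuming a spectrally flat point source and a
common noise floor, `NEP_k = NEP_cal * I_cal / I_k` with band-integrated
responses `I`. The section coinciding with the calibrated band returns the
calibrated NEP identically.

### Acoustic characterization (`acoustics`)

The optoacoustic point source is an N-wave: the time derivative of a
Gaussian whose FWHM is the excitation pulse width (default 1.2 ns),
centered at `distance/c` with 1/r spherical spreading. Band-pass filtering
is zero-phase (forward-backward Butterworth, order 4) so width and
bandwidth measurements are not phase-biased. The detection bandwidth is the
highest frequency at which the peak-normalized power spectrum crosses the
threshold fraction (default 20%), searched downward from the top of the
grid — the convention behind quoting a single bandwidth number whose lower
edge is fixed by the acquisition high-pass. Resolution estimates expose
their proportionality constants (`axial = k_ax * c / BW`,
`lateral = k_lat * aperture`, defaults 0.88 and 1.25) because no standard
fixes them; they are conventions, not physics. Acoustic diffraction at the
fiber tip, which gives real devices a rippled frequency response, is not
modelled; synthetic spectra are smooth.

### Imaging (`imaging`)

The detector aperture is the fiber mode field (Gaussian, FWHM = 10.1 um
MFD). A wave arriving from angle `theta` is smeared in time by the
path-length spread across the aperture, `sigma_t = sigma_ap*sin(theta)/c` —
a Gaussian directivity low-pass — with a hard cutoff at half the measured
100 degree acceptance angle; the smearing conserves pulse area, so the peak
drops as `sigma_src/sigma`. A finite source diameter adds `d/c` of Gaussian
temporal broadening; a suture is a dense line of point sources. Scan traces
are synthesized in the frequency domain from the closed-form spectrum of
the delayed Gaussian-derivative pulse, with the detector band applied as
the magnitude response of the same zero-phase Butterworth filter: this is
alias-free even when the excitation pulse is shorter than the sample
interval (time-domain deposition of a 1.2 ns pulse on a 2 ns grid can land
on the N-wave's zero crossing and lose the source entirely). The scan-step
Nyquist check requires two samples per minimum acoustic wavelength
projected on the scan axis at the acceptance half-angle.

Reconstruction is textbook planar f-k (Stolt) migration: FFT over scan
axes and time, dispersion mapping `omega = c*sqrt(kz^2 + kperp^2)` with
evanescent components zeroed and the `d omega/d kz` Jacobian applied,
inverse FFT to image space. Implementation points that matter:

* The temporal spectrum rotates rapidly with frequency (phase ~ omega times
  arrival time), which linear interpolation onto the mapped frequencies
  cannot follow; the known rotation at the window-center reference time is
  divided out before interpolating and restored afterwards, and the time
  axis is zero-padded 4x. Without this the point-spread function develops
  spurious twin lobes (validated against a delay-and-sum oracle).
* Only the positive-frequency half is migrated, so the depth profile of the
  image is the magnitude of the analytic signal — the amplitude envelope.
* A Tukey taper (fraction 0.25) over the scan axes suppresses coherent
  edge artifacts of the hard-truncated aperture.
* SIR widths are measured on maximum-intensity projections of the envelope
  onto each axis (the same reduction used for measured SIR maps), because a
  straight slice through the peak cuts across the slightly curved envelope
  wavefront.

With the 10.1 um / 5-160 MHz detector and a fixed 1 mm scan span, the
reconstructed point source localizes within one pixel for standoffs
0.25-5 mm; the lateral FWHM grows from ~11 um at 0.25 mm to ~100 um at
5 mm (span-limited angular aperture), while the axial FWHM stays near the
band limit (~15 um). Frequency-dependent tissue attenuation, the mechanism
behind depth-dependent axial broadening in real measurements, is not
modelled.

## Synthetic-fixture conditions

The fixture layer fixes the study conditions: device parameters
`kappa = 1.4 mm^-1`, 2 mm mirror, `lambda_B = 1549 nm`, `n_eff = 1.447`,
MFD 10.1 um; spectral noise 1% of peak reflectivity (additive Gaussian,
clipped to [0, 1]); excitation pulse 1.2 ns; `c = 1.5 mm/us`; suture
phantom of 12 sutures in 5 layers at depths 0.5-4.5 mm with diameters drawn
from 30-39 um. Every stochastic path takes an explicit seed and is
bit-reproducible.

Problem sizes are scaled to desk scale: the suture raster uses a
0.8 x 0.08 mm scan at 20 um steps with a 5-30 MHz band (the 1 mm layer
spacing only requires ~44 um axial resolution), sutures 0.4 mm long at
10 um point pitch, and single-shot acquisition for the noiseless layer
test; SIR sweeps use a 1 mm span at 4 um steps. These choices keep the
full suite and the acceptance script to a few minutes while preserving
every property under test.

## Known limitations

* Polarization/birefringence of the PM fiber, apodized or chirped gratings
  and thermal drift are out of scope.
* The silver terminator is a fixed complex reflectance, not a thin-film
  stack; its phase is a declared default.
* Laser intensity/phase noise, pulse-interferometric readout and the
  high-power nonlinear regime are not modelled.
* The f-k migration stands in for the exact published inversion used for
  the original images; it is validated by localization, linearity,
  resolvability and energy-compactness properties, not against that code.
* Absolute sensitivity in mV/kPa is calibratable, not predictable: the
  elasto-optic constant, acoustic penetration profile and photodetector
  gain enter as user-supplied constants.
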