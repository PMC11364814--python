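# eersim

Modelling toolkit for **embedded etalon resonator (EER)** fiber-optic
ultrasound detectors: a pi-shifted fiber Bragg grating, polished down to a
tens-of-micrometers spacer and terminated by a thin silver mirror, forms a
high-Q optical cavity at the fiber tip whose resonance shifts under incoming
ultrasound. Such sensors combine a ~10 um acoustic aperture with >100 MHz
bandwidth — an attractive detector for optoacoustic (photoacoustic)
mesoscopy — but their fabrication and characterization lean heavily on
simulation. This package provides that desk side, for sensor designers and
optoacoustic-imaging researchers:

* **Grating optics** — coupled-mode transfer-matrix spectra of grating
  stacks `[mirror FBG | pi shift | spacer FBG | terminator]`, resonance
  extraction (center, FWHM, depth, Q) and stop-band width.
* **Fabrication guidance** — estimate the remaining spacer length while
  polishing, by fitting each measured reflection spectrum against
  simulations in which only the spacer length varies; includes a streaming
  monitor with a stop flag.
* **Transduction** — intracavity field and facet exposure, working-point
  selection on the dip flank, small-signal responsivity, NEP/NEPD
  arithmetic and the band-sectioned NEP extrapolation used when a
  calibrated hydrophone covers only part of the detection band.
* **Acoustic characterization** — synthetic optoacoustic N-wave point
  sources, zero-phase band-pass, power spectra, threshold-crossing
  bandwidth and resolution estimates.
* **Imaging** — line/raster scan simulation over point and suture phantoms
  with an aperture-directivity model, frequency-domain (f-k / Stolt)
  back-projection, spatial-impulse-response FWHM metrics and
  maximum-intensity projections.

The core relations, in the field's usual notation: a uniform grating section
has the transfer matrix of coupled-mode theory with detuning
`delta = 2*pi*n_eff*(1/lambda - 1/lambda_B)` and
`gamma = sqrt(kappa^2 - delta^2)`; a stack with tip reflectance `rho`
reflects `r = (M21 + M22 rho)/(M11 + M12 rho)`. The detector's
noise-equivalent pressure is `NEP = noise_rms / sensitivity` and its density
`NEPD = NEP / sqrt(bandwidth)`; reconstruction maps temporal frequency to
axial wavenumber through the acoustic dispersion relation
`omega = c * sqrt(kz^2 + kx^2 + ky^2)`. See `docs/methods.md` for the full
model description and its assumptions.

## Worked example

```python
import numpy as np
from eersim import *

# 1. polishing guidance: recover a spacer length from a noisy spectrum
spectrum, truth = make_spectrum_fixture(0.45, FixtureConfig(seed=7, spectral_noise=0.01))
result = fit_spacer_length(spectrum, canonical_template())
print(f"true spacer: {truth['true_spacer_mm']*1e3:.0f} um")
print(f"estimated:   {result.spacer_length*1e3:.1f} um (mismatch {result.mismatch:.2e})")

# 2. the intact device's reflection stop band
intact = EtalonStack(canonical_template().build(2.0).elements, None)
sp = stack_reflectance(intact, default_wavelength_grid())
print(f"stop band of the intact device: {stopband_width(sp):.3f} nm")

# 3. noise-equivalent pressure from a hydrophone calibration
rep = nep_report(sensitivity=145.0, noise_rms=1.78, band=(10.0, 30.0))
print(f"NEP: {rep.nep:.2f} Pa, NEPD: {rep.nepd:.2f} mPa/sqrt(Hz)")

# 4. spatial impulse response of a scanned point source
det = DetectorModel()   # 10.1 um aperture, 5-160 MHz band
geo = ScanGeometry(standoff=0.5, step=4.0, span=1.0, dt=2.0)
sino = simulate_scan(Phantom([PointSource((0.0, 0.0, 0.5))]), det, geo, SourceModel())
lateral, axial = sir_fwhm(fd_backproject(sino))
print(f"SIR at D = 0.5 mm: lateral {lateral:.1f} um, axial {axial:.1f} um")
```

prints

```
true spacer: 450 um
estimated:   445.0 um (mismatch 2.85e-04)
stop band of the intact device: 1.000 nm
NEP: 12.28 Pa, NEPD: 2.74 mPa/sqrt(Hz)
SIR at D = 0.5 mm: lateral 11.9 um, axial 15.1 um
```

The spacer estimate lands 5 um from the truth at 1% spectral noise (the
fitting method's worst case over 0.07-1.0 mm spacers is ~6 um, well inside
the 50 um precision the method needs); the 2+2 mm, kappa = 1.4 mm^-1 grating
shows its ~1 nm stop band; 1.78 mV of RMS noise against 145 mV/kPa of
sensitivity is a 12.3 Pa NEP; and the reconstructed point-source response at
0.5 mm standoff is ~12 um lateral by ~15 um axial, the lateral width growing
with standoff as the fixed scan span subtends a shrinking angle.

## Command line

The `eer` console script wraps the same pipelines:

```bash
eer fixtures spectrum --spacer-mm 0.45 --noise 0.01 --out sp.csv
eer fit-spacer --observed sp.csv --out fit.json
eer fixtures polishing-stream --start-mm 1.2 --end-mm 0.07 --steps 24 --out-dir stream/
eer monitor --spectra-dir stream/ --target-um 100 --out monitor.json
eer characterize nep --sensitivity 145 --noise-mv 1.78 --band-lo 10 --band-hi 30
eer sir --d-mm 0.5 --out sir.h5
eer image --seed 7 --out phantom.h5
```

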