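"""File formats: spectra and traces as CSV, stack configs as YAML, scan data as HDF5.

Schemas (one authoritative form per format, units in the header/attrs):

* spectrum CSV      -- columns ``wavelength_nm, reflectivity[, phase_rad]``
* trace CSV         -- columns ``t_ns, value``
* power-spectrum CSV-- columns ``f_MHz, power``
* stack YAML        -- ``elements:`` list of {type, ...} + optional ``terminator:``
* trace HDF5        -- dataset ``samples`` with attrs t0_ns, dt_ns, unit
* sinogram HDF5     -- dataset ``data`` with attrs dt_ns, t0_ns, c_mm_per_us and
                       axis datasets ``x_mm`` (and ``y_mm`` for raster scans)
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from eersim.acoustics import PowerSpectrum, PressureTrace
from eersim.grating import (
    BareSection,
    EtalonStack,
    GratingSection,
    MirrorTerminator,
    PhaseShiftElement,
    ReflectionSpectrum,
)
from eersim.imaging import Sinogram
from eersim.spacerfit import SpacerFitResult

PathLike = Union[str, Path]

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_stack_yaml",
    "write_stack_yaml",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_hdf5",
    "write_trace_hdf5",
    "read_power_spectrum_csv",
    "write_power_spectrum_csv",
    "read_sinogram_hdf5",
    "write_sinogram_hdf5",
    "write_fit_json",
]


# -- spectra ---------------------------------------------------------------


def write_spectrum_csv(path: PathLike, spectrum: ReflectionSpectrum) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "reflectivity": spectrum.reflectivity,
            "phase_rad": np.angle(spectrum.amplitude),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectrum_csv(path: PathLike) -> ReflectionSpectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    df = pd.read_csv(path)
    required = {"wavelength_nm", "reflectivity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    phase = df["phase_rad"].to_numpy() if "phase_rad" in df.columns else None
    return ReflectionSpectrum.from_reflectivity(
        df["wavelength_nm"].to_numpy(), df["reflectivity"].to_numpy(), phase
    )


# -- stacks ----------------------------------------------------------------


def _element_to_dict(el) -> dict:
    if isinstance(el, GratingSection):
        return {
            "type": "grating",
            "length_mm": el.length,
            "kappa_per_mm": el.kappa,
            "bragg_nm": el.bragg_wavelength,
            "n_eff": el.n_eff,
            "loss_per_mm": el.loss,
        }
    if isinstance(el, PhaseShiftElement):
        return {"type": "phase_shift", "phase_rad": el.phase}
    if isinstance(el, BareSection):
        return {"type": "bare", "length_mm": el.length, "n_eff": el.n_eff}
    raise TypeError(type(el).__name__)


def _element_from_dict(d: dict):
    kind = d.get("type")
    if kind == "grating":
        return GratingSection(
            length=float(d["length_mm"]),
            kappa=float(d.get("kappa_per_mm", 1.4)),
            bragg_wavelength=float(d.get("bragg_nm", 1549.0)),
            n_eff=float(d.get("n_eff", 1.447)),
            loss=float(d.get("loss_per_mm", 0.0)),
        )
    if kind == "phase_shift":
        return PhaseShiftElement(float(d.get("phase_rad", math.pi)))
    if kind == "bare":
        return BareSection(float(d["length_mm"]), float(d.get("n_eff", 1.447)))
    raise ValueError(f"unknown element type {kind!r}")


def write_stack_yaml(path: PathLike, stack: EtalonStack) -> None:
    doc = {"elements": [_element_to_dict(el) for el in stack.elements]}
    if stack.terminator is not None:
        doc["terminator"] = {
            "reflectance": stack.terminator.amplitude_reflectance,
            "phase_rad": stack.terminator.phase,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_stack_yaml(path: PathLike) -> EtalonStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    elements = [_element_from_dict(d) for d in doc["elements"]]
    terminator = None
    if "terminator" in doc and doc["terminator"] is not None:
        t = doc["terminator"]
        terminator = MirrorTerminator(
            amplitude_reflectance=float(t["reflectance"]),
            phase=float(t.get("phase_rad", math.pi)),
        )
    return EtalonStack(elements, terminator)


# -- traces ----------------------------------------------------------------


def write_trace_csv(path: PathLike, trace: PressureTrace) -> None:
    pd.DataFrame({"t_ns": trace.times, "value": trace.samples}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_trace_csv(path: PathLike, unit: str = "Pa") -> PressureTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    t = df["t_ns"].to_numpy()
    dt = float(np.median(np.diff(t)))
    return PressureTrace(t0=float(t[0]), dt=dt, samples=df["value"].to_numpy(), unit=unit)


def write_trace_hdf5(path: PathLike, trace: PressureTrace) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=trace.samples)
        ds.attrs["t0_ns"] = trace.t0
        ds.attrs["dt_ns"] = trace.dt
        ds.attrs["unit"] = trace.unit


def read_trace_hdf5(path: PathLike) -> PressureTrace:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        return PressureTrace(
            t0=float(ds.attrs["t0_ns"]),
            dt=float(ds.attrs["dt_ns"]),
            samples=ds[()],
            unit=str(ds.attrs.get("unit", "Pa")),
        )


# -- power spectra ---------------------------------------------------------


def write_power_spectrum_csv(path: PathLike, ps: PowerSpectrum) -> None:
    pd.DataFrame({"f_MHz": ps.frequencies, "power": ps.power}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_power_spectrum_csv(path: PathLike) -> PowerSpectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"power-spectrum file not found: {path}")
    df = pd.read_csv(path)
    return PowerSpectrum(df["f_MHz"].to_numpy(), df["power"].to_numpy())


# -- sinograms -------------------------------------------------------------


def write_sinogram_hdf5(path: PathLike, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=sino.data)
        ds.attrs["dt_ns"] = sino.dt
        ds.attrs["t0_ns"] = sino.t0
        ds.attrs["c_mm_per_us"] = sino.c
        f.create_dataset("x_mm", data=sino.x)
        if sino.y is not None:
            f.create_dataset("y_mm", data=sino.y)


def read_sinogram_hdf5(path: PathLike) -> Sinogram:
    with h5py.File(path, "r") as f:
        ds = f["data"]
        y = f["y_mm"][()] if "y_mm" in f else None
        return Sinogram(
            data=ds[()],
            x=f["x_mm"][()],
            dt=float(ds.attrs["dt_ns"]),
            t0=float(ds.attrs["t0_ns"]),
            y=y,
            c=float(ds.attrs["c_mm_per_us"]),
        )


# -- fit results -----------------------------------------------------------


def write_fit_json(path: PathLike, result: SpacerFitResult) -> None:
    doc = {
        "spacer_length_mm": result.spacer_length,
        "mismatch": result.mismatch,
        "converged": result.converged,
        "curve": [[float(a), float(b)] for a, b in result.curve],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
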