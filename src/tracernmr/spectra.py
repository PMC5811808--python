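"""Frequency-domain spectrum containers and their native on-disk format.

A spectrum couples a frequency axis (stored in Hz as offsets from the
carrier, with a ppm view derived from the carrier position and the
spectrometer frequency) with real intensities.  The native container is a
JSON sidecar holding axis and acquisition metadata next to a CSV of the
numeric data — deliberately plain-text so spectra diff and version cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum1D", "Spectrum2D", "save_spectrum", "load_spectrum"]


@dataclass
class Axis:
    """One frequency axis: offsets from the carrier plus ppm calibration."""

    hz: np.ndarray  # offsets from carrier, strictly increasing
    nucleus: str  # "1H", "13C" or "15N"
    carrier_ppm: float
    field_mhz: float  # spectrometer frequency of this nucleus

    def __post_init__(self) -> None:
        self.hz = np.asarray(self.hz, dtype=float)
        if self.hz.ndim != 1 or len(self.hz) < 2:
            raise ValueError("axis needs at least two points")
        if not np.all(np.diff(self.hz) > 0):
            raise ValueError("axis must be strictly increasing in Hz")

    @property
    def ppm(self) -> np.ndarray:
        return self.carrier_ppm + self.hz / self.field_mhz

    @property
    def step_hz(self) -> float:
        return float(self.hz[1] - self.hz[0])

    def to_dict(self) -> dict:
        return {
            "nucleus": self.nucleus,
            "carrier_ppm": self.carrier_ppm,
            "field_mhz": self.field_mhz,
            "hz_start": float(self.hz[0]),
            "hz_step": self.step_hz,
            "n": int(len(self.hz)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Axis":
        hz = d["hz_start"] + d["hz_step"] * np.arange(d["n"])
        return cls(hz, d["nucleus"], d["carrier_ppm"], d["field_mhz"])


@dataclass
class Spectrum1D:
    """A 1D real spectrum on a uniform frequency grid."""

    axis: Axis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.hz.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axis "
                f"length {len(self.axis.hz)}"
            )

    @property
    def hz(self) -> np.ndarray:
        return self.axis.hz

    @property
    def ppm(self) -> np.ndarray:
        return self.axis.ppm

    def integral(self) -> float:
        """Trapezoidal integral over the full axis, in intensity·Hz."""
        return float(np.trapezoid(self.intensity, self.axis.hz))

    def same_axis(self, other: "Spectrum1D", tol: float = 1e-9) -> bool:
        return self.axis.hz.shape == other.axis.hz.shape and np.allclose(
            self.axis.hz, other.axis.hz, atol=tol
        )

    def __add__(self, other: "Spectrum1D") -> "Spectrum1D":
        if not self.same_axis(other):
            raise ValueError("cannot add spectra on different axes")
        return Spectrum1D(self.axis, self.intensity + other.intensity, dict(self.meta))

    def scaled(self, factor: float) -> "Spectrum1D":
        return Spectrum1D(self.axis, self.intensity * factor, dict(self.meta))


@dataclass
class Spectrum2D:
    """A 2D real spectrum; intensity indexed [f1, f2] (indirect, direct)."""

    f1_axis: Axis
    f2_axis: Axis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expect = (len(self.f1_axis.hz), len(self.f2_axis.hz))
        if self.intensity.shape != expect:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes {expect}"
            )

    def __add__(self, other: "Spectrum2D") -> "Spectrum2D":
        if self.intensity.shape != other.intensity.shape or not (
            np.allclose(self.f1_axis.hz, other.f1_axis.hz)
            and np.allclose(self.f2_axis.hz, other.f2_axis.hz)
        ):
            raise ValueError("cannot add 2D spectra on different axes")
        return Spectrum2D(
            self.f1_axis, self.f2_axis, self.intensity + other.intensity, dict(self.meta)
        )

    def scaled(self, factor: float) -> "Spectrum2D":
        return Spectrum2D(self.f1_axis, self.f2_axis, self.intensity * factor, dict(self.meta))


# ---------------------------------------------------------------------------
# Native container: <stem>.json (metadata) + <stem>.csv (numbers)
# ---------------------------------------------------------------------------


def save_spectrum(spec: Spectrum1D | Spectrum2D, stem: str | Path) -> tuple[Path, Path]:
    """Write a spectrum as ``<stem>.json`` + ``<stem>.csv``; return both paths."""
    stem = Path(stem)
    json_path = stem.with_suffix(".json")
    csv_path = stem.with_suffix(".csv")
    if isinstance(spec, Spectrum1D):
        meta = {"kind": "spectrum1d", "axis": spec.axis.to_dict(), "meta": spec.meta}
        data = np.column_stack([spec.axis.hz, spec.intensity])
        header = "hz,intensity"
        np.savetxt(csv_path, data, delimiter=",", header=header, comments="")
    else:
        meta = {
            "kind": "spectrum2d",
            "f1_axis": spec.f1_axis.to_dict(),
            "f2_axis": spec.f2_axis.to_dict(),
            "meta": spec.meta,
        }
        np.savetxt(csv_path, spec.intensity, delimiter=",")
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return json_path, csv_path


def load_spectrum(stem: str | Path) -> Spectrum1D | Spectrum2D:
    """Read back a spectrum written by :func:`save_spectrum`."""
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if meta["kind"] == "spectrum1d":
        data = np.loadtxt(stem.with_suffix(".csv"), delimiter=",", skiprows=1)
        axis = Axis.from_dict(meta["axis"])
        return Spectrum1D(axis, data[:, 1], meta.get("meta", {}))
    if meta["kind"] == "spectrum2d":
        intensity = np.loadtxt(stem.with_suffix(".csv"), delimiter=",")
        return Spectrum2D(
            Axis.from_dict(meta["f1_axis"]),
            Axis.from_dict(meta["f2_axis"]),
            intensity,
            meta.get("meta", {}),
        )
    raise ValueError(f"unknown spectrum kind {meta['kind']!r}")


def load_trace_csv(path: str | Path, nucleus: str = "13C",
                   carrier_ppm: float = 0.0, field_mhz: float = 150.9) -> Spectrum1D:
    """Read a bare two-column (Hz, intensity) CSV as a :class:`Spectrum1D`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    axis = Axis(data[:, 0], nucleus, carrier_ppm, field_mhz)
    return Spectrum1D(axis, data[:, 1])
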