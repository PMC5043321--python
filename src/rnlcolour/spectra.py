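"""Spectra as wavelength-value tables with explicit unit roles.

Every quantity in the colour model is a function of wavelength sampled on a
grid: radiances of stimuli and backgrounds, transmittances of ocular media
and oil droplets, and receptor sensitivities.  This module defines the
:class:`Spectrum` container, delimited-text I/O, resampling, and the
energy-to-quanta conversion that turns radiometer output (power units) into
the photon-flux units the quantum-catch integral requires.

Conventions used package-wide:

* the canonical wavelength grid is 300-700 nm at 1 nm steps (avian visual
  range; all catch integrals run over these bounds);
* all integrals use the trapezoid rule on the spectrum's grid;
* cross-spectrum operations resample both operands to the coarser common
  grid before combining.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "UNIT_ROLES",
    "DEFAULT_GRID",
    "default_grid",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "energy_to_quanta",
    "quanta_to_energy",
    "mean_spectra",
    "common_grid",
]

#: Planck constant (J s) and speed of light (m/s), CODATA 2018 exact values.
PLANCK_H = 6.62607015e-34
SPEED_OF_LIGHT = 2.99792458e8

#: Recognised unit roles and whether their values are bounded to [0, 1].
UNIT_ROLES = {
    "energy_radiance": False,   # µW cm^-2 nm^-1 sr^-1
    "quantum_radiance": False,  # quanta s^-1 cm^-2 nm^-1 sr^-1
    "transmittance": True,
    "reflectance": True,
    "sensitivity": False,       # relative, non-negative
}

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)


def default_grid() -> np.ndarray:
    """Return a copy of the canonical 300-700 nm, 1 nm wavelength grid."""
    return DEFAULT_GRID.copy()


class SpectrumError(ValueError):
    """Raised for malformed or physically invalid spectral data."""


class UnitRoleError(SpectrumError):
    """Raised when an operation receives a spectrum with the wrong unit role."""


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A sampled spectral function with a declared unit role.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    values
        Non-negative sample values, one per wavelength.
    unit_role
        One of ``energy_radiance``, ``quantum_radiance``, ``transmittance``,
        ``reflectance`` or ``sensitivity``.  Bounded roles (transmittance,
        reflectance) must lie in [0, 1].
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit_role: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.unit_role not in UNIT_ROLES:
            raise UnitRoleError(
                f"unknown unit role {self.unit_role!r}; "
                f"expected one of {sorted(UNIT_ROLES)}"
            )
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 1:
            raise SpectrumError("a spectrum needs at least one sample")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumError("non-finite entries in spectrum")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if np.any(vals < 0):
            raise SpectrumError(f"negative values not allowed for {self.unit_role}")
        if UNIT_ROLES[self.unit_role] and np.any(vals > 1.0 + 1e-12):
            raise SpectrumError(f"{self.unit_role} values must lie in [0, 1]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (self.unit_role == other.unit_role
                and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
                and np.array_equal(self.values, other.values))

    __hash__ = None

    # -- basic algebra ----------------------------------------------------
    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with values multiplied by a non-negative factor."""
        if factor < 0:
            raise SpectrumError("scale factor must be non-negative")
        return Spectrum(self.wavelengths_nm, self.values * factor,
                        self.unit_role, self.name)

    def integral(self) -> float:
        """Trapezoid integral of the spectrum over its own grid."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def to_json(self) -> str:
        """Serialise to a JSON document carrying the unit-role tag."""
        return json.dumps({
            "unit_role": self.unit_role,
            "name": self.name,
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "values": self.values.tolist(),
        })

    @classmethod
    def from_json(cls, doc: str) -> "Spectrum":
        d = json.loads(doc)
        return cls(np.asarray(d["wavelengths_nm"]), np.asarray(d["values"]),
                   d["unit_role"], d.get("name", ""))


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_spectrum(path: str | Path | io.StringIO, unit_role: str,
                  value_column: int = 1, name: str = "") -> Spectrum:
    """Read a delimited-text spectrum (wavelength column + value columns).

    Accepts comma- or tab-separated files, ``#`` comment lines and an
    optional single header row.  ``value_column`` selects among multiple
    value columns (1 = first value column).
    """
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
        src = "<buffer>"
    else:
        src = str(path)
        lines = Path(path).read_text().splitlines()
    wl: list[float] = []
    vals: list[float] = []
    delim = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < value_column + 1:
            raise SpectrumError(
                f"{src}:{lineno}: expected at least {value_column + 1} columns, "
                f"got {len(parts)}")
        try:
            w = float(parts[0])
            v = float(parts[value_column])
        except ValueError:
            if not wl:  # tolerate one header row
                continue
            raise SpectrumError(f"{src}:{lineno}: cannot parse {line!r}") from None
        wl.append(w)
        vals.append(v)
    if len(wl) < 2:
        raise SpectrumError(f"{src}: fewer than two data rows")
    if not name and not isinstance(path, io.StringIO):
        name = Path(path).stem
    return Spectrum(np.asarray(wl), np.asarray(vals), unit_role, name)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV (full float precision, round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(f"# unit_role: {spec.unit_role}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spec.wavelengths_nm, spec.values):
            fh.write(f"{float(w)!r},{float(v)!r}\n")


def resample(spec: Spectrum, grid: Sequence[float] | np.ndarray,
             fill: float | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Extrapolation is forbidden unless a ``fill`` value is supplied for
    out-of-range points.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.wavelengths_nm[0], spec.wavelengths_nm[-1]
    outside = (grid < lo) | (grid > hi)
    if outside.any() and fill is None:
        raise SpectrumError(
            f"grid extends outside data range [{lo}, {hi}] nm; "
            "pass fill= to permit")
    vals = np.interp(grid, spec.wavelengths_nm, spec.values)
    if fill is not None:
        vals = np.where(outside, fill, vals)
    return Spectrum(grid, vals, spec.unit_role, spec.name)


def common_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Coarser of the two grids, restricted to the overlapping range."""
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    if hi <= lo:
        raise SpectrumError("spectra have disjoint wavelength ranges")
    step_a = np.min(np.diff(a.wavelengths_nm))
    step_b = np.min(np.diff(b.wavelengths_nm))
    coarse = a if step_a >= step_b else b
    g = coarse.wavelengths_nm
    return g[(g >= lo) & (g <= hi)]


def energy_to_quanta(spec: Spectrum) -> Spectrum:
    """Convert energy radiance (µW cm^-2 nm^-1 sr^-1) to photon flux.

    A photon at wavelength λ carries hc/λ joules, so spectral power P(λ)
    corresponds to P(λ)·λ/(hc) photons per second.  The µW prefix is folded
    in (1 µW = 1e-6 W); output units are quanta s^-1 cm^-2 nm^-1 sr^-1.
    """
    if spec.unit_role != "energy_radiance":
        raise UnitRoleError(
            f"energy_to_quanta needs energy_radiance, got {spec.unit_role}")
    lam_m = spec.wavelengths_nm * 1e-9
    quanta = spec.values * 1e-6 * lam_m / (PLANCK_H * SPEED_OF_LIGHT)
    return Spectrum(spec.wavelengths_nm, quanta, "quantum_radiance", spec.name)


def quanta_to_energy(spec: Spectrum) -> Spectrum:
    """Inverse of :func:`energy_to_quanta`."""
    if spec.unit_role != "quantum_radiance":
        raise UnitRoleError(
            f"quanta_to_energy needs quantum_radiance, got {spec.unit_role}")
    lam_m = spec.wavelengths_nm * 1e-9
    energy = spec.values * (PLANCK_H * SPEED_OF_LIGHT) / lam_m * 1e6
    return Spectrum(spec.wavelengths_nm, energy, "energy_radiance", spec.name)


def mean_spectra(specs: Iterable[Spectrum]) -> Spectrum:
    """Plain arithmetic mean of spectra sharing a unit role.

    Measurement protocols often average radiance over repeated readings or
    viewing angles; absent stated weights this utility takes the unweighted
    mean on the coarsest common grid.
    """
    specs = list(specs)
    if not specs:
        raise SpectrumError("need at least one spectrum")
    role = specs[0].unit_role
    if any(s.unit_role != role for s in specs):
        raise UnitRoleError("cannot average spectra with mixed unit roles")
    grid = specs[0].wavelengths_nm
    for s in specs[1:]:
        grid = common_grid(Spectrum(grid, np.zeros_like(grid), role), s)
    stack = np.stack([resample(s, grid).values for s in specs])
    return Spectrum(grid, stack.mean(axis=0), role, "mean")
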