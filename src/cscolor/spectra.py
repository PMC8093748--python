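"""Reflectance spectra and the spectral tables used by the color conversions.

A :class:`Spectrum` is the primary physical measurement in this package: a
wavelength-indexed reflectance curve, as produced by a field or museum
spectrometer.  :class:`Illuminant` and :class:`ObserverCMF` are the two fixed
ingredients of the spectrum → tristimulus conversion; the package ships the
CIE standard illuminant D65 and the CIE 1931 2° observer as 5-nm CSV
resources, linearly interpolated onto finer grids as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Illuminant",
    "ObserverCMF",
    "resample_spectrum",
    "d65",
    "flat_illuminant",
    "cie1931_2deg",
    "read_spectra_csv",
    "write_spectra_csv",
]

_WAVELENGTH_MIN = 300.0
_WAVELENGTH_MAX = 2500.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A reflectance spectrum on a strictly increasing wavelength grid (nm).

    Reflectance is a dimensionless fraction; values above 1 (specular/gloss
    artifacts) are accepted but flagged via :attr:`exceeds_unity`.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        refl = _as_float_array(self.reflectance, "reflectance")
        if wl.size != refl.size:
            raise ValueError("wavelengths and reflectance must have equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _WAVELENGTH_MIN or wl[-1] > _WAVELENGTH_MAX:
            raise ValueError(
                f"wavelengths must lie within [{_WAVELENGTH_MIN:g}, {_WAVELENGTH_MAX:g}] nm"
            )
        if np.any(refl < 0):
            raise ValueError("reflectance must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    @property
    def exceeds_unity(self) -> bool:
        """True when any reflectance value is above 1 (flagged, not clamped)."""
        return bool(np.any(self.reflectance > 1.0))

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of reflectance onto ``grid`` (no extrapolation check)."""
        return np.interp(grid, self.wavelengths, self.reflectance)


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution of a light source."""

    wavelengths: np.ndarray
    power: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        power = _as_float_array(self.power, "power")
        if wl.size != power.size:
            raise ValueError("wavelengths and power must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("spectral power must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "power", power)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.power)


@dataclass(frozen=True)
class ObserverCMF:
    """Color matching functions (x̄, ȳ, z̄) of a standard observer."""

    wavelengths: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        bars = []
        for attr in ("xbar", "ybar", "zbar"):
            b = _as_float_array(getattr(self, attr), attr)
            if b.size != wl.size:
                raise ValueError(f"{attr} must match wavelengths in length")
            if np.any(b < 0):
                raise ValueError(f"{attr} must be non-negative")
            bars.append(b)
        if np.trapezoid(bars[1], wl) <= 0:
            raise ValueError("ybar must have positive area")
        object.__setattr__(self, "wavelengths", wl)
        for attr, b in zip(("xbar", "ybar", "zbar"), bars):
            object.__setattr__(self, attr, b)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Interpolate all three curves onto ``grid``; returns shape (3, n)."""
        return np.vstack(
            [np.interp(grid, self.wavelengths, b) for b in (self.xbar, self.ybar, self.zbar)]
        )


def resample_spectrum(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The grid must lie inside the spectrum's support; extrapolation is refused
    with an error naming the offending range.
    """
    grid = _as_float_array(np.asarray(grid, dtype=float), "grid")
    lo, hi = s.support
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            "resample grid requests extrapolation: grid spans "
            f"[{grid.min():g}, {grid.max():g}] nm but spectrum covers [{lo:g}, {hi:g}] nm"
        )
    return Spectrum(grid, s.interp(grid))


def _load_resource(filename: str) -> pd.DataFrame:
    with resources.files("cscolor.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh)


_CACHE: dict[str, object] = {}


def d65() -> Illuminant:
    """CIE standard illuminant D65, 300–780 nm at 5 nm."""
    if "d65" not in _CACHE:
        tbl = _load_resource("illuminant_d65_5nm.csv")
        _CACHE["d65"] = Illuminant(tbl["wavelength_nm"], tbl["power"], name="D65")
    return _CACHE["d65"]  # type: ignore[return-value]


def flat_illuminant(lo: float = 300.0, hi: float = 800.0) -> Illuminant:
    """Ideal equal-energy illuminant (constant power) over [lo, hi] nm."""
    wl = np.array([lo, hi])
    return Illuminant(wl, np.ones(2), name="flat")


def cie1931_2deg() -> ObserverCMF:
    """CIE 1931 2° standard observer, 380–780 nm at 5 nm."""
    if "cmf" not in _CACHE:
        tbl = _load_resource("cie1931_2deg_5nm.csv")
        _CACHE["cmf"] = ObserverCMF(
            tbl["wavelength_nm"], tbl["xbar"], tbl["ybar"], tbl["zbar"], name="CIE 1931 2deg"
        )
    return _CACHE["cmf"]  # type: ignore[return-value]


def read_spectra_csv(path) -> dict[str, Spectrum]:
    """Read spectra from CSV.

    Accepts either a two-column file ``wavelength_nm,reflectance`` (one
    spectrum, keyed ``"spectrum"``) or a long format with a ``sample_id``
    column holding several spectra.
    """
    tbl = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "reflectance"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"spectra CSV needs columns {sorted(required)}")
    if "sample_id" in tbl.columns:
        out = {}
        for sid, sub in tbl.groupby("sample_id", sort=False):
            sub = sub.sort_values("wavelength_nm")
            out[str(sid)] = Spectrum(sub["wavelength_nm"], sub["reflectance"])
        return out
    tbl = tbl.sort_values("wavelength_nm")
    return {"spectrum": Spectrum(tbl["wavelength_nm"], tbl["reflectance"])}


def write_spectra_csv(spectra: dict[str, Spectrum], path) -> None:
    """Write spectra to long-format CSV (``sample_id,wavelength_nm,reflectance``)."""
    frames = [
        pd.DataFrame(
            {"sample_id": sid, "wavelength_nm": s.wavelengths, "reflectance": s.reflectance}
        )
        for sid, s in spectra.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
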