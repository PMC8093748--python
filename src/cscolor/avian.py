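"""Avian color vision: receptor quantum catches and tetrahedral color space.

Birds have four single-cone classes (UV/violet ``u``, short ``s``, medium
``m``, long ``l``) plus a double cone ``d`` that drives achromatic vision.
Relative single-cone catches place a stimulus inside a regular tetrahedron
whose vertices correspond to exclusive stimulation of one cone class; the
chromatic coordinates are (x, y, z) and the achromatic signal is
``DL = ln(double-cone catch)``.

Two eye types are supported: U-type (UVS, λmax of the u cone ≈ 370 nm) and
V-type (VS, ≈ 410 nm).  Cone sensitivity curves are generated as log-normal
pigment templates with field-typical λmax values and can be replaced by
measured curves loaded from CSV.  Catches default to an ideal equal-energy
illuminant, appropriate for illumination-standardized museum spectrometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorimetry import spectrum_to_rgb8
from .spectra import Illuminant, Spectrum, flat_illuminant

__all__ = [
    "CONE_LAMBDA_MAX",
    "ConeSet",
    "QuantumCatch",
    "TetraPoint",
    "cone_templates",
    "read_cone_csv",
    "quantum_catch",
    "tetra_coordinates",
    "uv_contrast_demo",
    "TETRA_VERTICES",
]

#: Peak sensitivities (nm) of the log-normal cone templates per eye type.
CONE_LAMBDA_MAX = {
    "U": {"u": 370.0, "s": 445.0, "m": 508.0, "l": 565.0, "d": 565.0},
    "V": {"u": 410.0, "s": 445.0, "m": 508.0, "l": 565.0, "d": 565.0},
}

_CONE_ORDER = ("u", "s", "m", "l", "d")


@dataclass(frozen=True)
class ConeSet:
    """Wavelength-indexed spectral sensitivities for one avian eye type.

    Each curve is normalized to unit area on its grid, so a flat spectrum
    under a flat illuminant stimulates all cones equally.
    """

    eye_type: str
    wavelengths: np.ndarray
    sensitivities: np.ndarray  # shape (5, n), rows ordered u, s, m, l, d

    def __post_init__(self):
        if self.eye_type not in ("U", "V"):
            raise ValueError("eye_type must be 'U' or 'V'")
        wl = np.asarray(self.wavelengths, dtype=float)
        sens = np.asarray(self.sensitivities, dtype=float)
        if sens.shape != (5, wl.size):
            raise ValueError("sensitivities must have shape (5, len(wavelengths))")
        if np.any(sens < 0):
            raise ValueError("sensitivities must be non-negative")
        areas = np.trapezoid(sens, wl, axis=1)
        if np.any(areas <= 0):
            raise ValueError("each sensitivity curve must have positive area")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivities", sens / areas[:, None])

    def curve(self, cone: str) -> np.ndarray:
        return self.sensitivities[_CONE_ORDER.index(cone)]


def cone_templates(
    eye_type: str = "U",
    wavelengths: np.ndarray | None = None,
    log_width: float = 0.06,
) -> ConeSet:
    """Generate a :class:`ConeSet` from log-normal pigment templates.

    ``R_i(λ) ∝ exp(−ln²(λ/λmax_i) / (2 w²))`` with ``w`` the log-bandwidth
    (default 0.06, giving full widths near 90 nm for the long cone).
    """
    if eye_type not in CONE_LAMBDA_MAX:
        raise ValueError("eye_type must be 'U' or 'V'")
    wl = np.arange(300.0, 701.0) if wavelengths is None else np.asarray(wavelengths, float)
    lmax = CONE_LAMBDA_MAX[eye_type]
    sens = np.vstack(
        [np.exp(-np.log(wl / lmax[c]) ** 2 / (2.0 * log_width**2)) for c in _CONE_ORDER]
    )
    return ConeSet(eye_type, wl, sens)


def read_cone_csv(path, eye_type: str) -> ConeSet:
    """Load measured cone sensitivities from CSV ``wavelength_nm,u,s,m,l,d``."""
    tbl = pd.read_csv(path, comment="#")
    if "eye_type" in tbl.columns:
        tbl = tbl[tbl["eye_type"] == eye_type]
        if tbl.empty:
            raise ValueError(f"no rows with eye_type={eye_type!r}")
    tbl = tbl.sort_values("wavelength_nm")
    sens = np.vstack([tbl[c].to_numpy(float) for c in _CONE_ORDER])
    return ConeSet(eye_type, tbl["wavelength_nm"].to_numpy(float), sens)


@dataclass(frozen=True)
class QuantumCatch:
    """Photon catches per receptor and relative single-cone catches."""

    Qu: float
    Qs: float
    Qm: float
    Ql: float
    Qd: float
    #: True when the stimulus spectrum did not cover the UV band (support
    #: starting above 320 nm) so the u catch is extrapolation-free but partial.
    uv_coverage_warning: bool = False

    @property
    def single(self) -> np.ndarray:
        return np.array([self.Qu, self.Qs, self.Qm, self.Ql])

    @property
    def relative(self) -> np.ndarray:
        """Relative catches (qu, qs, qm, ql), summing to 1."""
        total = self.single.sum()
        if total <= 0:
            raise ValueError("relative catches undefined: total single-cone catch is zero")
        return self.single / total


def quantum_catch(
    s: Spectrum, ill: Illuminant | None = None, cones: ConeSet | None = None
) -> QuantumCatch:
    """Integrate receptor quantum catches ``Q_i = Σ s·I·R_i Δλ``.

    The illuminant defaults to ideal flat (equal-energy); cones default to
    the U-type template set.  Integration runs on a 1-nm grid over the
    intersection of the supports.  A spectrum whose support starts above
    320 nm triggers a UV-coverage warning flag rather than an error.
    """
    ill = flat_illuminant() if ill is None else ill
    cones = cone_templates("U") if cones is None else cones
    lo = max(s.support[0], ill.support[0], cones.wavelengths[0])
    hi = min(s.support[1], ill.support[1], cones.wavelengths[-1])
    if hi - lo < 100.0:
        raise ValueError(
            f"insufficient spectral overlap for quantum catches: [{lo:g}, {hi:g}] nm"
        )
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    refl = s.interp(grid)
    power = ill.interp(grid)
    sens = np.vstack([np.interp(grid, cones.wavelengths, c) for c in cones.sensitivities])
    q = np.trapezoid(refl * power * sens, grid, axis=1)
    return QuantumCatch(*q, uv_coverage_warning=bool(s.support[0] > 320.0))


# Regular tetrahedron with circumradius 0.75 (max-chroma convention).
# The u vertex lies on the +x axis, so x isolates relative UV/violet-cone
# stimulation: x = qu - 1/4.  Vertices are assigned to u, s, m, l in order.
TETRA_VERTICES = 0.75 * np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0 / 3.0, 2.0 * np.sqrt(2.0) / 3.0, 0.0],
        [-1.0 / 3.0, -np.sqrt(2.0) / 3.0, np.sqrt(6.0) / 3.0],
        [-1.0 / 3.0, -np.sqrt(2.0) / 3.0, -np.sqrt(6.0) / 3.0],
    ]
)


@dataclass(frozen=True)
class TetraPoint:
    """A stimulus in avian tetrahedral space plus the achromatic channel."""

    x: float
    y: float
    z: float
    DL: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def tetra_coordinates(q: QuantumCatch) -> TetraPoint:
    """Map relative catches to tetrahedral coordinates; ``DL = ln(Qd)``.

    The point is the catch-weighted average of the four vertices, so equal
    catches land at the origin and a pure single-cone stimulus at a vertex
    (norm 0.75).
    """
    rel = q.relative
    if abs(rel.sum() - 1.0) > 1e-9:
        raise ValueError("relative catches must sum to 1")
    point = rel @ TETRA_VERTICES
    if q.Qd <= 0:
        raise ValueError("double-cone catch must be positive for DL = ln(Qd)")
    return TetraPoint(float(point[0]), float(point[1]), float(point[2]), float(np.log(q.Qd)))


@dataclass(frozen=True)
class UVContrastReport:
    """sRGB vs avian-x separation of two spectra that differ only in the UV."""

    rgb_distance: float
    x_distance: float
    rgb_1: np.ndarray
    rgb_2: np.ndarray
    x_1: float
    x_2: float


def uv_contrast_demo(
    s1: Spectrum, s2: Spectrum, cones: ConeSet | None = None, tol: float = 1e-9
) -> UVContrastReport:
    """Demonstrate camera UV-blindness on a pair of spectra.

    The spectra must be identical above 400 nm (checked; differing visible
    bands are an invalid demo input).  Returns the Euclidean sRGB distance —
    expected ≈ 0, since consumer-camera channels carry no UV — and the
    avian tetrahedral x separation, expected > 0 for a UV-capable eye.
    """
    cones = cone_templates("U") if cones is None else cones
    lo = max(400.0, s1.support[0], s2.support[0])
    hi = min(s1.support[1], s2.support[1])
    grid = np.arange(lo, hi + 0.5)
    if np.max(np.abs(s1.interp(grid) - s2.interp(grid))) > tol:
        raise ValueError("invalid demo input: spectra differ above 400 nm")
    rgb1 = spectrum_to_rgb8(s1).rgb
    rgb2 = spectrum_to_rgb8(s2).rgb
    t1 = tetra_coordinates(quantum_catch(s1, cones=cones))
    t2 = tetra_coordinates(quantum_catch(s2, cones=cones))
    return UVContrastReport(
        rgb_distance=float(np.linalg.norm(rgb1 - rgb2)),
        x_distance=float(abs(t1.x - t2.x)),
        rgb_1=rgb1,
        rgb_2=rgb2,
        x_1=t1.x,
        x_2=t2.x,
    )
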