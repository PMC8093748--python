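"""Color-space conversions: reflectance spectrum → XYZ → sRGB, and RGB → HSV / CIE-LAB.

The conversion chain mirrors standard colorimetric practice: tristimulus
integration of reflectance × illuminant × observer curves on a common 1-nm
grid (trapezoidal rule), the IEC sRGB 3×3 matrix and transfer curve, and
CIE-LAB with the D65 reference white.  All RGB values are on the 8-bit 0–255
scale used by photographs; out-of-gamut tristimulus values are clipped and
flagged rather than gamut-mapped, which is what a consumer camera pipeline
does.

Functions are vectorized: color arguments are arrays of shape ``(..., 3)``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from matplotlib import colors as _mcolors

from .spectra import Illuminant, ObserverCMF, Spectrum, cie1931_2deg, d65

__all__ = [
    "D65_WHITE",
    "XYZConversion",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "srgb_to_xyz",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_lab",
    "xyz_to_lab",
    "spectrum_to_rgb8",
]

# sRGB / D65 primaries (IEC 61966-2-1 derivation, 7 decimals).
_M_XYZ_TO_RGB = np.array(
    [
        [3.2404542, -1.5371385, -0.4985314],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0556434, -0.2040259, 1.0572252],
    ]
)
_M_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: D65 reference white (Y normalized to 1), the white point of sRGB and of
#: the Lab conversion here.
D65_WHITE = np.array([0.95047, 1.00000, 1.08883])


class XYZConversion(NamedTuple):
    """Result of a tristimulus integration (white-relative, Y of white = 1)."""

    xyz: np.ndarray
    #: True when the source reflectance exceeded 1 somewhere (gloss artifact).
    reflectance_flagged: bool


def _integration_grid(s: Spectrum, ill: Illuminant, cmf: ObserverCMF) -> np.ndarray:
    lo = max(s.support[0], ill.support[0], cmf.support[0])
    hi = min(s.support[1], ill.support[1], cmf.support[1])
    # The visible-band integral needs the supports to overlap at least over
    # 380-760 nm (the CMFs vanish outside 380-780).
    if lo > 380.0 or hi < 760.0:
        raise ValueError(
            "insufficient spectral overlap for tristimulus integration: common "
            f"support is [{lo:g}, {hi:g}] nm, need at least [380, 760] nm"
        )
    return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


def spectrum_to_xyz(
    s: Spectrum, ill: Illuminant | None = None, cmf: ObserverCMF | None = None
) -> XYZConversion:
    """Integrate a reflectance spectrum to CIE XYZ tristimulus values.

    ``X = k Σ s·I·x̄ Δλ`` (likewise Y, Z) with ``k = 1 / Σ I·ȳ Δλ``, evaluated
    by the trapezoidal rule on a common 1-nm grid over the intersection of
    the three supports.  Defaults: illuminant D65, CIE 1931 2° observer —
    a perfect white reflector then maps to the D65 white point.
    """
    ill = d65() if ill is None else ill
    cmf = cie1931_2deg() if cmf is None else cmf
    grid = _integration_grid(s, ill, cmf)
    refl = s.interp(grid)
    power = ill.interp(grid)
    bars = cmf.interp(grid)
    k = 1.0 / np.trapezoid(power * bars[1], grid)
    xyz = np.array([k * np.trapezoid(refl * power * b, grid) for b in bars])
    return XYZConversion(xyz, bool(np.any(s.reflectance > 1.0)))


def _srgb_encode(linear: np.ndarray) -> np.ndarray:
    """sRGB transfer curve on linear values in [0, 1]."""
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(np.clip(linear, 0.0031308, None), 1.0 / 2.4) - 0.055,
    )


def _srgb_decode(encoded: np.ndarray) -> np.ndarray:
    encoded = np.asarray(encoded, dtype=float)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        np.power(np.clip((encoded + 0.055) / 1.055, 0.0, None), 2.4),
    )


class SRGBConversion(NamedTuple):
    rgb: np.ndarray
    #: True where any pre-clip linear channel fell outside [0, 1].
    clipped: np.ndarray


def xyz_to_srgb(xyz) -> SRGBConversion:
    """XYZ → 8-bit sRGB with clip-and-flag out-of-gamut handling.

    Returns real-valued channels in [0, 255] plus a boolean ``clipped`` flag
    per color (True when any linear channel was outside [0, 1] before
    clipping — either out-of-gamut chromaticity or over-range luminance).
    """
    xyz = np.asarray(xyz, dtype=float)
    linear = xyz @ _M_XYZ_TO_RGB.T
    # Sub-LSB overshoots (matrix rounding at the white point) are not
    # meaningful clipping; flag only deviations visible at 8-bit precision.
    clipped = np.any((linear < -1e-4) | (linear > 1.0 + 1e-4), axis=-1)
    linear = np.clip(linear, 0.0, 1.0)
    rgb = 255.0 * _srgb_encode(linear)
    return SRGBConversion(np.clip(rgb, 0.0, 255.0), clipped)


def srgb_to_xyz(rgb8) -> np.ndarray:
    """8-bit sRGB → XYZ (inverse of :func:`xyz_to_srgb` inside the gamut)."""
    rgb8 = np.asarray(rgb8, dtype=float)
    linear = _srgb_decode(rgb8 / 255.0)
    return linear @ _M_RGB_TO_XYZ.T


def rgb_to_hsv(rgb8) -> np.ndarray:
    """8-bit RGB → HSV with hue in degrees [0, 360), S and V in [0, 1].

    Standard hexcone formulas; achromatic colors (S = 0) take the
    conventional sentinel hue H = 0.
    """
    rgb8 = np.asarray(rgb8, dtype=float)
    # hue/saturation are undefined outside the cube; clamp over-range values
    hsv = _mcolors.rgb_to_hsv(np.clip(rgb8 / 255.0, 0.0, 1.0))
    hsv = np.asarray(hsv, dtype=float)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def hsv_to_rgb(hsv) -> np.ndarray:
    """HSV (degrees, fractions) → 8-bit RGB (real-valued)."""
    hsv = np.array(hsv, dtype=float, copy=True)
    hsv[..., 0] = (hsv[..., 0] % 360.0) / 360.0
    return np.asarray(_mcolors.hsv_to_rgb(hsv), dtype=float) * 255.0


_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white: np.ndarray | None = None) -> np.ndarray:
    """XYZ → CIE-LAB against the D65 reference white (cube-root with linear toe)."""
    white = D65_WHITE if white is None else np.asarray(white, dtype=float)
    xyz = np.asarray(xyz, dtype=float)
    f = _lab_f(xyz / white)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def rgb_to_lab(rgb8) -> np.ndarray:
    """8-bit sRGB → CIE-LAB (D65, 2° observer), via linear RGB and XYZ."""
    return xyz_to_lab(srgb_to_xyz(rgb8))


def spectrum_to_rgb8(
    s: Spectrum, ill: Illuminant | None = None, cmf: ObserverCMF | None = None
) -> SRGBConversion:
    """Convenience: reflectance spectrum straight to 8-bit sRGB under D65."""
    return xyz_to_srgb(spectrum_to_xyz(s, ill, cmf).xyz)
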