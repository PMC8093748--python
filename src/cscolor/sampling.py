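"""The photo measurement model: ROI point sampling, aggregation, filtering.

Photograph color is measured as a small number of random points (default 3)
inside a region of interest (ROI) — one patch per photo, patterned or not.
Points are averaged to a per-photo value, photos to a per-unit value (unit =
species for the bird analysis, treatment for the plant analysis), in each of
the three working color spaces (RGB, HSV, Lab).  Quality filtering mirrors
the star ratings of photo archives; saturation screening flags units whose
channel values pile up at the 8-bit ceiling.

Tables are long-format :class:`pandas.DataFrame` objects with columns
``photo_id, unit_id, point, R, G, B`` plus optional covariates
(``quality, color_family, patterned, specimen_age, treatment``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorimetry import rgb_to_hsv, rgb_to_lab

__all__ = [
    "sample_roi_points",
    "aggregate_points",
    "aggregate_photos",
    "aggregate",
    "filter_quality",
    "detect_saturation",
    "circular_mean_deg",
    "POINT_COLUMNS",
]

POINT_COLUMNS = ["photo_id", "unit_id", "point", "R", "G", "B"]

_COVARIATE_COLUMNS = ["quality", "color_family", "patterned", "specimen_age", "treatment", "species"]


def sample_roi_points(
    roi,
    k: int = 3,
    rng: np.random.Generator | int | None = None,
    photo_id: str = "photo",
    unit_id: str = "unit",
) -> pd.DataFrame:
    """Draw ``k`` i.i.d. uniform color points from a photo ROI.

    ``roi`` is either an explicit pixel set — an array of shape (n_pixels, 3)
    in 8-bit RGB — or a callable ``roi(k, rng) -> (k, 3)`` array sampling a
    synthetic color distribution.  Reproducible under a seeded ``rng``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if callable(roi):
        pts = np.asarray(roi(k, rng), dtype=float)
        if pts.shape != (k, 3):
            raise ValueError("roi sampler must return an array of shape (k, 3)")
    else:
        pixels = np.asarray(roi, dtype=float)
        if pixels.ndim != 2 or pixels.shape[1] != 3 or pixels.shape[0] == 0:
            raise ValueError("empty or malformed ROI: need a non-empty (n_pixels, 3) array")
        idx = rng.integers(0, pixels.shape[0], size=k)
        pts = pixels[idx]
    return pd.DataFrame(
        {
            "photo_id": photo_id,
            "unit_id": unit_id,
            "point": np.arange(1, k + 1),
            "R": pts[:, 0],
            "G": pts[:, 1],
            "B": pts[:, 2],
        }
    )


def circular_mean_deg(deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, in [0, 360); 0 for a zero resultant."""
    rad = np.deg2rad(np.asarray(deg, dtype=float))
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    if np.hypot(s, c) < 1e-12:
        return 0.0
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def _check_hierarchy(points: pd.DataFrame) -> None:
    missing = [c for c in POINT_COLUMNS[:2] if c not in points.columns]
    if missing:
        raise ValueError(f"point table missing columns: {missing}")
    orphans = points.loc[points["unit_id"].isna(), "photo_id"].unique()
    if orphans.size:
        raise ValueError(f"orphan points (no unit): photo ids {sorted(map(str, orphans))}")
    multi = points.groupby("photo_id")["unit_id"].nunique()
    bad = multi[multi > 1].index.tolist()
    if bad:
        raise ValueError(f"photos assigned to multiple units: {sorted(map(str, bad))}")


def aggregate_points(points: pd.DataFrame, hue_mean: str = "circular") -> pd.DataFrame:
    """Average point measurements to one row per photo, in all three spaces.

    RGB channels are averaged arithmetically.  Points are converted to HSV
    and Lab first and then averaged, matching how per-point measurement
    software output is aggregated; hue uses a circular mean by default
    (``hue_mean="arithmetic"`` reproduces naive degree averaging).
    Covariate columns must be constant within a photo and are carried along.
    """
    if hue_mean not in ("circular", "arithmetic"):
        raise ValueError("hue_mean must be 'circular' or 'arithmetic'")
    _check_hierarchy(points)
    pts = points.copy()
    rgb = pts[["R", "G", "B"]].to_numpy(float)
    hsv = rgb_to_hsv(rgb)
    lab = rgb_to_lab(rgb)
    for i, c in enumerate(["H", "S", "V"]):
        pts[c] = hsv[:, i]
    for i, c in enumerate(["L", "a", "b"]):
        pts[c] = lab[:, i]

    agg = {c: "mean" for c in ["R", "G", "B", "S", "V", "L", "a", "b"]}
    agg["H"] = circular_mean_deg if hue_mean == "circular" else "mean"
    carried = [c for c in _COVARIATE_COLUMNS if c in pts.columns]
    for c in carried:
        nun = pts.groupby("photo_id")[c].nunique(dropna=False)
        if (nun > 1).any():
            raise ValueError(f"covariate {c!r} varies within a photo")
        agg[c] = "first"
    out = (
        pts.groupby(["unit_id", "photo_id"], sort=True, dropna=False)
        .agg(agg | {"point": "size"})
        .rename(columns={"point": "n_points"})
        .reset_index()
    )
    return out


def aggregate_photos(photos: pd.DataFrame) -> pd.DataFrame:
    """Average per-photo values to one row per unit; SDs where n_photos ≥ 2.

    Means and sample standard deviations (n−1 denominator) are computed per
    channel in each space; SD columns are NaN for single-photo units.
    """
    channels = [c for c in ["R", "G", "B", "H", "S", "V", "L", "a", "b"] if c in photos.columns]
    if not channels:
        raise ValueError("photo table has no channel columns")
    g = photos.groupby("unit_id", sort=True)
    out = g[channels].mean()
    sds = g[channels].std(ddof=1)
    sds.columns = [f"sd_{c}" for c in channels]
    out = out.join(sds)
    out["n_photos"] = g.size()
    carried = [c for c in ["color_family", "patterned", "species"] if c in photos.columns]
    for c in carried:
        out[c] = g[c].first()
    return out.reset_index()


def aggregate(points: pd.DataFrame, hue_mean: str = "circular") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full hierarchy: points → photo means → unit means/SDs."""
    photos = aggregate_points(points, hue_mean=hue_mean)
    return photos, aggregate_photos(photos)


@dataclass(frozen=True)
class QualityFilterReport:
    kept: int
    dropped: int
    unrated: int


def filter_quality(
    photos: pd.DataFrame, min_stars: int = 4, allow_unrated: bool = False
) -> tuple[pd.DataFrame, QualityFilterReport]:
    """Keep photos rated at least ``min_stars`` (1–5 star scale).

    Unrated photos are dropped unless ``allow_unrated``; the report counts
    kept / dropped / unrated rows.
    """
    if "quality" not in photos.columns:
        if allow_unrated:
            return photos, QualityFilterReport(len(photos), 0, len(photos))
        raise ValueError("no 'quality' column; pass allow_unrated=True to keep unrated photos")
    rated = photos["quality"].notna()
    keep = rated & (photos["quality"] >= min_stars)
    if allow_unrated:
        keep |= ~rated
    out = photos[keep]
    return out, QualityFilterReport(
        kept=int(keep.sum()), dropped=int((~keep).sum()), unrated=int((~rated).sum())
    )


def detect_saturation(
    photos: pd.DataFrame,
    level: float = 255.0,
    frac_threshold: float = 0.25,
    channels: tuple[str, ...] = ("R", "G", "B"),
    group_cols: tuple[str, ...] = ("unit_id",),
) -> pd.DataFrame:
    """Flag unit × channel combinations with values piled at the 8-bit ceiling.

    A channel is flagged when the fraction of photo-mean values at or above
    ``level − 1`` exceeds ``frac_threshold`` (default 25%).  Values condensed
    at the ceiling indicate sensor saturation, which destroys color
    information; flagged units should be excluded from variance analyses.
    """
    group_cols = [c for c in group_cols if c in photos.columns]
    if not group_cols:
        raise ValueError("no grouping columns present")
    rows = []
    for key, sub in photos.groupby(group_cols, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for ch in channels:
            frac = float(np.mean(sub[ch].to_numpy(float) >= level - 1.0))
            rows.append(
                dict(zip(group_cols, key))
                | {
                    "channel": ch,
                    "saturated_fraction": frac,
                    "flagged": frac > frac_threshold,
                    "n_photos": len(sub),
                }
            )
    return pd.DataFrame(rows)
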