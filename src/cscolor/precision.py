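"""Sample-size versus precision: how many photos per species are enough?

Precision is summarized as the mean absolute regression residual of
photo-derived species color against spectrometry-derived species color, as
a function of the number of photographs averaged per species (k = 1..25).
Two estimators are provided:

* :func:`empirical_curve` — the fidelity procedure: one regression on all
  species means, absolute residuals grouped by each species' own photo
  count.  Species identity and photo count are confounded here (different
  species contribute at different k), which is documented rather than fixed.
* :func:`resampled_curve` — a de-confounded bootstrap variant: the same set
  of well-sampled species contributes at every k via repeated k-photo
  subsamples, so the curve isolates the averaging effect.

The plateau rule turns a curve into a recommended k: the smallest k at
which all but a ``threshold`` fraction (default 10%) of the achievable
precision gain — the drop from the k = 1 residual level to the k_max level —
has been realized, after 3-point smoothing of the curve interior.  Under
the theoretical 1/√k noise-averaging decay with k_max = 25 this recommends
k = 13, inside the 12–14 band a visual plateau reading suggests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PrecisionCurve",
    "empirical_curve",
    "resampled_curve",
    "plateau",
    "PlateauResult",
]


@dataclass(frozen=True)
class PrecisionCurve:
    """Mean absolute residual per channel at each photos-per-species count."""

    table: pd.DataFrame  # columns: k, channel, mean_abs_residual, n_species
    mode: str  # "empirical" or "resampled"

    def channel(self, ch: str) -> pd.DataFrame:
        return (
            self.table[self.table["channel"] == ch]
            .sort_values("k")
            .reset_index(drop=True)
        )


def _species_regression_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


def empirical_curve(
    photo_units: pd.DataFrame,
    museum_units: pd.DataFrame,
    channels: tuple[str, ...] = ("R", "G", "B"),
    k_max: int = 25,
) -> PrecisionCurve:
    """Precision curve from the observed photos-per-species distribution.

    Species means are regressed on spectrometry means per channel (one
    regression over all species); absolute residuals are grouped by each
    species' photo count and averaged.  Counts with no species leave a gap
    in the curve rather than raising.
    """
    merged = photo_units.merge(museum_units, on="unit_id", suffixes=("_photo", "_museum"))
    if "n_photos" not in merged.columns:
        raise ValueError("photo unit table must carry n_photos")
    rows = []
    for ch in channels:
        resid = _species_regression_residuals(
            merged[f"{ch}_museum"].to_numpy(float), merged[f"{ch}_photo"].to_numpy(float)
        )
        sub = pd.DataFrame({"k": merged["n_photos"].to_numpy(int), "abs_resid": np.abs(resid)})
        sub = sub[sub["k"] <= k_max]
        grouped = sub.groupby("k")["abs_resid"].agg(["mean", "size"]).reset_index()
        for _, r in grouped.iterrows():
            rows.append(
                {"k": int(r["k"]), "channel": ch,
                 "mean_abs_residual": float(r["mean"]), "n_species": int(r["size"])}
            )
    return PrecisionCurve(pd.DataFrame(rows).sort_values(["channel", "k"]).reset_index(drop=True), "empirical")


def resampled_curve(
    photos: pd.DataFrame,
    museum_units: pd.DataFrame,
    k_max: int = 25,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
    channels: tuple[str, ...] = ("R", "G", "B"),
    refit_per_k: bool = False,
) -> PrecisionCurve:
    """Bootstrap precision curve with the same species at every k.

    Only species with at least ``k_max`` photos are eligible, so every k is
    estimated from an identical species set.  For each bootstrap replicate
    the photos of each species are randomly re-ordered and running means
    over the first k give all subsample means at once.  Residuals are taken
    against the regression line fitted to the full-data species means
    (``refit_per_k=True`` refits the regression on each subsample instead).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = photos.groupby("unit_id").size()
    eligible = counts[counts >= k_max].index
    if eligible.empty:
        raise ValueError(f"no species with at least {k_max} photos")
    museum = museum_units.set_index("unit_id").loc[eligible]
    rows = []
    for ch in channels:
        # (n_species, max_count) value matrix, NaN-padded.
        wide = (
            photos[photos["unit_id"].isin(eligible)]
            .assign(_i=lambda d: d.groupby("unit_id").cumcount())
            .pivot(index="unit_id", columns="_i", values=ch)
            .loc[eligible]
            .to_numpy(float)
        )
        x = museum[ch].to_numpy(float)
        full_means = np.nanmean(wide, axis=1)
        line = sm.OLS(full_means, sm.add_constant(x)).fit()
        acc = np.zeros(k_max)
        for _ in range(n_boot):
            # Independent permutation of each species' own photos.
            keys = rng.random(wide.shape)
            keys[np.isnan(wide)] = np.inf  # push padding to the end
            perm = np.take_along_axis(wide, np.argsort(keys, axis=1), axis=1)[:, :k_max]
            cmeans = np.cumsum(perm, axis=1) / np.arange(1, k_max + 1)
            if refit_per_k:
                for j in range(k_max):
                    resid = _species_regression_residuals(x, cmeans[:, j])
                    acc[j] += np.abs(resid).mean()
            else:
                pred = line.params[0] + line.params[1] * x
                acc += np.abs(cmeans - pred[:, None]).mean(axis=0)
        for j in range(k_max):
            rows.append(
                {"k": j + 1, "channel": ch,
                 "mean_abs_residual": float(acc[j] / n_boot), "n_species": int(len(eligible))}
            )
    return PrecisionCurve(pd.DataFrame(rows), "resampled")


@dataclass(frozen=True)
class PlateauResult:
    per_channel: dict[str, int]
    recommended_k: int
    plateaued: bool
    threshold: float


def _smooth_interior(c: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average on interior points; endpoints kept raw."""
    if c.size < window:
        return c.copy()
    out = c.copy()
    half = window // 2
    for i in range(half, c.size - half):
        out[i] = c[i - half : i + half + 1].mean()
    return out


def plateau(
    curve: PrecisionCurve, threshold: float = 0.10, window: int = 3
) -> PlateauResult:
    """Recommended photos-per-species from the remaining-gain plateau rule.

    For each channel, with smoothed curve values c̃(k), the remaining gain is
    ``R(k) = (c̃(k) − c̃(K)) / (c̃(1) − c̃(K))``; the plateau is the smallest k
    with ``R(k) < threshold`` — i.e. at least a fraction 1 − threshold of the
    achievable improvement is realized.  A flat curve plateaus at k = 1; a
    curve with no overall decrease returns K with ``plateaued=False``.  The
    overall recommendation is the max across channels.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    per_channel: dict[str, int] = {}
    all_plateaued = True
    for ch in curve.table["channel"].unique():
        sub = curve.channel(ch)
        if len(sub) < 3:
            raise ValueError(f"channel {ch}: curve needs at least 3 consecutive k")
        ks = sub["k"].to_numpy(int)
        c = _smooth_interior(sub["mean_abs_residual"].to_numpy(float), window)
        drop = c[0] - c[-1]
        if drop < 0:
            per_channel[ch] = int(ks[-1])
            all_plateaued = False
            continue
        if drop == 0:
            per_channel[ch] = int(ks[0])
            continue
        remaining = (c - c[-1]) / drop
        hit = np.nonzero(remaining < threshold)[0]
        per_channel[ch] = int(ks[hit[0]]) if hit.size else int(ks[-1])
    return PlateauResult(
        per_channel=per_channel,
        recommended_k=max(per_channel.values()),
        plateaued=all_plateaued,
        threshold=threshold,
    )
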