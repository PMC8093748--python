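"""Measurement-agreement analysis between photo and spectrometry color.

The central statistic is per-channel ordinary least squares of photo-derived
values on spectrometry-derived values across units (species), reported as
R².  Two levels are analyzed: species means (each species contributes one
averaged photo value) and individual photos (each photo regressed against
its species' spectrometry mean).  Residual diagnostics cover specimen age,
patterned-vs-plain contrasts, and color-family summaries; a final set of
models predicts avian visual-space coordinates from the Lab chromatic
components a and b — the channels a camera can see.

OLS fits go through :mod:`statsmodels`; results carry slope, intercept, R²
and unit-keyed residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AgreementResult",
    "fit_channel",
    "individual_level_fit",
    "fit_spaces",
    "residuals_vs_covariate",
    "group_contrast",
    "family_summaries",
    "predict_bird_space",
    "SPACE_CHANNELS",
]

SPACE_CHANNELS = {"RGB": ["R", "G", "B"], "HSV": ["H", "S", "V"], "Lab": ["L", "a", "b"]}


@dataclass(frozen=True)
class AgreementResult:
    """One per-channel OLS agreement fit (photo ~ spectrometry)."""

    channel: str
    level: str  # "species" or "individual"
    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: pd.Series = field(repr=False)
    p_value: float = np.nan

    @property
    def space(self) -> str:
        for space, chans in SPACE_CHANNELS.items():
            if self.channel in chans:
                return space
        return "unknown"


def fit_channel(x, y, labels=None, channel: str = "", level: str = "species") -> AgreementResult:
    """OLS of photo values ``y`` on spectrometry values ``x`` for one channel.

    Requires at least 3 paired finite observations and variance in ``x``.
    Zero variance in ``y`` yields R² = 0 with a warning rather than an error.
    Residuals are returned keyed by ``labels`` (unit or photo ids).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired units")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in spectrometry values: slope undefined")
    index = pd.Index(labels if labels is not None else np.arange(x.size), name="unit_id")
    if np.ptp(y) == 0:
        warnings.warn("zero variance in photo values; R² reported as 0", stacklevel=2)
        return AgreementResult(
            channel, level, 0.0, float(y[0]), 0.0, x.size,
            pd.Series(np.zeros_like(y), index=index), np.nan,
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AgreementResult(
        channel=channel,
        level=level,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        residuals=pd.Series(model.resid, index=index),
        p_value=float(model.pvalues[1]),
    )


def individual_level_fit(
    photos: pd.DataFrame, museum_units: pd.DataFrame, channel: str
) -> AgreementResult:
    """Individual-photo fit: photo values against the species' spectrometry mean.

    Every photo must map to a museum unit; unmatched species raise with the
    offending ids.  Repeated x values (many photos per species) are expected.
    """
    museum = museum_units.set_index("unit_id")[channel]
    unmatched = sorted(map(str, set(photos["unit_id"]) - set(museum.index)))
    if unmatched:
        raise ValueError(f"photos reference species missing from museum data: {unmatched}")
    x = museum.loc[photos["unit_id"]].to_numpy(float)
    return fit_channel(
        x, photos[channel].to_numpy(float), labels=photos["photo_id"].to_numpy(),
        channel=channel, level="individual",
    )


def fit_spaces(
    photo_units: pd.DataFrame,
    museum_units: pd.DataFrame,
    photos: pd.DataFrame | None = None,
    spaces: tuple[str, ...] = ("RGB", "HSV", "Lab"),
) -> tuple[pd.DataFrame, dict[tuple[str, str], AgreementResult]]:
    """Fit every channel of the requested spaces at species level (and, when a
    photo table is given, at individual level).

    Returns a tidy frame (space, channel, level, slope, intercept, r2, n)
    plus the full results keyed by (channel, level).
    """
    merged = photo_units.merge(museum_units, on="unit_id", suffixes=("_photo", "_museum"))
    rows, results = [], {}
    for space in spaces:
        for ch in SPACE_CHANNELS[space]:
            res = fit_channel(
                merged[f"{ch}_museum"], merged[f"{ch}_photo"],
                labels=merged["unit_id"].to_numpy(), channel=ch, level="species",
            )
            results[(ch, "species")] = res
            if photos is not None:
                res_i = individual_level_fit(photos, museum_units, ch)
                results[(ch, "individual")] = res_i
    for (ch, level), res in results.items():
        rows.append(
            {
                "space": res.space,
                "channel": ch,
                "level": level,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r_squared,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows), results


@dataclass(frozen=True)
class CovariateEffect:
    slope: float
    r_squared: float
    p_value: float
    n: int


def residuals_vs_covariate(residuals: pd.Series, covariate: pd.Series) -> CovariateEffect:
    """Regress agreement residuals on a numeric covariate (e.g. specimen age).

    Returns the slope, R² and the two-sided t-test p-value for the slope.
    """
    joined = pd.concat([residuals.rename("resid"), covariate.rename("cov")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 residual/covariate pairs")
    if np.ptp(joined["cov"].to_numpy(float)) == 0:
        raise ValueError("constant covariate: effect undefined")
    model = sm.OLS(joined["resid"], sm.add_constant(joined["cov"].astype(float))).fit()
    return CovariateEffect(
        slope=float(model.params.iloc[1]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues.iloc[1]),
        n=len(joined),
    )


def group_contrast(
    residuals: pd.DataFrame,
    group: pd.Series,
    channels: tuple[str, ...] = ("R", "G", "B"),
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Contrast residuals between two groups (e.g. patterned vs plain patches).

    Welch's two-sample t-test per channel, with the p-values adjusted across
    channels (Bonferroni by default, Holm optional), capped at 1.
    """
    if method not in ("bonferroni", "holm"):
        raise ValueError("method must be 'bonferroni' or 'holm'")
    mask = group.astype(bool).to_numpy()
    if min(mask.sum(), (~mask).sum()) < 2:
        raise ValueError("each group needs at least 2 observations")
    raw, effects = [], []
    for ch in channels:
        a = residuals.loc[mask, ch].to_numpy(float)
        b = residuals.loc[~mask, ch].to_numpy(float)
        t = stats.ttest_ind(a, b, equal_var=False)
        raw.append(float(t.pvalue))
        effects.append(float(a.mean() - b.mean()))
    raw = np.asarray(raw)
    if method == "bonferroni":
        adj = np.minimum(raw * len(channels), 1.0)
    else:
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (len(channels) - rank))
            adj[idx] = min(running, 1.0)
    return pd.DataFrame(
        {"channel": channels, "effect": effects, "p_raw": raw, "p_adjusted": adj}
    )


def family_summaries(
    residuals: pd.DataFrame,
    unit_sds: pd.DataFrame,
    families: pd.DataFrame,
    channels: tuple[str, ...] = ("R", "G", "B"),
) -> pd.DataFrame:
    """Per color-family bias and precision summaries.

    ``families`` maps ``unit_id`` to ``color_family``; a species assigned to
    several families appears in each (one row per membership).  Bias is the
    five-number summary of residuals, precision the distribution of
    per-species SDs.  Families with no members are omitted with a warning.
    """
    rows = []
    for fam, members in families.groupby("color_family")["unit_id"]:
        res = residuals[residuals["unit_id"].isin(members)]
        sds = unit_sds[unit_sds["unit_id"].isin(members)]
        if res.empty:
            warnings.warn(f"color family {fam!r} has no residuals; omitted", stacklevel=2)
            continue
        for ch in channels:
            v = res[ch].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            row = {
                "color_family": fam,
                "channel": ch,
                "n_units": res["unit_id"].nunique(),
                "bias_min": float(v.min()),
                "bias_q1": float(q1),
                "bias_median": float(med),
                "bias_q3": float(q3),
                "bias_max": float(v.max()),
            }
            sd_col = f"sd_{ch}"
            if sd_col in sds.columns and sds[sd_col].notna().any():
                row["sd_median"] = float(sds[sd_col].median())
                row["sd_iqr"] = float(
                    sds[sd_col].quantile(0.75) - sds[sd_col].quantile(0.25)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def predict_bird_space(
    photo_lab: pd.DataFrame, avian_values: pd.DataFrame
) -> pd.DataFrame:
    """Predict avian visual-space coordinates from photo Lab species means.

    Fits ``DL ~ L`` (achromatic against achromatic) and, per eye type,
    ``x ~ a + b``, ``y ~ a + b``, ``z ~ a + b`` (chromatic against the
    chromatic plane a camera records).  Returns a tidy frame with R² per
    response; UV-weighted responses are expected to fare worst because
    cameras record nothing below ~400 nm.
    """
    merged = photo_lab.merge(avian_values, on="unit_id")
    if len(merged) < 4:
        raise ValueError("need at least 4 paired species")
    rows = []

    def _fit(y: np.ndarray, X: np.ndarray) -> float:
        design = sm.add_constant(X)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design in bird-space prediction")
        return float(sm.OLS(y, design).fit().rsquared)

    for eye in sorted({c.split("_")[-1] for c in merged.columns if c.startswith(("x_", "y_", "z_"))}):
        for resp in ("x", "y", "z"):
            col = f"{resp}_{eye}"
            r2 = _fit(merged[col].to_numpy(float), merged[["a", "b"]].to_numpy(float))
            rows.append(
                {"eye_type": eye, "response": resp, "predictors": "a+b",
                 "r2": r2, "n": len(merged)}
            )
    if "DL" in merged.columns:
        r2 = _fit(merged["DL"].to_numpy(float), merged[["L"]].to_numpy(float))
        rows.append(
            {"eye_type": "both", "response": "DL", "predictors": "L", "r2": r2, "n": len(merged)}
        )
    return pd.DataFrame(rows)
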