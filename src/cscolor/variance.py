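"""Treatment-variance analysis: per-treatment SDs, Bartlett, Kruskal–Wallis.

The intraspecific analysis asks whether lowering methodological control
(spectrometry → controlled photography → citizen-science photographs)
inflates the spread of repeated color measurements of the same flower
species.  Per-treatment sample SDs are computed in RGB and Lab; Bartlett's
test checks variance homogeneity across treatments and the Kruskal–Wallis
rank test checks for location differences.

Both test statistics are implemented directly from their formulas (the
statistic is the point of this module); established library routines serve
as independent cross-checks in the test suite, not as the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import rgb_to_lab

__all__ = [
    "treatment_sds",
    "bartlett_test",
    "kruskal_wallis",
    "variance_report",
    "TestResult",
    "VarianceReport",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


def _clean_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if any(not np.all(np.isfinite(g)) for g in out):
        raise ValueError("groups must contain finite values")
    return out


def bartlett_test(groups) -> TestResult:
    """Bartlett's test of variance homogeneity across k groups.

    ``T = [(N−k)·ln Sp² − Σ (n_i−1)·ln S_i²] / C`` with the pooled variance
    ``Sp²`` and correction ``C = 1 + (Σ 1/(n_i−1) − 1/(N−k)) / (3(k−1))``;
    the p-value is the upper tail of χ²(k−1).  Groups with zero variance
    make the log-variance term undefined and raise, naming the group.
    """
    gs = _clean_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    ns = np.array([g.size for g in gs], dtype=float)
    variances = np.array([g.var(ddof=1) for g in gs])
    zero = np.nonzero(variances == 0)[0]
    if zero.size:
        raise ValueError(
            f"group(s) {zero.tolist()} have zero variance: Bartlett log-variance undefined"
        )
    N = ns.sum()
    k = len(gs)
    pooled = np.sum((ns - 1) * variances) / (N - k)
    T = (N - k) * np.log(pooled) - np.sum((ns - 1) * np.log(variances))
    C = 1.0 + (np.sum(1.0 / (ns - 1)) - 1.0 / (N - k)) / (3.0 * (k - 1))
    T /= C
    df = k - 1
    return TestResult(float(T), int(df), float(stats.chi2.sf(T, df)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis rank test with mid-ranks and tie correction.

    ``H = 12/(N(N+1)) · Σ n_i r̄_i² − 3(N+1)``, divided by the tie correction
    ``1 − Σ(t_j³ − t_j)/(N³ − N)``; p from χ²(k−1).  All-identical pooled
    values leave H undefined (tie correction zero) and raise.
    """
    gs = _clean_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(gs)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 values in total")
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts.astype(float) ** 3 - tie_counts)
    correction = 1.0 - tie_term / (N**3 - N)
    if correction <= 0:
        raise ValueError("all pooled values identical: H undefined")
    H = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        H += g.size * r.mean() ** 2
        start += g.size
    H = (12.0 / (N * (N + 1))) * H - 3.0 * (N + 1)
    H /= correction
    df = len(gs) - 1
    return TestResult(float(H), int(df), float(stats.chi2.sf(H, df)))


@dataclass(frozen=True)
class VarianceReport:
    """SD table plus homogeneity/location tests per channel in RGB and Lab."""

    sds: pd.DataFrame  # treatment x channel SDs (long)
    tests: pd.DataFrame  # space, channel, test, statistic, df, p
    excluded: list[str]


def treatment_sds(
    photos: pd.DataFrame,
    channels: tuple[str, ...] = ("R", "G", "B"),
    group_col: str = "treatment",
) -> pd.DataFrame:
    """Sample SD (n−1 denominator) per channel per treatment.

    Treatments with fewer than 2 photos cannot yield an SD and are omitted
    with a warning.
    """
    rows = []
    for treatment, sub in photos.groupby(group_col, sort=True):
        if len(sub) < 2:
            warnings.warn(
                f"treatment {treatment!r} has n < 2; omitted from SD table", stacklevel=2
            )
            continue
        for ch in channels:
            rows.append(
                {
                    group_col: treatment,
                    "channel": ch,
                    "sd": float(sub[ch].to_numpy(float).std(ddof=1)),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def variance_report(
    photos: pd.DataFrame,
    group_col: str = "treatment",
    exclude: tuple[str, ...] = (),
) -> VarianceReport:
    """Full intraspecific report: SDs in RGB and Lab plus both tests per channel.

    ``exclude`` lists treatments dropped before testing (e.g. those flagged
    as saturated).  One Bartlett and one Kruskal–Wallis test is run per
    channel in each space.
    """
    photos = photos[~photos[group_col].isin(exclude)].copy()
    if photos.empty:
        raise ValueError("no data left after exclusions")
    lab = rgb_to_lab(photos[["R", "G", "B"]].to_numpy(float))
    for i, c in enumerate(["L", "a", "b"]):
        photos[c] = lab[:, i]
    sd_rgb = treatment_sds(photos, ("R", "G", "B"), group_col).assign(space="RGB")
    sd_lab = treatment_sds(photos, ("L", "a", "b"), group_col).assign(space="Lab")
    sds = pd.concat([sd_rgb, sd_lab], ignore_index=True)

    test_rows = []
    n_groups = photos[group_col].nunique()
    for space, channels in (("RGB", ("R", "G", "B")), ("Lab", ("L", "a", "b"))):
        for ch in channels:
            groups = [sub[ch].to_numpy(float) for _, sub in photos.groupby(group_col)]
            if n_groups < 2:
                continue
            for name, fn in (("bartlett", bartlett_test), ("kruskal_wallis", kruskal_wallis)):
                try:
                    res = fn(groups)
                    test_rows.append(
                        {"space": space, "channel": ch, "test": name,
                         "statistic": res.statistic, "df": res.df, "p": res.p_value}
                    )
                except ValueError as err:
                    test_rows.append(
                        {"space": space, "channel": ch, "test": name,
                         "statistic": np.nan, "df": np.nan, "p": np.nan, "note": str(err)}
                    )
    return VarianceReport(sds=sds, tests=pd.DataFrame(test_rows), excluded=list(exclude))
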