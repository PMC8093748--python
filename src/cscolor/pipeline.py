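"""End-to-end runs tying the stages into the two study analyses.

:func:`run_interspecific` is the bird analysis: photo point table + museum
spectrometry table → quality filter → aggregation → per-channel agreement
in RGB/HSV/Lab at species and individual level → bird-visual-space
prediction from Lab → precision curve and recommended sample size.

:func:`run_intraspecific` is the plant analysis: flower treatment table →
saturation screening (with species exclusion) → per-treatment SDs in RGB
and Lab → Bartlett and Kruskal–Wallis per channel.

Every CSV written carries a comment header with package version, seed and
config hash, so reruns are byte-identical and self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, agreement, precision, sampling, synthetic, variance

__all__ = ["RunConfig", "run_interspecific", "run_intraspecific", "write_table", "read_table"]

log = logging.getLogger("cscolor")


@dataclass(frozen=True)
class RunConfig:
    """Run parameters shared by the pipelines and the CLI."""

    seed: int = 0
    outdir: str | None = None
    min_stars: int = 4
    allow_unrated: bool = False
    points_per_roi: int = 3
    k_max: int = 25
    n_boot: int = 200
    saturation_level: float = 255.0
    saturation_frac: float = 0.25
    plateau_threshold: float = 0.10
    hue_mean: str = "circular"
    exclude_saturated: bool = True
    make_plots: bool = False
    generator: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (I/O paths excluded)."""
        d = json.loads(self.to_json())
        d.pop("outdir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def generator_config(self) -> synthetic.GeneratorConfig:
        return synthetic.GeneratorConfig(seed=self.seed, **self.generator)


def write_table(df: pd.DataFrame, path, config: RunConfig) -> None:
    """Write a CSV with a provenance comment header (version, seed, hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cscolor {__version__}\n")
        fh.write(f"# seed={config.seed} config_hash={config.config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _maybe_write(tables: dict[str, pd.DataFrame], config: RunConfig) -> None:
    if config.outdir is None:
        return
    for name, df in tables.items():
        write_table(df, Path(config.outdir) / f"{name}.csv", config)


def run_interspecific(
    config: RunConfig,
    points: pd.DataFrame | None = None,
    museum: pd.DataFrame | None = None,
    species: synthetic.SpeciesSet | None = None,
) -> dict:
    """The full bird analysis; synthesizes its inputs when none are given.

    Returns a dict of result tables: ``agreement`` (space × channel × level
    R²), ``bird_space`` (avian-coordinate prediction R²), ``precision_curve``,
    ``plateau``, ``photo_units``, ``museum_units``, plus diagnostics.
    """
    gen = config.generator_config()
    if points is None or museum is None:
        if species is None:
            species = synthetic.generate_species(gen)
        points = synthetic.generate_photos(species) if points is None else points
        museum = synthetic.generate_museum(species) if museum is None else museum
    log.info("interspecific run: %d point rows", len(points))

    photos, _ = sampling.aggregate(points, hue_mean=config.hue_mean)
    if "quality" in photos.columns:
        photos, qreport = sampling.filter_quality(
            photos, config.min_stars, allow_unrated=config.allow_unrated
        )
        log.info("quality filter: kept %d dropped %d", qreport.kept, qreport.dropped)
    photo_units = sampling.aggregate_photos(photos)
    museum_units = synthetic.museum_species_means(museum)
    # Drop species filtered out entirely (no qualifying photos).
    museum_units = museum_units[museum_units["unit_id"].isin(photo_units["unit_id"])]

    tidy, results = agreement.fit_spaces(photo_units, museum_units, photos=photos)

    out: dict = {
        "agreement": tidy,
        "photo_units": photo_units,
        "museum_units": museum_units,
        "results": results,
    }

    curve = precision.empirical_curve(photo_units, museum_units, k_max=config.k_max)
    out["precision_curve"] = curve.table
    counts = photos.groupby("unit_id").size()
    if (counts >= config.k_max).sum() >= 3:
        rcurve = precision.resampled_curve(
            photos, museum_units, k_max=config.k_max, n_boot=config.n_boot, rng=config.seed
        )
        out["precision_curve_resampled"] = rcurve.table
        plat = precision.plateau(rcurve, threshold=config.plateau_threshold)
    else:
        plat = precision.plateau(curve, threshold=config.plateau_threshold)
    out["plateau"] = pd.DataFrame(
        [
            {"channel": ch, "k": k, "recommended_k": plat.recommended_k,
             "plateaued": plat.plateaued, "threshold": plat.threshold}
            for ch, k in plat.per_channel.items()
        ]
    )

    # Avian visual space: only available when species truths carry spectra-
    # derived avian coordinates (synthetic runs, or precomputed input).
    if species is not None and "x_U" in species.truths.columns:
        avian_cols = ["unit_id", "DL", "x_U", "y_U", "z_U", "x_V", "y_V", "z_V"]
        avian_values = species.truths[avian_cols]
        lab_means = photo_units[["unit_id", "L", "a", "b"]]
        out["bird_space"] = agreement.predict_bird_space(lab_means, avian_values)

    if "specimen_age" in museum_units.columns:
        age_rows = []
        for ch in ("R", "G", "B"):
            res = results[(ch, "species")]
            merged = museum_units.set_index("unit_id").loc[res.residuals.index]
            eff = agreement.residuals_vs_covariate(res.residuals, merged["specimen_age"])
            age_rows.append(
                {"channel": ch, "slope_per_year": eff.slope, "r2": eff.r_squared,
                 "p": eff.p_value, "n": eff.n}
            )
        out["age_effects"] = pd.DataFrame(age_rows)

    if "patterned" in photo_units.columns:
        resid = pd.DataFrame(
            {ch: results[(ch, "species")].residuals for ch in ("R", "G", "B")}
        ).reset_index()
        merged = resid.merge(photo_units[["unit_id", "patterned"]], on="unit_id")
        if merged["patterned"].nunique() == 2:
            out["patterned_contrast"] = agreement.group_contrast(
                merged, merged["patterned"]
            )

    if "color_family" in photo_units.columns:
        resid = pd.DataFrame(
            {ch: results[(ch, "individual")].residuals for ch in ("R", "G", "B")}
        )
        resid["unit_id"] = photos.set_index("photo_id").loc[resid.index, "unit_id"].to_numpy()
        fam = photo_units[["unit_id", "color_family"]].dropna()
        out["family_summaries"] = agreement.family_summaries(
            resid, photo_units, fam
        )

    _maybe_write({k: v for k, v in out.items() if isinstance(v, pd.DataFrame)}, config)
    if config.make_plots and config.outdir is not None:
        _plot_interspecific(out, config)
    return out


def run_intraspecific(config: RunConfig, points: pd.DataFrame | None = None) -> dict:
    """The full plant analysis on a seven-treatment flower table.

    Saturation screening runs per species × treatment × channel; a species
    with any flagged cell is excluded entirely before the variance tests
    (saturated channels carry no usable color information), mirroring how a
    saturated source must be dropped rather than averaged over.
    """
    if points is None:
        points = synthetic.generate_flower_experiment(config.generator_config())
    photos, _ = sampling.aggregate(points, hue_mean=config.hue_mean)

    sat = sampling.detect_saturation(
        photos,
        level=config.saturation_level,
        frac_threshold=config.saturation_frac,
        group_cols=("species", "treatment"),
    )
    flagged_species = sorted(sat.loc[sat["flagged"], "species"].unique())
    out: dict = {"saturation": sat, "excluded_species": flagged_species}

    reports = {}
    rows_sd, rows_tests = [], []
    for species_name, sub in photos.groupby("species"):
        if config.exclude_saturated and species_name in flagged_species:
            log.info("excluding %s: saturated treatment channel(s)", species_name)
            continue
        if sub["treatment"].nunique() < 2:
            rep = variance.VarianceReport(
                sds=variance.treatment_sds(sub).assign(space="RGB"),
                tests=pd.DataFrame(),
                excluded=[],
            )
            log.info("%s: single treatment, tests skipped", species_name)
        else:
            rep = variance.variance_report(sub)
        reports[species_name] = rep
        rows_sd.append(rep.sds.assign(species=species_name))
        if not rep.tests.empty:
            rows_tests.append(rep.tests.assign(species=species_name))
    out["sds"] = pd.concat(rows_sd, ignore_index=True) if rows_sd else pd.DataFrame()
    out["tests"] = pd.concat(rows_tests, ignore_index=True) if rows_tests else pd.DataFrame()
    out["reports"] = reports

    _maybe_write({k: v for k, v in out.items() if isinstance(v, pd.DataFrame)}, config)
    return out


def _plot_interspecific(out: dict, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(config.outdir)
    merged = out["photo_units"].merge(
        out["museum_units"], on="unit_id", suffixes=("_photo", "_museum")
    )
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, ch in zip(axes, ("R", "G", "B")):
        ax.scatter(merged[f"{ch}_museum"], merged[f"{ch}_photo"], s=8, alpha=0.6)
        ax.set_xlabel(f"museum {ch}")
        ax.set_ylabel(f"photo {ch}")
    fig.tight_layout()
    fig.savefig(outdir / "agreement_rgb.png", dpi=120)
    plt.close(fig)

    curve = out.get("precision_curve_resampled", out["precision_curve"])
    fig, ax = plt.subplots(figsize=(6, 4))
    for ch, sub in curve.groupby("channel"):
        sub = sub.sort_values("k")
        ax.plot(sub["k"], sub["mean_abs_residual"], marker="o", label=ch)
    ax.set_xlabel("photographs per species")
    ax.set_ylabel("mean |residual|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "precision_curve.png", dpi=120)
    plt.close(fig)
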