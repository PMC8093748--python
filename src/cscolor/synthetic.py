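"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the three data sources of the study design:

* :func:`generate_species` — per-species "true" reflectance spectra built
  from color-family templates (red, yellow, white, black, pink, purple,
  gray/brown, and a UV-contrast family whose variation lives below 400 nm),
  with true color coordinates in every working space plus avian visual
  coordinates for both eye types.
* :func:`generate_photos` — an explicit camera observation model: linear-RGB
  truth × lognormal exposure gain × per-channel lognormal white balance,
  additive sensor noise, sRGB gamma encoding and 8-bit clipping, then
  point-level within-ROI scatter.  Every distortion can be switched off, so
  noiseless runs return the gamma-encoded truth exactly.
* :func:`generate_museum` — spectrometry replicates per species (1–5
  specimens, mean ≈ 2.62) with small replicate noise and an optional planted
  specimen-age drift per channel.
* :func:`generate_flower_experiment` — a two-species, seven-treatment
  control ladder from spectrometry to citizen-science photography with
  monotonically increasing noise, including one deliberately overexposed
  species × treatment cell that reproduces the saturation pathology.

All outputs are deterministic functions of ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import avian
from .colorimetry import _srgb_decode, _srgb_encode, rgb_to_hsv, rgb_to_lab, spectrum_to_rgb8
from .spectra import Spectrum

__all__ = [
    "GeneratorConfig",
    "TreatmentSpec",
    "DEFAULT_FAMILY_MIX",
    "DEFAULT_TREATMENTS",
    "SpeciesSet",
    "generate_species",
    "generate_photos",
    "generate_museum",
    "generate_flower_experiment",
    "museum_species_means",
    "estimate_variance_components",
]

#: Default color-family proportions, weighted toward the gray/brown plumage
#: that dominates a continental avifauna.
DEFAULT_FAMILY_MIX = {
    "gray_brown": 0.34,
    "black": 0.14,
    "white": 0.10,
    "red": 0.08,
    "yellow": 0.08,
    "pink": 0.06,
    "purple": 0.08,
    "uv_contrast": 0.12,
}


@dataclass(frozen=True)
class TreatmentSpec:
    """One rung of the control ladder (camera noise levels and sample size)."""

    name: str
    gain_log_sd: float
    wb_log_sd: float
    sensor_sd: float
    n_photos: int
    quality: tuple[int, int] = (4, 5)  # inclusive star-rating range
    #: systematic exposure bias of the method (flash brightens, ambient dims)
    gain_bias: float = 1.0
    #: within-ROI point scatter (8-bit scale); replicate scatter for spectrometry
    roi_sd: float = 3.0


#: Seven treatments from full control to none, noise increasing monotonically.
#: Each camera method also carries a small systematic exposure bias, so
#: treatments differ in location as well as spread.
DEFAULT_TREATMENTS = (
    TreatmentSpec("spectrometry", 0.0, 0.0, 1.5, 15, (5, 5), 1.0, 1.0),
    TreatmentSpec("olympus_flash", 0.03, 0.01, 2.5, 20, (4, 5), 1.08, 2.0),
    TreatmentSpec("olympus_no_flash", 0.06, 0.02, 4.0, 20, (4, 5), 0.95, 2.5),
    TreatmentSpec("phone_flash", 0.08, 0.03, 6.0, 20, (4, 5), 1.18, 3.0),
    TreatmentSpec("phone_no_flash", 0.10, 0.04, 8.0, 20, (4, 5), 0.90, 3.5),
    TreatmentSpec("citizen_science_45", 0.18, 0.06, 12.0, 30, (4, 5), 1.05, 6.0),
    TreatmentSpec("citizen_science", 0.25, 0.08, 16.0, 48, (1, 5), 0.92, 8.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, fully determined by ``seed``.

    Photo-noise defaults describe uncurated citizen-science photography:
    ~35% exposure scatter, ~12% per-channel white-balance scatter, 10/255
    sensor noise and 8/255 within-ROI scatter, with sRGB gamma and 8-bit
    clipping applied.  ``truth_mode="gaussian"`` bypasses spectra and draws
    species truths N(center, τ²) per channel directly on the 8-bit scale,
    the configuration used for variance-components calibration.
    """

    seed: int = 0
    n_species: int = 200
    photos_per_species: int | tuple[int, int] = (1, 25)
    family_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    truth_mode: str = "spectral"  # or "gaussian"
    tau: float = 25.0  # gaussian-mode species signal SD, 8-bit scale
    truth_center: float = 128.0
    gain_log_sd: float = 0.35
    wb_log_sd: float = 0.12
    sensor_sd: float = 10.0  # additive, quoted on the 8-bit scale
    roi_sd: float = 8.0  # within-ROI point scatter, 8-bit scale
    gamma: bool = True
    clip: bool = True
    points_per_photo: int = 3
    spec_replicate_sd: float = 3.0
    age_slope: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per decade, R/G/B
    age_range: tuple[float, float] = (0.0, 80.0)
    patterned_fraction: float = 0.3
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS
    #: species × treatment exposure multipliers planting the saturation pathology
    overexposure: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("senna_like", "olympus_no_flash"): 2.2}
    )

    def __post_init__(self):
        total = sum(self.family_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family proportions must sum to 1, got {total}")
        if self.truth_mode not in ("spectral", "gaussian"):
            raise ValueError("truth_mode must be 'spectral' or 'gaussian'")
        for name in ("tau", "gain_log_sd", "wb_log_sd", "sensor_sd", "roi_sd", "spec_replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["treatments"] = [dataclasses.asdict(t) for t in self.treatments]
        d["overexposure"] = {f"{k[0]}|{k[1]}": v for k, v in self.overexposure.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        d["treatments"] = tuple(
            TreatmentSpec(**{**t, "quality": tuple(t["quality"])})
            for t in d.get("treatments", [])
        )
        d["overexposure"] = {
            tuple(k.split("|", 1)): v for k, v in d.get("overexposure", {}).items()
        }
        d["photos_per_species"] = (
            tuple(d["photos_per_species"])
            if isinstance(d["photos_per_species"], list)
            else d["photos_per_species"]
        )
        for key in ("family_mix",):
            if key in d:
                d[key] = dict(d[key])
        d["age_slope"] = tuple(d["age_slope"])
        d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


# --- family spectral templates -------------------------------------------

_GRID = np.arange(300.0, 801.0)


def _sigmoid(wl, mid, width):
    return 1.0 / (1.0 + np.exp(-(wl - mid) / width))


def _gauss(wl, mu, sd):
    return np.exp(-0.5 * ((wl - mu) / sd) ** 2)


def _family_spectrum(family: str, rng: np.random.Generator) -> np.ndarray:
    """One jittered reflectance curve for a color family, on the 300–800 grid."""
    wl = _GRID
    u = rng.uniform
    if family == "red":
        r = 0.05 + u(0.45, 0.75) * _sigmoid(wl, u(590, 620), 18.0)
    elif family == "yellow":
        r = 0.07 + u(0.55, 0.85) * _sigmoid(wl, u(505, 535), 22.0)
    elif family == "white":
        r = u(0.65, 0.92) + 0.03 * _sigmoid(wl, 450, 40.0)
    elif family == "black":
        r = np.full_like(wl, u(0.010, 0.035)) + u(0.0, 0.005) * (wl - 300) / 500
    elif family == "gray_brown":
        base = u(0.12, 0.35)
        r = base + u(0.0, 0.15) * (wl - 300) / 500
    elif family == "pink":
        r = u(0.25, 0.45) + u(0.3, 0.5) * _sigmoid(wl, u(575, 600), 25.0)
    elif family == "purple":
        r = (
            0.05
            + u(0.2, 0.4) * _gauss(wl, u(420, 445), 30.0)
            + u(0.25, 0.45) * _sigmoid(wl, u(620, 650), 20.0)
        )
    elif family == "uv_contrast":
        r = np.full_like(wl, u(0.2, 0.4)) + u(0.05, 0.18) * _gauss(wl, 360.0, 14.0)
    else:
        raise ValueError(f"unknown color family: {family!r}")
    # Small UV-independent perturbation for every species, proportional to
    # the local reflectance (UV brightness tracks overall brightness; truly
    # independent UV variation is rare in plumage, hence kept small).
    r = r * (1.0 + u(0.0, 0.15) * _gauss(wl, 355.0, 12.0))
    return np.clip(r, 0.0, 1.05)


@dataclass(frozen=True)
class SpeciesSet:
    """Species truths: color coordinates per species plus the spectra."""

    truths: pd.DataFrame
    spectra: dict[str, Spectrum]
    config: GeneratorConfig


def generate_species(config: GeneratorConfig) -> SpeciesSet:
    """Draw the species-level ground truth.

    Spectral mode: family-templated spectra with jittered parameters; true
    RGB/HSV/Lab values via the colorimetric chain and avian (x, y, z, DL)
    for both eye types via the visual model.  Gaussian mode: direct
    N(center, τ²) channel truths on the 8-bit scale, no spectra.
    """
    rng = _rng(config, 1)
    ids = [f"sp{i:04d}" for i in range(config.n_species)]
    patterned = rng.random(config.n_species) < config.patterned_fraction

    if config.truth_mode == "gaussian":
        rgb = rng.normal(config.truth_center, config.tau, size=(config.n_species, 3))
        truths = pd.DataFrame(
            {"unit_id": ids, "color_family": "gaussian", "patterned": patterned}
        )
        for i, c in enumerate(["R", "G", "B"]):
            truths[c] = rgb[:, i]
        return SpeciesSet(truths, {}, config)

    families = list(config.family_mix)
    probs = np.array([config.family_mix[f] for f in families])
    assigned = rng.choice(families, size=config.n_species, p=probs)
    cones_u = avian.cone_templates("U")
    cones_v = avian.cone_templates("V")
    rows, spectra = [], {}
    for sid, fam, pat in zip(ids, assigned, patterned):
        spec = Spectrum(_GRID, _family_spectrum(fam, rng))
        spectra[sid] = spec
        conv = spectrum_to_rgb8(spec)
        rgb = conv.rgb
        hsv = rgb_to_hsv(rgb)
        lab = rgb_to_lab(rgb)
        row = {
            "unit_id": sid,
            "color_family": fam,
            "patterned": bool(pat),
            "gamut_clipped": bool(conv.clipped),
            "R": rgb[0], "G": rgb[1], "B": rgb[2],
            "H": hsv[0], "S": hsv[1], "V": hsv[2],
            "L": lab[0], "a": lab[1], "b": lab[2],
        }
        for cones, eye in ((cones_u, "U"), (cones_v, "V")):
            t = avian.tetra_coordinates(avian.quantum_catch(spec, cones=cones))
            row[f"x_{eye}"] = t.x
            row[f"y_{eye}"] = t.y
            row[f"z_{eye}"] = t.z
            if eye == "U":
                row["DL"] = t.DL
        rows.append(row)
    return SpeciesSet(pd.DataFrame(rows), spectra, config)


def _observe_photos(
    truth8: np.ndarray,
    n_photos: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    gain_log_sd: float,
    wb_log_sd: float,
    sensor_sd: float,
    gain_bias: float = 1.0,
    roi_sd: float | None = None,
) -> np.ndarray:
    """Camera model for one unit: returns (n_photos, points, 3) 8-bit values.

    Exposure gain and white balance act per photo; sensor noise is a
    per-photo additive term (the component that does not average out within
    a photo) and within-ROI scatter is per point.  In the gamma pipeline all
    noise acts in linear RGB before clipping and encoding — the scene and
    sensor live upstream of the transfer curve — so a saturated photo's
    points sit exactly at 255.
    """
    n_pts = config.points_per_photo
    roi_sd = config.roi_sd if roi_sd is None else roi_sd
    gains = gain_bias * np.exp(rng.normal(0.0, gain_log_sd, size=(n_photos, 1, 1)))
    wb = np.exp(rng.normal(0.0, wb_log_sd, size=(n_photos, 1, 3)))
    if config.gamma:
        lin = _srgb_decode(np.asarray(truth8, float) / 255.0)[None, None, :]
        v = (
            lin * gains * wb
            + rng.normal(0.0, sensor_sd / 255.0, size=(n_photos, 1, 3))
            + rng.normal(0.0, roi_sd / 255.0, size=(n_photos, n_pts, 3))
        )
        return 255.0 * _srgb_encode(np.clip(v, 0.0, 1.0))
    pts = (
        np.asarray(truth8, float)[None, None, :] * gains * wb
        + rng.normal(0.0, sensor_sd, size=(n_photos, 1, 3))
        + rng.normal(0.0, roi_sd, size=(n_photos, n_pts, 3))
    )
    if config.clip:
        pts = np.clip(pts, 0.0, 255.0)
    return pts


def _photo_counts(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.photos_per_species, int):
        return np.full(config.n_species, config.photos_per_species)
    lo, hi = config.photos_per_species
    return rng.integers(lo, hi + 1, size=config.n_species)


def generate_photos(species: SpeciesSet, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Point-measurement table for the photo source (long format).

    Photo counts per species follow ``photos_per_species`` (fixed or uniform
    range); each photo gets its own exposure gain and white balance, then
    ``points_per_photo`` point replicates with within-ROI scatter.  Star
    ratings are drawn 1–5 with a distribution skewed toward good photos.
    """
    config = species.config if config is None else config
    rng = _rng(config, 2)
    counts = _photo_counts(config, rng)
    frames = []
    stars = np.array([1, 2, 3, 4, 5])
    star_p = np.array([0.05, 0.10, 0.25, 0.35, 0.25])
    for (_, row), n in zip(species.truths.iterrows(), counts):
        truth8 = np.array([row["R"], row["G"], row["B"]], dtype=float)
        pts = _observe_photos(
            truth8, int(n), config, rng,
            config.gain_log_sd, config.wb_log_sd, config.sensor_sd,
        )
        quality = rng.choice(stars, size=int(n), p=star_p)
        n_pts = config.points_per_photo
        frames.append(
            pd.DataFrame(
                {
                    "photo_id": np.repeat(
                        [f"{row['unit_id']}_p{j:03d}" for j in range(int(n))], n_pts
                    ),
                    "unit_id": row["unit_id"],
                    "point": np.tile(np.arange(1, n_pts + 1), int(n)),
                    "R": pts[:, :, 0].ravel(),
                    "G": pts[:, :, 1].ravel(),
                    "B": pts[:, :, 2].ravel(),
                    "quality": np.repeat(quality, n_pts),
                    "color_family": row["color_family"],
                    "patterned": row["patterned"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_museum(species: SpeciesSet, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Spectrometry table: 1–5 specimen replicates per species with ages.

    Specimen counts are 1 + Binomial(4, 0.405), giving a mean of 2.62
    specimens per species.  Specimen values are the species truth plus small
    replicate noise and an optional planted age drift (``age_slope`` per
    decade and channel).
    """
    config = species.config if config is None else config
    rng = _rng(config, 3)
    rows = []
    slope = np.asarray(config.age_slope, float)
    for _, row in species.truths.iterrows():
        n_spec = 1 + rng.binomial(4, 0.405)
        ages = rng.uniform(*config.age_range, size=n_spec)
        truth8 = np.array([row["R"], row["G"], row["B"]], dtype=float)
        vals = (
            truth8[None, :]
            + rng.normal(0.0, config.spec_replicate_sd, size=(n_spec, 3))
            + slope[None, :] * (ages[:, None] / 10.0)
        )
        if config.clip:
            vals = np.clip(vals, 0.0, 255.0)
        for j in range(n_spec):
            rows.append(
                {
                    "unit_id": row["unit_id"],
                    "specimen_id": f"{row['unit_id']}_m{j}",
                    "specimen_age": float(ages[j]),
                    "R": vals[j, 0], "G": vals[j, 1], "B": vals[j, 2],
                }
            )
    museum = pd.DataFrame(rows)
    hsv = rgb_to_hsv(museum[["R", "G", "B"]].to_numpy(float))
    lab = rgb_to_lab(museum[["R", "G", "B"]].to_numpy(float))
    for i, c in enumerate(["H", "S", "V"]):
        museum[c] = hsv[:, i]
    for i, c in enumerate(["L", "a", "b"]):
        museum[c] = lab[:, i]
    return museum


def museum_species_means(museum: pd.DataFrame) -> pd.DataFrame:
    """Unweighted specimen means per species, all channels, plus mean age."""
    channels = [c for c in ["R", "G", "B", "H", "S", "V", "L", "a", "b"] if c in museum.columns]
    g = museum.groupby("unit_id", sort=True)
    out = g[channels].mean()
    out["n_specimens"] = g.size()
    if "specimen_age" in museum.columns:
        out["specimen_age"] = g["specimen_age"].mean()
    return out.reset_index()


_FLOWER_TRUTH_LIN = {
    # linear-RGB petal reflectance truths (0-1): dark purple-red vs bright yellow
    "macroptilium_like": np.array([0.30, 0.05, 0.12]),
    "senna_like": np.array([0.85, 0.65, 0.08]),
}


def generate_flower_experiment(config: GeneratorConfig) -> pd.DataFrame:
    """Two synthetic flower species across the seven-treatment control ladder.

    Noise rises monotonically from spectrometry to citizen science; the
    ``overexposure`` map multiplies exposure for selected species ×
    treatment cells, driving bright channels into 8-bit saturation (the
    pathology that forces exclusion of that species downstream).
    """
    rng = _rng(config, 4)
    frames = []
    for species_name, lin in _FLOWER_TRUTH_LIN.items():
        truth8 = 255.0 * _srgb_encode(lin)
        for t in config.treatments:
            bias = t.gain_bias * config.overexposure.get((species_name, t.name), 1.0)
            pts = _observe_photos(
                truth8, t.n_photos, config, rng,
                t.gain_log_sd, t.wb_log_sd, t.sensor_sd,
                gain_bias=bias, roi_sd=t.roi_sd,
            )
            quality = rng.integers(t.quality[0], t.quality[1] + 1, size=t.n_photos)
            n_pts = config.points_per_photo
            frames.append(
                pd.DataFrame(
                    {
                        "photo_id": np.repeat(
                            [f"{species_name}_{t.name}_p{j:03d}" for j in range(t.n_photos)],
                            n_pts,
                        ),
                        "unit_id": f"{species_name}|{t.name}",
                        "species": species_name,
                        "treatment": t.name,
                        "point": np.tile(np.arange(1, n_pts + 1), t.n_photos),
                        "R": pts[:, :, 0].ravel(),
                        "G": pts[:, :, 1].ravel(),
                        "B": pts[:, :, 2].ravel(),
                        "quality": np.repeat(quality, n_pts),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def estimate_variance_components(photos: pd.DataFrame, channel: str = "R") -> tuple[float, float]:
    """Method-of-moments (τ̂², σ̂²) from a per-photo table.

    σ̂² is the pooled within-species variance of photo values; τ̂² is the
    between-species variance of species means minus the sampling share
    σ̂²·mean(1/n).  Used to confirm that planted generator parameters are
    recoverable from the generated data.
    """
    g = photos.groupby("unit_id")[channel]
    n = g.size()
    if (n < 2).all():
        raise ValueError("need species with at least 2 photos")
    within = g.var(ddof=1).dropna()
    sigma2 = float(np.average(within, weights=n[within.index] - 1))
    means = g.mean()
    tau2 = float(means.var(ddof=1) - sigma2 * np.mean(1.0 / n))
    return tau2, sigma2
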