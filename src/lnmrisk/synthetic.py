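"""Synthetic tissue-texture tiles and case cohorts for pipeline testing.

No public T1 colorectal-cancer whole-slide cohort exists for this task, so
this module fabricates the two kinds of input the pipeline consumes:

1. **Labeled texture tiles** for the ten tissue classes the tissue-type
   classifier distinguishes.  Textures are procedural — a flat background
   gray with dark elliptical blobs and Gaussian noise — with per-class
   parameters chosen to make classes separable by construction.  No
   histologic realism is attempted; separability is the only requirement.

2. **Case cohorts of tile-probability records** with the statistical
   structure the case-scoring stages assume: a ~10:1 negative:positive
   class imbalance (prevalence 7.8%), per-tile metastatic probabilities
   drawn from a two-level truncated-normal hierarchy whose class-conditional
   modes default to 0.53 (node-negative cases) and 0.73 (node-positive
   cases), cancer-class probabilities skewed toward 1, and tumor locations
   enriched for the rectum among node-positive cases.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import truncnorm

TISSUE_CLASSES = (
    "cancer",
    "non_tumoral_mucosa",
    "hyperplastic_mucosa",
    "adenoma",
    "lymphoid_tissue",
    "smooth_muscle",
    "vessels",
    "fat",
    "nerve",
    "background",
)

LOCATION_GROUPS = (1, 2, 3)  # 1: cecum/ascending/transverse, 2: descending/sigmoid, 3: rectum


@dataclass(frozen=True)
class TextureSpec:
    """Procedural texture parameters for one tissue class."""

    class_name: str
    blob_density: float = 8e-4  # blobs per pixel
    blob_radius: float = 6.0  # px
    background_gray: int = 200
    noise_sd: float = 8.0
    tile_size: int = 299

    def __post_init__(self) -> None:
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if not (0 <= self.background_gray <= 255):
            raise ValueError("background_gray must lie in [0, 255]")


def default_texture_specs(tile_size: int = 299) -> list[TextureSpec]:
    """One spec per tissue class, mutually separable by construction.

    Background grays are spaced ~15 levels apart and blob densities differ,
    so even a heavily downscaled tile identifies its class.  The
    ``background`` class is pure white with no blobs and no noise: its
    minimum gray is 255, so it is always rejected by the tissue pixel
    threshold, mirroring the role of non-material background on a slide.
    """
    grays = (120, 135, 150, 165, 180, 195, 210, 225, 240, 255)
    densities = (2e-3, 1.5e-3, 1.1e-3, 8e-4, 2.4e-3, 4e-4, 6e-4, 2e-4, 3e-4, 0.0)
    radii = (5.0, 7.0, 6.0, 8.0, 4.0, 9.0, 5.0, 10.0, 7.0, 1.0)
    specs = []
    for name, g, d, r in zip(TISSUE_CLASSES, grays, densities, radii):
        noise = 0.0 if name == "background" else 6.0
        specs.append(
            TextureSpec(
                class_name=name,
                blob_density=d,
                blob_radius=r,
                background_gray=g,
                noise_sd=noise,
                tile_size=tile_size,
            )
        )
    return specs


def render_texture_tile(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one uint8 grayscale tile from a texture spec."""
    s = spec.tile_size
    img = np.full((s, s), float(spec.background_gray))
    n_blobs = rng.poisson(spec.blob_density * s * s)
    if n_blobs:
        yy, xx = np.mgrid[0:s, 0:s]
        cx = rng.uniform(0, s, n_blobs)
        cy = rng.uniform(0, s, n_blobs)
        radii = rng.uniform(0.6, 1.4, n_blobs) * spec.blob_radius
        blob_gray = max(spec.background_gray - 90.0, 20.0)
        for x, y, r in zip(cx, cy, radii):
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
            img[mask] = blob_gray
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (s, s))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_tissue_tiles(
    specs: list[TextureSpec],
    n_per_class: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n_per_class`` labeled tiles for every spec.

    Returns ``(images, labels)`` where ``images`` has shape
    ``(n_classes * n_per_class, tile_size, tile_size)`` (uint8) and
    ``labels`` is the matching array of class names.  Deterministic under
    the seed.

    Raises
    ------
    ValueError
        On duplicate class names or ``n_per_class < 1``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not specs:
        raise ValueError("specs must be non-empty")
    names = [s.class_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names in specs: {names}")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for spec in specs:
        for _ in range(n_per_class):
            images.append(render_texture_tile(spec, rng))
            labels.append(spec.class_name)
    return np.stack(images), np.asarray(labels)


def save_tile_images(
    images: np.ndarray, labels: np.ndarray, out_dir: str | os.PathLike
) -> list[str]:
    """Write tiles as PNG under ``out_dir/<label>/<i>.png``."""
    paths = []
    counters: dict[str, int] = {}
    for img, lab in zip(images, labels):
        d = os.path.join(out_dir, str(lab))
        os.makedirs(d, exist_ok=True)
        i = counters.get(lab, 0)
        counters[lab] = i + 1
        p = os.path.join(d, f"{i:05d}.png")
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Cohorts of tile-probability records
# ---------------------------------------------------------------------------

# Location-group probabilities read from the published training-set
# contingency counts: node-negative 193/138/174 of 505, node-positive
# 10/9/24 of 43 (rectal enrichment among positives).
_LOC_ODDS_NEG = (193 / 505, 138 / 505, 174 / 505)
_LOC_ODDS_POS = (10 / 43, 9 / 43, 24 / 43)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic case cohort.

    ``p_met_mode_neg``/``p_met_mode_pos`` are the class-conditional modes of
    the per-tile metastatic probability (0.53 / 0.73 by default).  Tiles are
    drawn from a truncated normal centred on a case-level mean, which is
    itself drawn from a truncated normal centred on the class mode — the
    two-level hierarchy makes cases vary realistically.  ``p_met_sd`` is the
    within-case spread, ``case_mean_sd`` the between-case spread.
    Cancer-class probabilities are Beta-distributed, skewed toward 1.
    """

    n_cases: int = 600
    prevalence: float = 0.078
    tiles_per_case_log_mean: float = math.log(400.0)
    tiles_per_case_log_sd: float = 0.6
    p_met_mode_neg: float = 0.53
    p_met_mode_pos: float = 0.73
    p_met_sd: float = 0.12
    case_mean_sd: float = 0.06
    p_cancer_alpha: float = 6.0
    p_cancer_beta: float = 1.5
    location_odds_neg: tuple[float, float, float] = _LOC_ODDS_NEG
    location_odds_pos: tuple[float, float, float] = _LOC_ODDS_POS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for m in (self.p_met_mode_neg, self.p_met_mode_pos):
            if not 0 < m < 1:
                raise ValueError("metastatic-probability modes must lie in (0, 1)")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")


@dataclass
class SyntheticCohort:
    """Cases plus their tile-probability records."""

    cases: pd.DataFrame  # case_id, lnm_label, location_group
    tiles: pd.DataFrame  # case_id, tile_id, p_cancer, p_met
    config: CohortConfig = field(default=None)  # type: ignore[assignment]

    def write_csv(self, out_dir: str | os.PathLike) -> tuple[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        cp = os.path.join(out_dir, "cases.csv")
        tp = os.path.join(out_dir, "tiles.csv")
        self.cases.to_csv(cp, index=False)
        self.tiles.to_csv(tp, index=False)
        return cp, tp


def _truncnorm_01(mean, sd, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws on [0, 1]; equivalent to resampling to range."""
    mean = np.asarray(mean, dtype=float)
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Draw a full synthetic cohort from a :class:`CohortConfig`.

    Warns (does not fail) if the prevalence draw yields zero positive cases.
    Fully deterministic under ``config.seed``.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    n = config.n_cases
    positive = rng.random(n) < config.prevalence
    if not positive.any():
        warnings.warn(
            "no LNM-positive case drawn at this prevalence and cohort size",
            stacklevel=2,
        )

    locations = np.empty(n, dtype=int)
    for is_pos, odds in ((False, config.location_odds_neg), (True, config.location_odds_pos)):
        mask = positive == is_pos
        locations[mask] = rng.choice(LOCATION_GROUPS, size=int(mask.sum()), p=odds)

    n_tiles = np.maximum(
        1,
        np.round(
            rng.lognormal(
                config.tiles_per_case_log_mean, config.tiles_per_case_log_sd, n
            )
        ).astype(int),
    )

    modes = np.where(positive, config.p_met_mode_pos, config.p_met_mode_neg)
    case_means = _truncnorm_01(modes, config.case_mean_sd, rng)

    case_ids = np.array([f"case_{i:05d}" for i in range(n)])
    cases = pd.DataFrame(
        {
            "case_id": case_ids,
            "lnm_label": positive.astype(int),
            "location_group": locations,
        }
    )

    tile_case = np.repeat(np.arange(n), n_tiles)
    tile_means = case_means[tile_case]
    p_met = _truncnorm_01(tile_means, config.p_met_sd, rng)
    p_cancer = rng.beta(config.p_cancer_alpha, config.p_cancer_beta, tile_case.size)
    tile_idx = np.concatenate([np.arange(k) for k in n_tiles])
    tiles = pd.DataFrame(
        {
            "case_id": case_ids[tile_case],
            "tile_id": [f"t{j:05d}" for j in tile_idx],
            "p_cancer": p_cancer,
            "p_met": p_met,
        }
    )
    return SyntheticCohort(cases=cases, tiles=tiles, config=config)
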