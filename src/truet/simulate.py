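"""Synthetic IHC patches and survival cohorts with exact ground truth.

The patch generator renders DAB-brown positive cells and hematoxylin-blue
negative nuclei as anti-aliased filled ellipses on a pale stromal background.
The binary mask is computed from the same ellipse geometry that is painted,
so mask pixels are exactly the union of rendered positive-cell supports, and
with non-overlapping placement the number of 4-connected mask components
equals the number of rendered cells.

The cohort generator draws a latent immune-hot/cold state per patient; the
state drives the three marker densities (hot means sit above the 500/300/700
cells/mm^2 working thresholds, cold means below) and multiplies an
exponential baseline hazard, giving a known hazard ratio for downstream
stratification tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .types import MARKERS, AnnotatedPatch

__all__ = [
    "StainProfile",
    "PatchSimConfig",
    "CohortSimConfig",
    "simulate_patch",
    "simulate_dataset",
    "simulate_cohort",
    "save_patch",
    "load_patch",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = [
    "patient_id", "cd3_density", "cd4_density", "cd8_density",
    "time", "event", "age", "stage", "msi", "chemo",
]


@dataclass
class StainProfile:
    """Mean chromogen colours for one simulated institution."""

    positive_color_mean: tuple = (120, 72, 38)    # DAB brown
    negative_color_mean: tuple = (92, 102, 168)   # hematoxylin blue
    background_color_mean: tuple = (233, 228, 232)
    color_jitter_sd: float = 8.0
    institution_id: str = "inst0"

    def __post_init__(self):
        for c in (self.positive_color_mean, self.negative_color_mean,
                  self.background_color_mean):
            if not all(0 <= v <= 255 for v in c):
                raise ValueError("channel means must lie in [0, 255]")
        if self.color_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")

    def shifted(self, offset, jitter_sd=None, institution_id=None):
        """New profile with all mean colours offset (clipped to [0,255])."""
        off = np.asarray(offset, dtype=float)
        clip = lambda c: tuple(np.clip(np.asarray(c, float) + off, 0, 255))
        return StainProfile(
            clip(self.positive_color_mean),
            clip(self.negative_color_mean),
            clip(self.background_color_mean),
            self.color_jitter_sd if jitter_sd is None else jitter_sd,
            institution_id or self.institution_id,
        )


@dataclass
class PatchSimConfig:
    patch_height_px: int = 512
    patch_width_px: int = 512
    um_per_px: float = 0.25
    # count distributions: an int means an exact count, ("poisson", mean)
    # draws Poisson.
    positive_count_dist: object = ("poisson", 40.0)
    negative_count_dist: object = ("poisson", 120.0)
    cell_radius_range_px: tuple = (4.0, 9.0)
    overlap_allowed: bool = False
    max_place_retries: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.patch_height_px <= 0 or self.patch_width_px <= 0:
            raise ValueError("patch dimensions must be positive")
        rmin, rmax = self.cell_radius_range_px
        if rmin > rmax or rmin <= 0:
            raise ValueError("invalid cell radius range")
        mean = self.positive_count_dist
        if isinstance(mean, (tuple, list)) and float(mean[1]) < 0:
            raise ValueError("count mean must be >= 0")


@dataclass
class CohortSimConfig:
    n_patients: int = 300
    p_hot: float = 0.5
    # marker -> (mean, sd) cells/mm^2, drawn from a Gamma with that moment pair
    density_dist_hot: dict = field(default_factory=lambda: {
        "CD3": (900.0, 250.0), "CD4": (550.0, 150.0), "CD8": (1100.0, 300.0)})
    density_dist_cold: dict = field(default_factory=lambda: {
        "CD3": (250.0, 100.0), "CD4": (140.0, 60.0), "CD8": (350.0, 120.0)})
    hazard_ratio_cold_vs_hot: float = 3.0
    baseline_hazard: float = 0.045       # events / year for the hot group
    censoring_rate: float = 0.03         # / year; 0 disables random censoring
    max_followup: float = 5.0            # years; inf disables the cap
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_hot <= 1.0:
            raise ValueError("p_hot must be a probability")
        if self.hazard_ratio_cold_vs_hot <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


def _draw_count(dist, rng):
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    kind, mean = dist
    if kind != "poisson":
        raise ValueError(f"unknown count distribution {kind!r}")
    return int(rng.poisson(mean))


def _ellipse_alpha(h, w, cy, cx, a, b, theta):
    """Subpixel (4x4) coverage of a rotated ellipse, clipped to the patch."""
    pad = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return y0, x0, np.zeros((0, 0))
    sub = (np.arange(4) + 0.5) / 4.0
    yy = (y0 + np.add.outer(np.arange(y1 - y0), sub)).reshape(-1)  # (ny*4,)
    xx = (x0 + np.add.outer(np.arange(x1 - x0), sub)).reshape(-1)
    dy = yy[:, None] - cy
    dx = xx[None, :] - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = (u * u + v * v) <= 1.0
    alpha = inside.reshape(y1 - y0, 4, x1 - x0, 4).mean(axis=(1, 3))
    return y0, x0, alpha


def _paint(img, y0, x0, alpha, color):
    h, w = alpha.shape
    region = img[y0 : y0 + h, x0 : x0 + w]
    region *= (1.0 - alpha)[..., None]
    region += alpha[..., None] * np.asarray(color, dtype=float)


def _place_cells(rng, n_wanted, radius_range, h, w, overlap_allowed, retries):
    """Sample (cy, cx, a, b, theta) tuples fully inside the patch.

    Non-overlap is enforced by rejection sampling on bounding circles with a
    1.5 px margin, which also keeps the thresholded masks of distinct cells
    4-disconnected. Returns possibly fewer cells than requested when the
    retry budget is exhausted.
    """
    rmin, rmax = radius_range
    if 2 * rmax + 4 > min(h, w):
        raise ValueError("cell radius too large for patch size")
    cells = []
    for _ in range(n_wanted):
        placed = False
        for _ in range(retries):
            a = rng.uniform(rmin, rmax)
            ecc = rng.uniform(0.0, 0.6)
            b = a * np.sqrt(1.0 - ecc**2)
            theta = rng.uniform(0.0, np.pi)
            margin = a + 2.0
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if overlap_allowed or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (a + oa + 1.5) ** 2
                for oy, ox, oa, _, _ in cells
            ):
                cells.append((cy, cx, a, b, theta))
                placed = True
                break
        if not placed:
            break
    return cells


def simulate_patch(config: PatchSimConfig, stain: StainProfile,
                   marker: str = "CD3", patient_id: str = "P000",
                   rng: np.random.Generator | None = None) -> AnnotatedPatch:
    """Render one patch; the mask marks exactly the positive-cell pixels."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.patch_height_px, config.patch_width_px

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(stain.background_color_mean, dtype=float)
    img += rng.normal(0.0, 3.0, size=img.shape)

    n_neg = _draw_count(config.negative_count_dist, rng)
    for cy, cx, a, b, theta in _place_cells(
        rng, n_neg, config.cell_radius_range_px, h, w, True, config.max_place_retries
    ):
        color = np.asarray(stain.negative_color_mean, float) + rng.normal(
            0.0, stain.color_jitter_sd, 3
        )
        y0, x0, alpha = _ellipse_alpha(h, w, cy, cx, a, b, theta)
        _paint(img, y0, x0, alpha, np.clip(color, 0, 255))

    n_pos = _draw_count(config.positive_count_dist, rng)
    pos_cells = _place_cells(
        rng, n_pos, config.cell_radius_range_px, h, w,
        config.overlap_allowed, config.max_place_retries,
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    for cy, cx, a, b, theta in pos_cells:
        color = np.asarray(stain.positive_color_mean, float) + rng.normal(
            0.0, stain.color_jitter_sd, 3
        )
        y0, x0, alpha = _ellipse_alpha(h, w, cy, cx, a, b, theta)
        _paint(img, y0, x0, alpha, np.clip(color, 0, 255))
        mask[y0 : y0 + alpha.shape[0], x0 : x0 + alpha.shape[1]] |= (
            alpha >= 0.5
        ).astype(np.uint8)

    return AnnotatedPatch(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        mask=mask,
        marker=marker,
        patient_id=patient_id,
        institution_id=stain.institution_id,
        n_cells=len(pos_cells),
    )


def simulate_dataset(config: PatchSimConfig, stains: list[StainProfile],
                     n_patients: int, patches_per_patient: int,
                     markers: tuple = MARKERS) -> list[AnnotatedPatch]:
    """Patches for a cohort; each patient gets one round-robin stain profile.

    Per-patient randomness is seeded from ``SeedSequence([config.seed,
    patient_index])``, so a patient's patches do not depend on how many other
    patients are generated.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    patches = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        stain = stains[i % len(stains)]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        for marker in markers:
            for _ in range(patches_per_patient):
                patches.append(simulate_patch(config, stain, marker, pid, rng=rng))
    return patches


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Survival cohort with a latent hot/cold state driving marker densities.

    Event times are exponential with hazard ``baseline_hazard`` (hot) or
    ``baseline_hazard * hazard_ratio_cold_vs_hot`` (cold); follow-up is the
    minimum of the event time, an exponential censoring time and
    ``max_followup``. The returned frame keeps the latent state in
    ``latent_hot`` for oracle checks; the CSV writer drops it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    hot = rng.random(n) < config.p_hot

    dens = {}
    for marker in MARKERS:
        mu_h, sd_h = config.density_dist_hot[marker]
        mu_c, sd_c = config.density_dist_cold[marker]
        draw = lambda mu, sd, size: rng.gamma((mu / sd) ** 2, sd**2 / mu, size)
        d = np.where(hot, draw(mu_h, sd_h, n), draw(mu_c, sd_c, n))
        dens[marker.lower() + "_density"] = d

    hazard = config.baseline_hazard * np.where(
        hot, 1.0, config.hazard_ratio_cold_vs_hot
    )
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.max_followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "cd3_density": dens["cd3_density"],
        "cd4_density": dens["cd4_density"],
        "cd8_density": dens["cd8_density"],
        "time": time,
        "event": event,
        "age": np.clip(np.round(rng.normal(68, 10, n)), 30, 95).astype(int),
        "stage": rng.choice(["II", "III", "IV"], n, p=[0.45, 0.40, 0.15]),
        "msi": rng.binomial(1, 0.15, n),
        "chemo": rng.binomial(1, 0.50, n),
        "latent_hot": hot.astype(int),
    })


# ---------------------------------------------------------------------------
# disk I/O

def patch_basename(patch: AnnotatedPatch, idx: int) -> str:
    return f"{patch.patient_id}_{patch.marker}_{idx}"


def save_patch(patch: AnnotatedPatch, outdir, idx: int) -> None:
    stem = patch_basename(patch, idx)
    Image.fromarray(patch.image).save(f"{outdir}/{stem}.png")
    Image.fromarray(patch.mask * 255).save(f"{outdir}/{stem}_mask.png")


def load_patch(image_path, mask_path=None) -> AnnotatedPatch:
    image_path = str(image_path)
    stem = image_path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    pid, marker, _ = stem.split("_")[:3]
    image = np.asarray(Image.open(image_path).convert("RGB"))
    if mask_path is None:
        mask_path = image_path[: -len(".png")] + "_mask.png"
    mask = (np.asarray(Image.open(mask_path).convert("L")) >= 128).astype(np.uint8)
    return AnnotatedPatch(image=image, mask=mask, marker=marker, patient_id=pid)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def config_from_dict(cls, payload: dict):
    """Build any of the simulation configs from a parsed YAML/JSON mapping."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(payload)
    for key in ("positive_count_dist", "negative_count_dist"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)
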