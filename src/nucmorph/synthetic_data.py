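"""Seeded synthetic fixtures: nucleus images, survival cohorts, rating panels.

Every generator is a pure function of its spec (the seed is part of the
spec), so identical specs give bit-identical outputs.  The image generator
draws densely packed elliptical nuclei with a controllable area
distribution (anisokaryosis), radial contour irregularity and optional
overlap, and returns exact ground truth: an instance label mask plus the
boundary polygon of every nucleus.  The mask is produced *by rasterizing
the polygons*, so polygon/mask consistency holds by construction when
overlap is disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaLaw:
    """Log-normal law for nuclear cross-section area, in µm²."""

    mean_um2: float = 30.0
    sd_um2: float = 10.0

    def __post_init__(self) -> None:
        if self.mean_um2 <= 7.0:
            raise ValueError("mean nuclear area must exceed the 7 µm² noise floor")
        if self.sd_um2 < 0:
            raise ValueError("sd_um2 must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd_um2 == 0:
            return np.full(n, self.mean_um2)
        sigma2 = np.log1p((self.sd_um2 / self.mean_um2) ** 2)
        mu = np.log(self.mean_um2) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


@dataclass(frozen=True)
class AxisRatioLaw:
    """Uniform law for the major/minor axis ratio, restricted to [1, 4]."""

    low: float = 1.1
    high: float = 2.2

    def __post_init__(self) -> None:
        if not (1.0 <= self.low <= self.high <= 4.0):
            raise ValueError("axis ratio support must lie within [1, 4]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class StainPalette:
    """Hematoxylin-like rendering: dark nuclei on a pale background.

    Contrast only — no attempt at realistic chromatin texture.
    """

    foreground_rgb: tuple[float, float, float] = (110.0, 75.0, 150.0)
    background_rgb: tuple[float, float, float] = (235.0, 228.0, 238.0)
    noise_sd: float = 8.0


@dataclass(frozen=True)
class ImageSpec:
    """Geometry of one simulated ROI.

    Defaults mirror a 0.1185 mm² field (0.5 HPF) at 0.25 µm/pixel with a
    4:3 aspect ratio, i.e. a 1590×1192 px canvas, and ~630 nuclei per ROI.
    """

    width_px: int = 1590
    height_px: int = 1192
    resolution_um_per_px: float = 0.25
    n_nuclei: int = 630
    area_law: AreaLaw = field(default_factory=AreaLaw)
    axis_ratio_law: AxisRatioLaw = field(default_factory=AxisRatioLaw)
    irregularity: float = 0.10
    overlap_fraction: float = 0.0
    stain_palette: StainPalette = field(default_factory=StainPalette)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas must have positive area")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")


# --------------------------------------------------------------------------
# nucleus image generation
# --------------------------------------------------------------------------

_N_VERTICES = 72
_HARMONICS = (2, 3, 4, 5)
_MAX_PLACEMENT_TRIES = 100


def _nucleus_polygon(rng: np.random.Generator, area_px: float, axis_ratio: float,
                     irregularity: float) -> np.ndarray:
    """One closed boundary polygon (N×2, [x, y]) centred on the origin.

    An ellipse of the requested area/axis-ratio at a random orientation,
    perturbed radially by a low-order Fourier series whose RMS amplitude is
    ``irregularity`` times the mean radius, then rescaled so the polygon
    area matches ``area_px`` exactly (the perturbation must not bias the
    area law).
    """
    b = np.sqrt(area_px / (np.pi * axis_ratio))
    a = axis_ratio * b
    theta = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    if irregularity > 0:
        amps = rng.normal(size=len(_HARMONICS))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_HARMONICS))
        wave = np.zeros_like(theta)
        for k, amp, ph in zip(_HARMONICS, amps, phases):
            wave += amp * np.cos(k * theta + ph)
        rms = np.sqrt(np.mean(wave**2))
        if rms > 0:
            mean_radius = np.sqrt(a * b)
            wave *= irregularity * mean_radius / rms
        r = np.clip(r_ell + wave, 0.25 * np.min(r_ell), None)
    else:
        r = r_ell

    phi = rng.uniform(0.0, 2.0 * np.pi)
    x = r * np.cos(theta + phi)
    y = r * np.sin(theta + phi)

    # shoelace rescale to the target area
    poly_area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if poly_area > 0:
        s = np.sqrt(area_px / poly_area)
        x, y = x * s, y * s
    return np.column_stack([x, y])


def _rasterize(poly_xy: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=shape)
    return rr, cc


def generate_nucleus_image(
    spec: ImageSpec,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Generate one ROI: RGB image, instance label mask, boundary polygons.

    Returns
    -------
    image : (H, W, 3) uint8
    labels : (H, W) uint16 — instance labels 1..K contiguous, 0 = background
    polygons : list of ``{"label": k, "vertices": [[x, y], ...]}`` with
        0-based pixel coordinates, x = column.

    Placement is rejection-sampled; with ``overlap_fraction = 0`` instances
    are pairwise disjoint with at least a one-pixel gap.  If a nucleus
    cannot be placed within a bounded number of tries it is dropped and the
    shortfall is reported through a warning (K < n_nuclei).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    labels = np.zeros((h, w), dtype=np.uint16)
    occupied = np.zeros((h, w), dtype=bool)  # foreground dilated by 1 px

    areas_um2 = spec.area_law.sample(rng, spec.n_nuclei)
    ratios = spec.axis_ratio_law.sample(rng, spec.n_nuclei)
    res2 = spec.resolution_um_per_px**2

    polygons: list[dict] = []
    k = 0
    for i in range(spec.n_nuclei):
        area_px = areas_um2[i] / res2
        poly = _nucleus_polygon(rng, area_px, ratios[i], spec.irregularity)
        may_overlap = rng.random() < spec.overlap_fraction
        r_max = float(np.max(np.hypot(poly[:, 0], poly[:, 1])))
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cx = rng.uniform(r_max + 1, w - r_max - 1) if w > 2 * (r_max + 1) else w / 2
            cy = rng.uniform(r_max + 1, h - r_max - 1) if h > 2 * (r_max + 1) else h / 2
            # vertices are stored rounded to 3 decimals; rasterize the
            # rounded polygon so the JSON round-trip reproduces the mask
            shifted = np.round(poly + np.array([cx, cy]), 3)
            rr, cc = _rasterize(shifted, (h, w))
            if rr.size == 0:
                continue
            if not may_overlap and occupied[rr, cc].any():
                continue
            k += 1
            labels[rr, cc] = k  # overlap pixels go to the later label
            # reserve the full 8-neighbourhood so disjoint instances never
            # touch, even diagonally (they must survive 8-connectivity
            # relabeling as separate components)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    occupied[np.clip(rr + dr, 0, h - 1),
                             np.clip(cc + dc, 0, w - 1)] = True
            polygons.append({"label": k, "vertices": shifted.tolist()})
            placed = True
            break
        if not placed:
            continue

    if k < spec.n_nuclei:
        warnings.warn(
            f"placed only {k} of {spec.n_nuclei} nuclei before exhausting retries",
            stacklevel=2,
        )

    pal = spec.stain_palette
    image = np.empty((h, w, 3), dtype=np.uint8)
    fg = labels > 0
    for ch in range(3):
        plane = np.full((h, w), pal.background_rgb[ch], dtype=float)
        plane[fg] = pal.foreground_rgb[ch]
        plane += rng.normal(0.0, pal.noise_sd, size=(h, w))
        image[..., ch] = np.clip(plane, 0, 255).astype(np.uint8)

    return image, labels, polygons


def rasterize_polygons(polygons: list[dict], shape: tuple[int, int]) -> np.ndarray:
    """Rebuild a label mask from boundary polygons (later label wins)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for entry in sorted(polygons, key=lambda e: e["label"]):
        poly = np.asarray(entry["vertices"], dtype=float)
        rr, cc = _rasterize(poly, shape)
        labels[rr, cc] = entry["label"]
    return labels


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """One per-case covariate with its planted log-hazard coefficient."""

    name: str
    distribution: str = "normal"   # "normal" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5                 # binary success probability
    log_hr: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.distribution == "binary":
            return rng.binomial(1, self.p, size=n).astype(float)
        raise ValueError(f"unknown covariate distribution {self.distribution!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Proportional-hazards cohort: exponential baseline, planted log-HRs,
    uniform administrative censoring, and a hard follow-up cap in days."""

    n_cases: int = 46
    covariates: tuple[CovariateSpec, ...] = (
        CovariateSpec(name="sd_area_um2", distribution="normal",
                      mean=16.0, sd=6.0, log_hr=0.0),
    )
    baseline_rate_per_day: float = 1.0 / 400.0
    censor_horizon_days: float = 2000.0
    followup_cap_days: float = 250.0
    other_death_frac: float = 0.0   # fraction of pre-cap censorings that are
    seed: int = 0                   # tumor-unrelated deaths (rest are "lost")

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("a cohort needs at least 2 cases")
        if self.baseline_rate_per_day <= 0:
            raise ValueError("baseline hazard rate must be positive")
        if self.censor_horizon_days <= 0 or self.followup_cap_days <= 0:
            raise ValueError("times must be positive")


def generate_outcome_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate an outcome table: case_id, covariates, time_days, event flag.

    Event times are exponential with rate ``baseline × exp(Σ β·x)``; each
    case also draws a uniform censoring time on (0, censor_horizon] and
    everything is truncated at the follow-up cap.  ``event`` is the 0/1
    tumor-death indicator; ``status`` carries the categorical outcome
    ("tumor-death", "other-death", "lost", "alive") consumed by cohort
    preparation downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    cols = {c.name: c.sample(rng, n) for c in spec.covariates}
    lp = np.zeros(n)
    for c in spec.covariates:
        lp += c.log_hr * cols[c.name]
    rate = spec.baseline_rate_per_day * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, spec.censor_horizon_days, size=n)

    cap = spec.followup_cap_days
    time = np.minimum(np.minimum(t_event, t_censor), cap)
    event = (t_event <= np.minimum(t_censor, cap)).astype(int)

    status = np.where(event == 1, "tumor-death", "alive").astype(object)
    early = (event == 0) & (time < cap)
    if early.any():
        u = rng.random(n)
        status[early] = "lost"
        status[early & (u < spec.other_death_frac)] = "other-death"

    if event.sum() == 0:
        warnings.warn("degenerate cohort: all cases censored", stacklevel=2)

    df = pd.DataFrame({"case_id": [f"case{i:04d}" for i in range(n)], **cols})
    df["time_days"] = time
    df["event"] = event
    df["status"] = status
    return df


# --------------------------------------------------------------------------
# multi-rater ordinal panels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterSpec:
    """Threshold raters: each rater bins a noisy copy of a latent score.

    ``cutpoints`` holds one strictly increasing cutpoint vector per rater
    (length ``n_categories - 1``); ``noise_sd`` is per-rater measurement
    noise on the latent scale.  Three categories emulate anisokaryosis
    grading, two emulate the shape-irregularity call.
    """

    cutpoints: tuple[tuple[float, ...], ...]
    noise_sd: tuple[float, ...]
    n_categories: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cutpoints) < 1:
            raise ValueError("at least one rater required")
        if len(self.noise_sd) != len(self.cutpoints):
            raise ValueError("one noise SD per rater")
        for cp in self.cutpoints:
            if len(cp) != self.n_categories - 1:
                raise ValueError("cutpoint count must be n_categories - 1")
            if any(b <= a for a, b in zip(cp, cp[1:])):
                raise ValueError("cutpoints must be strictly increasing")

    @property
    def n_raters(self) -> int:
        return len(self.cutpoints)


def generate_rating_panel(latent_scores: np.ndarray, spec: RaterSpec) -> pd.DataFrame:
    """Ordinal category per (rater, case): one column per rater, 1-based
    categories.  With shared cutpoints and zero noise all raters agree."""
    latent = np.asarray(latent_scores, dtype=float)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for r in range(spec.n_raters):
        noisy = latent + rng.normal(0.0, spec.noise_sd[r], size=latent.shape)
        cats = np.ones(latent.shape, dtype=int)
        for cp in spec.cutpoints[r]:
            cats += (noisy > cp).astype(int)
        out[f"rater{r + 1}"] = cats
    df = pd.DataFrame(out)
    df.insert(0, "case_id", [f"case{i:04d}" for i in range(len(latent))])
    return df
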