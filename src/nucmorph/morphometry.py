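"""Per-nucleus shape descriptors and the per-ROI morphometric profile.

Size is quantified by the nuclear cross-section area in µm²; shape by
eccentricity (elongation of the moment-matched ellipse, 0 = circle) and
solidity (area over convex-hull area, 1 = no contour indentations).  The
ROI profile aggregates each descriptor with mean / median / SD / skewness,
plus — for area — the mean and median of the largest 10 % of nuclei, the
90th percentile, and the percentage of karyomegalic nuclei above two fixed
thresholds (defaults 42.3 and 50.5 µm², the 90th percentile and twice the
median of a pooled reference annotation set).  Because a larger solidity
means a *more* regular contour, the profile also carries the inverted
values 1 − mean and 1 − median solidity so that larger numbers read as
more irregular.

Estimator conventions: SD uses the sample (n−1) denominator and skewness
the adjusted Fisher–Pearson standardized third moment, matching mainstream
statistical software.  The "largest 10 %" is the ⌈0.1·n⌉ largest
instances; percentiles interpolate linearly between order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

from .instance_extraction import NucleusInstance

logger = logging.getLogger(__name__)

_ECC_CAP = 1.0 - 1e-9


@dataclass(frozen=True)
class KaryomegalyThresholds:
    """Area cutoffs (µm²) above which a nucleus counts as karyomegalic."""

    p90_um2: float = 42.3
    twice_median_um2: float = 50.5

    def __post_init__(self) -> None:
        if self.p90_um2 <= 0 or self.twice_median_um2 <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class InstanceShape:
    area_um2: float
    eccentricity: float
    solidity: float


@dataclass(frozen=True)
class MorphometryProfile:
    """The per-ROI parameter vector (one row of the profile CSV)."""

    n_instances: int
    area_mean: float
    area_median: float
    area_sd: float
    area_skewness: float
    area_largest10_mean: float
    area_largest10_median: float
    area_p90: float
    area_pct_above_p90_threshold: float
    area_pct_above_twice_median_threshold: float
    ecc_mean: float
    ecc_median: float
    ecc_sd: float
    ecc_skewness: float
    sol_mean: float
    sol_median: float
    sol_sd: float
    sol_skewness: float
    irregularity_mean: float       # 1 − mean solidity
    irregularity_median: float     # 1 − median solidity

    def as_dict(self) -> dict:
        return asdict(self)


def measure_instance(
    pixel_coords: np.ndarray, resolution_um_per_px: float
) -> InstanceShape:
    """Shape descriptors from a pixel set ((N, 2) array of (row, col)).

    Eccentricity comes from the ellipse matching the pixel set's second
    central moments, √(1 − λ₂/λ₁); solidity is pixel count over the pixel
    count of the rasterized convex hull, so a convex rasterized shape
    scores exactly 1.  Degenerate sets (single pixel, collinear pixels)
    get eccentricity 0 and 1⁻ respectively rather than an error.
    """
    coords = np.asarray(pixel_coords, dtype=np.intp)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("pixel_coords must be a non-empty (N, 2) array")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")

    area = len(coords) * resolution_um_per_px**2
    if len(coords) == 1:
        return InstanceShape(area_um2=area, eccentricity=0.0, solidity=1.0)

    r0 = coords.min(axis=0)
    patch = np.zeros(coords.max(axis=0) - r0 + 1, dtype=np.uint8)
    patch[coords[:, 0] - r0[0], coords[:, 1] - r0[1]] = 1
    rp = regionprops(patch)[0]
    ecc = float(rp.eccentricity)
    if ecc >= 1.0:
        logger.debug("capping eccentricity of a degenerate (collinear) pixel set")
        ecc = _ECC_CAP
    return InstanceShape(area_um2=area, eccentricity=ecc, solidity=float(rp.solidity))


def invert_solidity(mean_or_median_solidity: float) -> float:
    """Irregularity score ``1 − solidity`` (larger = more irregular)."""
    if not 0.0 < mean_or_median_solidity <= 1.0:
        raise ValueError("solidity must lie in (0, 1]")
    return 1.0 - mean_or_median_solidity


def derive_karyomegaly_thresholds(
    reference_areas_um2: np.ndarray | None = None,
) -> KaryomegalyThresholds:
    """(90th percentile, 2 × median) of a reference area distribution.

    With no reference supplied, returns the published defaults
    (42.3, 50.5) µm² derived from a pooled ground-truth annotation set.
    """
    if reference_areas_um2 is None:
        return KaryomegalyThresholds()
    areas = np.asarray(reference_areas_um2, dtype=float)
    if areas.size < 10:
        raise ValueError("need at least 10 reference areas")
    return KaryomegalyThresholds(
        p90_um2=float(np.percentile(areas, 90)),
        twice_median_um2=float(2.0 * np.median(areas)),
    )


def _skew(x: np.ndarray) -> float:
    # adjusted Fisher–Pearson; needs n ≥ 3 and nonzero spread
    if len(x) < 3 or np.ptp(x) == 0:
        return math.nan
    return float(stats.skew(x, bias=False))


def _sd(x: np.ndarray) -> float:
    if len(x) < 2:
        return math.nan
    return float(np.std(x, ddof=1))


def profile_roi(
    instances: list[NucleusInstance],
    thresholds: KaryomegalyThresholds = KaryomegalyThresholds(),
) -> MorphometryProfile:
    """Aggregate instance shapes into the per-ROI profile.

    SD needs ≥ 2 instances and skewness ≥ 3; below that the fields are
    NaN ("undefined") rather than an error.  The profile is invariant to
    the ordering of the instance list.
    """
    if not instances:
        raise ValueError("cannot profile an ROI with zero instances")
    shapes = [
        measure_instance(i.coords, i.resolution_um_per_px) for i in instances
    ]
    area = np.array([s.area_um2 for s in shapes])
    ecc = np.array([s.eccentricity for s in shapes])
    sol = np.array([s.solidity for s in shapes])

    n = len(area)
    k = math.ceil(0.1 * n)
    largest = np.sort(area)[-k:]

    sol_mean, sol_median = float(sol.mean()), float(np.median(sol))
    return MorphometryProfile(
        n_instances=n,
        area_mean=float(area.mean()),
        area_median=float(np.median(area)),
        area_sd=_sd(area),
        area_skewness=_skew(area),
        area_largest10_mean=float(largest.mean()),
        area_largest10_median=float(np.median(largest)),
        area_p90=float(np.percentile(area, 90)),
        area_pct_above_p90_threshold=float(100.0 * np.mean(area > thresholds.p90_um2)),
        area_pct_above_twice_median_threshold=float(
            100.0 * np.mean(area > thresholds.twice_median_um2)
        ),
        ecc_mean=float(ecc.mean()),
        ecc_median=float(np.median(ecc)),
        ecc_sd=_sd(ecc),
        ecc_skewness=_skew(ecc),
        sol_mean=sol_mean,
        sol_median=sol_median,
        sol_sd=_sd(sol),
        sol_skewness=_skew(sol),
        irregularity_mean=invert_solidity(sol_mean),
        irregularity_median=invert_solidity(sol_median),
    )


def profiles_to_table(profiles: dict[str, MorphometryProfile]) -> pd.DataFrame:
    """One CSV-ready row per ROI, keyed by ROI id."""
    rows = []
    for roi_id, prof in profiles.items():
        row = {"roi_id": roi_id}
        row.update(prof.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
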