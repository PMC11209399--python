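"""Binary mask → measured nucleus instances.

Connected-component labeling (8-connectivity by default), pixel→µm²
conversion from the scan resolution, and the small-object noise filter:
objects below 7 µm² are considered too small to be nuclei and removed.
The removal rule is a strict inequality, so an object of exactly 7 µm²
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

DEFAULT_MIN_AREA_UM2 = 7.0


@dataclass(frozen=True)
class NucleusInstance:
    """One segmented nucleus: its pixel set plus basic measurements."""

    label: int
    pixel_count: int
    area_um2: float
    centroid: tuple[float, float]       # (row, col)
    coords: np.ndarray                  # (N, 2) int array of (row, col)
    resolution_um_per_px: float


def pixels_to_area(pixel_count: int, resolution_um_per_px: float) -> float:
    """Convert a pixel count to µm² via the scan resolution (µm/pixel)."""
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    return pixel_count * resolution_um_per_px**2


def label_components(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Label maximal connected foreground sets 1..K (0 stays background).

    ``connectivity`` follows scikit-image: 1 = 4-neighbourhood,
    2 = 8-neighbourhood (default).
    """
    return sk_label(np.asarray(mask) > 0, connectivity=connectivity)


def extract_instances(
    label_mask: np.ndarray,
    resolution_um_per_px: float,
    exclude_border: bool = False,
) -> list[NucleusInstance]:
    """Turn a label mask into instance records with areas in µm².

    Border-touching instances are retained by default (margin exclusion is
    a manual-protocol rule, not an algorithmic one); pass
    ``exclude_border=True`` to drop them.
    """
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    lm = np.asarray(label_mask)
    h, w = lm.shape
    out: list[NucleusInstance] = []
    for rp in regionprops(lm):
        if exclude_border:
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        out.append(
            NucleusInstance(
                label=int(rp.label),
                pixel_count=int(rp.area),
                area_um2=pixels_to_area(int(rp.area), resolution_um_per_px),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                coords=rp.coords.copy(),
                resolution_um_per_px=resolution_um_per_px,
            )
        )
    return out


def filter_small_objects(
    instances: list[NucleusInstance],
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> list[NucleusInstance]:
    """Drop noise objects with area strictly below ``min_area_um2``.

    Original labels are preserved on the survivors.
    """
    return [inst for inst in instances if inst.area_um2 >= min_area_um2]


def instances_to_mask(instances: list[NucleusInstance], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize instance records back into a label mask."""
    lm = np.zeros(shape, dtype=np.int32)
    for inst in instances:
        lm[inst.coords[:, 0], inst.coords[:, 1]] = inst.label
    return lm


def instances_to_table(instances: list[NucleusInstance]) -> pd.DataFrame:
    """Flat per-instance table (label, pixel_count, area_um2, centroid)."""
    return pd.DataFrame(
        {
            "label": [i.label for i in instances],
            "pixel_count": [i.pixel_count for i in instances],
            "area_um2": [i.area_um2 for i in instances],
            "centroid_row": [i.centroid[0] for i in instances],
            "centroid_col": [i.centroid[1] for i in instances],
        }
    )
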