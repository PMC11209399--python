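"""The manual-morphometry sampling protocol on a 5×6 grid.

A pathologist doing manual morphometry does not trace every nucleus in an
ROI; the field protocol overlays a 5×6 grid (30 equal cells), walks the
cells in a meandering order starting from the upper-left corner, annotates
every nucleus in each visited cell, and stops at the first cell boundary
where at least 100 nuclei have been annotated (the current cell is always
completed).  Nuclei cut by the image margin are excluded; nuclei crossing
an interior grid line are annotated whole and counted once, in the
earliest visited cell that contains any of their pixels.

This module reproduces that procedure deterministically on polygon
annotations, so manual-style subsamples can be drawn from exact synthetic
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon


@dataclass(frozen=True)
class GridPlan:
    """A rows×cols partition of the ROI with a meandering traversal order.

    Cell boundaries are integer pixel edges that tile the image exactly;
    the traversal alternates left→right and right→left by row.
    """

    width_px: int
    height_px: int
    rows: int = 5
    cols: int = 6
    row_edges: tuple[int, ...] = field(init=False)
    col_edges: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.width_px < self.cols or self.height_px < self.rows:
            raise ValueError("image smaller than the grid")
        object.__setattr__(
            self, "row_edges",
            tuple(round(i * self.height_px / self.rows) for i in range(self.rows + 1)),
        )
        object.__setattr__(
            self, "col_edges",
            tuple(round(j * self.width_px / self.cols) for j in range(self.cols + 1)),
        )

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def traversal_order(self) -> list[tuple[int, int]]:
        """Meander: row 0 left→right, row 1 right→left, alternating."""
        order = []
        for r in range(self.rows):
            cs = range(self.cols) if r % 2 == 0 else range(self.cols - 1, -1, -1)
            order.extend((r, c) for c in cs)
        return order

    def cell_of_pixel(self, row: int, col: int) -> tuple[int, int]:
        r = int(np.searchsorted(self.row_edges, row, side="right")) - 1
        c = int(np.searchsorted(self.col_edges, col, side="right")) - 1
        return (min(r, self.rows - 1), min(c, self.cols - 1))


def _polygon_pixels(vertices: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_polygon(vertices[:, 1], vertices[:, 0], shape=shape)
    return rr, cc


def assign_to_grid(
    polygons: list[dict], plan: GridPlan
) -> dict[int, int | None]:
    """Assign each annotation to one grid cell (or None if margin-cut).

    An annotation touching the image border (its pixels reach row/col 0 or
    the last row/col) is excluded per the margin rule.  An annotation that
    straddles interior grid lines is assigned to the earliest cell in the
    meandering traversal order containing any of its pixels, so it is
    counted exactly once.

    Returns a mapping ``label -> traversal position`` (None = excluded).
    """
    shape = (plan.height_px, plan.width_px)
    order = plan.traversal_order()
    pos_of_cell = {cell: t for t, cell in enumerate(order)}
    out: dict[int, int | None] = {}
    for entry in polygons:
        verts = np.asarray(entry["vertices"], dtype=float)
        rr, cc = _polygon_pixels(verts, shape)
        if rr.size == 0:
            out[entry["label"]] = None
            continue
        if (rr.min() == 0 or cc.min() == 0
                or rr.max() == plan.height_px - 1 or cc.max() == plan.width_px - 1):
            out[entry["label"]] = None      # margin-cut → excluded
            continue
        cells = {plan.cell_of_pixel(int(r), int(c)) for r, c in zip(rr, cc)}
        out[entry["label"]] = min(pos_of_cell[cell] for cell in cells)
    return out


def grid_subsample(
    polygons: list[dict], plan: GridPlan, min_n: int = 100
) -> tuple[list[dict], list[dict]]:
    """Accumulate whole cells in meander order until ≥ ``min_n`` nuclei.

    Margin-cut annotations never enter the count.  The returned subset is
    always a prefix of the meander cell order with no cell partially
    included; its size lies in ``[min_n, min_n + max cell count − 1]``
    whenever enough annotations exist.  If the whole ROI holds fewer than
    ``min_n`` eligible annotations, everything is returned with a warning.

    Returns ``(subset, log)`` where ``log`` has one record per visited
    cell: traversal position, (row, col), per-cell and cumulative counts.
    """
    assignment = assign_to_grid(polygons, plan)
    by_pos: dict[int, list[dict]] = {}
    for entry in polygons:
        pos = assignment[entry["label"]]
        if pos is not None:
            by_pos.setdefault(pos, []).append(entry)

    order = plan.traversal_order()
    subset: list[dict] = []
    log: list[dict] = []
    cumulative = 0
    for t, cell in enumerate(order):
        members = by_pos.get(t, [])
        subset.extend(members)
        cumulative += len(members)
        log.append(
            {"position": t, "row": cell[0], "col": cell[1],
             "cell_count": len(members), "cumulative": cumulative}
        )
        if cumulative >= min_n:
            return subset, log

    warnings.warn(
        f"only {cumulative} eligible annotations in the ROI (< {min_n}); returning all",
        stacklevel=2,
    )
    return subset, log
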