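"""Reticulation morphometrics: costa counts and elytral cell areas.

Net-winged beetle elytra carry longitudinal costae (ridges running base to
apex) connected by transverse costae; the enclosed depressions are "cells".
A reticulate aposematic pattern has few costae and therefore large cells
(0.29–0.48 mm² versus 0.10–0.26 mm² in dense, non-reticulate elytra), so
cell area and transverse-costa count are the structural discriminators.

Inputs are binary masks (true = cell-bottom pixel, or true = costa pixel)
plus a pixel scale; automatic segmentation of costae from photographs is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import line as _draw_line
from skimage.measure import label as _label
from skimage.segmentation import clear_border as _clear_border

__all__ = [
    "ElytronMorphology",
    "BoxplotStats",
    "measure_cells",
    "count_transverse",
    "boxplot_stats",
]


@dataclass(frozen=True)
class ElytronMorphology:
    """Structural description of one elytron's reticulation."""

    n_longitudinal: int
    n_transverse: int
    cell_areas_mm2: tuple[float, ...] = ()
    scale_px_per_mm: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_longitudinal < 0 or self.n_transverse < 0:
            raise ValueError("costa counts must be non-negative")
        if any(a <= 0 for a in self.cell_areas_mm2):
            raise ValueError("cell areas must be positive")

    @property
    def mean_cell_area_mm2(self) -> float:
        if not self.cell_areas_mm2:
            return float("nan")
        return float(np.mean(self.cell_areas_mm2))


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary: extremes plus linearly interpolated quartiles."""

    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float

    def __post_init__(self) -> None:
        seq = (self.minimum, self.q25, self.median, self.q75, self.maximum)
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"summary not monotone: {seq}")


def measure_cells(cell_mask: np.ndarray, scale_px_per_mm: float) -> list[float]:
    """Areas (mm²) of complete elytral cells in a binary cell-bottom mask.

    Cells are 4-connected components of true pixels (costae are thin, so
    8-connectivity would leak across diagonal costa junctions).  Components
    touching the raster border are excluded: only complete cells are
    measured, since partial marginal cells would bias areas downward.
    """
    if scale_px_per_mm <= 0:
        raise ValueError("scale_px_per_mm must be positive")
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("cell_mask must be a 2-D raster")
    if not mask.any():
        return []
    labels = _label(mask, connectivity=1)
    labels = _clear_border(labels)
    counts = np.bincount(labels.ravel())[1:]  # skip background
    counts = counts[counts > 0]
    return sorted(float(c) / scale_px_per_mm**2 for c in counts)


def count_transverse(
    costa_mask: np.ndarray, transect: Sequence[Sequence[float]]
) -> int:
    """Number of costae crossed by a longitudinal transect.

    The transect is a line segment given as ((x0, y0), (x1, y1)) in pixel
    coordinates; the count is the number of maximal runs of costa pixels
    met along the rasterised line.
    """
    mask = np.asarray(costa_mask, dtype=bool)
    (x0, y0), (x1, y1) = transect
    h, w = mask.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"transect endpoint ({x}, {y}) outside the raster")
    rr, cc = _draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    hits = mask[rr, cc]
    # run-length crossing count: number of False->True transitions (incl. start)
    return int(np.count_nonzero(np.diff(np.concatenate([[False], hits]).astype(int)) == 1))


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Five-number summary with sample extremes as whiskers.

    Quartiles use linear interpolation between closest ranks (the common
    type-7 rule); whiskers are the sample minimum and maximum.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return BoxplotStats(
        minimum=float(arr.min()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        maximum=float(arr.max()),
    )


def plot_cell_area_boxplots(groups, path):
    """Box plot of cell areas (mm²) per genus/group, whiskers at the
    sample extremes; ``groups`` maps label → list of areas."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(groups)
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.boxplot([groups[k] for k in labels], tick_labels=labels, whis=(0, 100))
    ax.set_ylabel("elytral cell area (mm²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
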