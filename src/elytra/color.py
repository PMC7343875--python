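"""CIELAB colour arithmetic and elytral region contrast statistics.

The internal contrast of an aposematic pattern is quantified as the CIE76
colour difference (ΔE, Euclidean distance in CIE 1976 L*a*b* space) between
the mean colours of homologous elytral regions — typically the humeral
(basal, brightly coloured) part against the apical (dark) part, and, for
reticulate patterns, the raised costae against the cell bottoms.

Region colours are estimated by averaging small square pixel patches placed
at seeded-random positions inside an annotated region polygon: ten 31×31-px
patches for the large elytral regions, ten 5×5-px patches for the narrow
costae and cell bottoms.  Pixels are converted to L*a*b* individually and
averaged in Lab space; ΔE is then the distance between region *means*
(distance of averages, not average of distances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "LabColour",
    "RegionSample",
    "ContrastProfile",
    "srgb_to_lab",
    "lab_to_srgb",
    "delta_e_cie76",
    "sample_region",
    "costa_cell_contrast",
    "contrast_profile",
    "pattern_distance_summary",
    "GeometryError",
]

REGION_LABELS = ("humeral", "middle", "apical", "costa", "cell")


class GeometryError(ValueError):
    """A region polygon cannot accommodate the requested sampling."""


@dataclass(frozen=True)
class LabColour:
    """A point in CIE 1976 L*a*b* space (D65 white, 2° observer).

    L is lightness in [0, 100]; a and b are the green–red and blue–yellow
    opponent axes (nominally −128..127 for colours within the sRGB gamut).
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for v in (self.L, self.a, self.b):
            if not math.isfinite(v):
                raise ValueError(f"non-finite Lab component: {v!r}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "LabColour":
        L, a, b = (float(v) for v in arr)
        return cls(L, a, b)


@dataclass(frozen=True)
class RegionSample:
    """Patch-sampled colour of one elytral region."""

    region_label: str
    patch_means: tuple[LabColour, ...]
    mean_lab: LabColour
    patch_size_px: int
    n_patches: int
    patch_positions: tuple[tuple[int, int], ...] = ()  # (x, y) patch top-left

    def __post_init__(self) -> None:
        if self.n_patches < 1 or self.n_patches != len(self.patch_means):
            raise ValueError("n_patches must equal len(patch_means) and be >= 1")


@dataclass(frozen=True)
class ContrastProfile:
    """ΔE (CIE76) between homologous elytral region means of one specimen."""

    delta_humeral_apical: float
    delta_humeral_middle: float | None = None
    delta_costa_cell: float | None = None

    def __post_init__(self) -> None:
        for v in (self.delta_humeral_apical, self.delta_humeral_middle, self.delta_costa_cell):
            if v is not None and v < 0:
                raise ValueError("ΔE values must be non-negative")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Coerce an 8-/16-bit or float sRGB raster to float in [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an H×W×3 sRGB raster")
    image = image[..., :3]
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    if image.dtype == np.uint16:
        return image.astype(float) / 65535.0
    image = image.astype(float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("float images must be scaled to [0, 1]")
    return image


def srgb_to_lab(rgb: Sequence[int]) -> LabColour:
    """Convert one 8-bit sRGB triple to CIE L*a*b*.

    Uses the IEC 61966-2-1 transfer function with the D65 white point and
    the 2° standard observer (scikit-image's default pipeline).
    """
    r, g, b = rgb
    for ch in (r, g, b):
        if not 0 <= ch <= 255:
            raise ValueError(f"sRGB channel out of range [0, 255]: {ch}")
    arr = np.array([[[r, g, b]]], dtype=float) / 255.0
    lab = _skcolor.rgb2lab(arr)[0, 0]
    return LabColour.from_array(lab)


def lab_to_srgb(lab: LabColour, clip: bool = True) -> tuple[int, int, int]:
    """Inverse conversion to an 8-bit sRGB triple (gamut-clipped by default)."""
    rgb = _skcolor.lab2rgb(np.array([[lab.as_array()]]))[0, 0]
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    elif (rgb < 0).any() or (rgb > 1).any():
        raise ValueError(f"Lab colour {lab} is outside the sRGB gamut")
    return tuple(int(round(v * 255)) for v in rgb)


def delta_e_cie76(c1: LabColour, c2: LabColour) -> float:
    """CIE76 colour difference: Euclidean distance in L*a*b* space."""
    return float(
        math.sqrt((c1.L - c2.L) ** 2 + (c1.a - c2.a) ** 2 + (c1.b - c2.b) ** 2)
    )


def _polygon_mask(shape: tuple[int, int], poly: np.ndarray) -> np.ndarray:
    """Rasterise a polygon given as (x, y) vertices, 0-based, top-left origin."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def _valid_patch_origins(mask: np.ndarray, size: int) -> np.ndarray:
    """(y, x) top-left positions whose size×size window lies fully inside mask."""
    h, w = mask.shape
    if h < size or w < size:
        return np.empty((0, 2), dtype=int)
    # integral-image sliding window: window sum == size**2 means fully interior
    ii = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    win = (
        ii[size:, size:] - ii[:-size, size:] - ii[size:, :-size] + ii[:-size, :-size]
    )
    ys, xs = np.nonzero(win == size * size)
    return np.column_stack([ys, xs])


def _patch_mean_lab(image_rgb: np.ndarray, y: int, x: int, size: int) -> LabColour:
    patch = image_rgb[y : y + size, x : x + size]
    lab = _skcolor.rgb2lab(patch)
    return LabColour.from_array(lab.reshape(-1, 3).mean(axis=0))


def sample_region(
    image: np.ndarray,
    region: Sequence[Sequence[float]],
    patch_size_px: int = 31,
    n_patches: int = 10,
    seed: int = 0,
    region_label: str = "region",
    disjoint: bool = False,
) -> RegionSample:
    """Estimate a region's mean Lab colour from seeded-random square patches.

    Parameters
    ----------
    image
        Calibrated sRGB raster (uint8, uint16 or float in [0, 1]).
    region
        Polygon vertices as (x, y) pixel coordinates, 0-based, top-left
        origin, x right, y down.
    patch_size_px, n_patches
        Patch geometry: ten 31×31-px patches by default.
    seed
        Seeds the uniform-random placement of patch origins.
    disjoint
        If true, reject patch placements overlapping an earlier patch.
        Overlap is permitted by default.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    img = _as_float_rgb(image)
    poly = np.asarray(region, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise GeometryError("region polygon needs at least 3 vertices")
    mask = _polygon_mask(img.shape[:2], poly)
    if not mask.any():
        raise GeometryError("region polygon has zero rasterised area")
    origins = _valid_patch_origins(mask, patch_size_px)
    if len(origins) == 0:
        raise GeometryError(
            f"polygon cannot contain a single {patch_size_px}×{patch_size_px}-px patch"
        )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    if disjoint:
        free = origins.copy()
        for _ in range(n_patches):
            if len(free) == 0:
                raise GeometryError("polygon too small for disjoint patches")
            y, x = free[rng.integers(len(free))]
            chosen.append((int(y), int(x)))
            keep = (np.abs(free[:, 0] - y) >= patch_size_px) | (
                np.abs(free[:, 1] - x) >= patch_size_px
            )
            free = free[keep]
    else:
        for idx in rng.integers(len(origins), size=n_patches):
            y, x = origins[idx]
            chosen.append((int(y), int(x)))
    patch_means = tuple(
        _patch_mean_lab(img, y, x, patch_size_px) for y, x in chosen
    )
    mean = LabColour.from_array(
        np.mean([p.as_array() for p in patch_means], axis=0)
    )
    return RegionSample(
        region_label=region_label,
        patch_means=patch_means,
        mean_lab=mean,
        patch_size_px=patch_size_px,
        n_patches=n_patches,
        patch_positions=tuple((x, y) for y, x in chosen),
    )


def _points_mean_lab(
    image_rgb: np.ndarray,
    points: Sequence[Sequence[float]],
    patch_size_px: int,
    n_patches: int,
    rng: np.random.Generator,
) -> LabColour:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("point list must be non-empty")
    if len(pts) < n_patches:
        raise ValueError(
            f"need at least {n_patches} candidate positions, got {len(pts)}"
        )
    h, w = image_rgb.shape[:2]
    half = patch_size_px // 2
    idx = rng.choice(len(pts), size=n_patches, replace=False)
    means = []
    for x, y in pts[idx]:
        x0, y0 = int(round(x)) - half, int(round(y)) - half
        if x0 < 0 or y0 < 0 or x0 + patch_size_px > w or y0 + patch_size_px > h:
            raise GeometryError(f"patch at ({x}, {y}) falls outside the image")
        means.append(_patch_mean_lab(image_rgb, y0, x0, patch_size_px).as_array())
    return LabColour.from_array(np.mean(means, axis=0))


def costa_cell_contrast(
    image: np.ndarray,
    costa_points: Sequence[Sequence[float]],
    cell_points: Sequence[Sequence[float]],
    patch_size_px: int = 5,
    n_patches: int = 10,
    seed: int = 0,
) -> float:
    """ΔE between mean costa colour and mean cell-bottom colour.

    Each mean is taken over ``n_patches`` small patches (5×5 px by default)
    centred on annotated costa / cell positions; the contrast is the CIE76
    distance between the two means.
    """
    img = _as_float_rgb(image)
    rng = np.random.default_rng(seed)
    costa_mean = _points_mean_lab(img, costa_points, patch_size_px, n_patches, rng)
    cell_mean = _points_mean_lab(img, cell_points, patch_size_px, n_patches, rng)
    return delta_e_cie76(costa_mean, cell_mean)


def contrast_profile(samples: Mapping[str, RegionSample]) -> ContrastProfile:
    """Build a specimen's ΔE profile from its region samples.

    Requires at least the humeral and apical regions; humeral–middle and
    costa–cell distances are reported when those regions were sampled.
    """
    for required in ("humeral", "apical"):
        if required not in samples:
            raise ValueError(f"missing required region sample: {required!r}")
    hum = samples["humeral"].mean_lab
    d_ha = delta_e_cie76(hum, samples["apical"].mean_lab)
    d_hm = (
        delta_e_cie76(hum, samples["middle"].mean_lab) if "middle" in samples else None
    )
    d_cc = None
    if "costa" in samples and "cell" in samples:
        d_cc = delta_e_cie76(samples["costa"].mean_lab, samples["cell"].mean_lab)
    return ContrastProfile(
        delta_humeral_apical=d_ha,
        delta_humeral_middle=d_hm,
        delta_costa_cell=d_cc,
    )


def pattern_distance_summary(
    region_means: Mapping[str, Sequence[Mapping[str, LabColour]]],
) -> pd.DataFrame:
    """Within- and between-pattern ΔE statistics over homologous regions.

    Parameters
    ----------
    region_means
        Maps each pattern label to its specimens, each specimen being a
        mapping ``region label → mean LabColour``.

    Returns
    -------
    DataFrame with one row per (pattern_1, pattern_2, region): the mean and
    maximum ΔE over all cross-specimen comparisons of that region's means.
    Within-pattern rows (pattern_1 == pattern_2) compare distinct specimens
    only; groups with a single specimen get NaN within-pattern statistics.
    """
    patterns = sorted(region_means)
    rows = []
    for i, p1 in enumerate(patterns):
        for p2 in patterns[i:]:
            recs1, recs2 = region_means[p1], region_means[p2]
            regions = sorted(
                {r for rec in list(recs1) + list(recs2) for r in rec}
            )
            for region in regions:
                dists = []
                if p1 == p2:
                    for a in range(len(recs1)):
                        for b in range(a + 1, len(recs1)):
                            if region in recs1[a] and region in recs1[b]:
                                dists.append(
                                    delta_e_cie76(recs1[a][region], recs1[b][region])
                                )
                else:
                    for ra in recs1:
                        for rb in recs2:
                            if region in ra and region in rb:
                                dists.append(delta_e_cie76(ra[region], rb[region]))
                rows.append(
                    {
                        "pattern_1": p1,
                        "pattern_2": p2,
                        "region": region,
                        "n_pairs": len(dists),
                        "mean_delta_e": float(np.mean(dists)) if dists else np.nan,
                        "max_delta_e": float(np.max(dists)) if dists else np.nan,
                    }
                )
    return pd.DataFrame(rows)
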