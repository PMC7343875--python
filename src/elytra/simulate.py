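"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the statistical structure the analysis assumes:

* :func:`gen_elytron` — a rasterised elytron with a planted costa grid
  (longitudinal × transverse costae enclosing cells of known area) and
  planted region Lab colours, with optional Gaussian Lab noise, plus the
  full annotation (region polygons, costa/cell masks, sampling points,
  transect) and a truth record of every planted quantity.
* :func:`gen_sequences` — per-gene alignments simulated under a
  Jukes–Cantor process on a star-of-stars genealogy: OTU ancestors diverge
  d_b/2 from a common root, members d_w/2 from their ancestor, so the
  expected uncorrected p-distance for total path d is ¾(1 − e^(−4d/3)).
* :func:`gen_clock_tree` — a Yule-topology ultrametric tree with planted
  crown age, per-partition branch lengths ℓ_g = r_g·t (exact, or
  Poisson-noised at the partition's site count), and focal pattern states
  planted on leaves chosen so that each requires its own origin.
* :func:`gen_community` / :func:`sample_specimen` — specimen records with
  contrast and morphology parameters drawn inside the published
  per-pattern ranges, planted pattern proportions per elevation band, and
  optional sexually dimorphic taxa (female reticulate C, male yellow/black
  B by default).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from skimage import color as _skcolor

from .classifier import SpecimenRecord
from .color import ContrastProfile, LabColour, delta_e_cie76
from .morphometrics import ElytronMorphology
from .otu import AlignedSeq
from .phylo import PAPER_RATE_TABLE, PatternTree, RateTable, min_origins

__all__ = [
    "ElytronSpec",
    "SyntheticElytron",
    "SeqSimSpec",
    "ClockSimSpec",
    "ClockSim",
    "BandSpec",
    "gen_elytron",
    "gen_sequences",
    "gen_clock_tree",
    "gen_community",
    "sample_specimen",
    "default_community_bands",
    "jc_p_from_d",
    "jc_d_from_p",
    "PATTERN_RANGES",
]


# ---------------------------------------------------------------------------
# elytron images


#: Default planted region colours per pattern.  The B humeral/middle pair and
#: the C costa colour are published Lab positions; the rest are chosen so the
#: resulting region contrasts fall inside the published per-pattern ΔE ranges.
_PATTERN_COLOURS: dict[str, dict[str, LabColour]] = {
    "A": {
        "humeral": LabColour(48, 25, 30),
        "middle": LabColour(40, 21, 26),
        "apical": LabColour(33, 18, 22),
        "costa": LabColour(48, 25, 30),  # == humeral: no costa/cell contrast
    },
    "B": {
        "humeral": LabColour(52, 33, 51),
        "middle": LabColour(64, 25, 52),
        "apical": LabColour(20, 8, 6),
        "costa": LabColour(52, 33, 51),
    },
    "C": {
        "humeral": LabColour(24, 10, 20),  # cell bottoms dominate the base
        "middle": LabColour(25, 8, 8),
        "apical": LabColour(22, 7, 6),
        "costa": LabColour(53, 19, 43),
    },
    "BLACK": {
        "humeral": LabColour(12, 3, 2),
        "middle": LabColour(13, 3, 2),
        "apical": LabColour(14, 4, 3),
        "costa": LabColour(12, 3, 2),
    },
}

_PATTERN_GEOMETRY = {
    "A": dict(n_longitudinal=9, n_transverse=32, cell_area_mm2=0.12),
    "B": dict(n_longitudinal=9, n_transverse=30, cell_area_mm2=0.13),
    "C": dict(n_longitudinal=4, n_transverse=12, cell_area_mm2=0.35),
    "BLACK": dict(n_longitudinal=9, n_transverse=32, cell_area_mm2=0.12),
}


@dataclass(frozen=True)
class ElytronSpec:
    """Blueprint of one synthetic elytron image."""

    pattern: str
    region_lab: Mapping[str, LabColour]
    noise_sd: float = 2.0
    n_longitudinal: int = 9
    n_transverse: int = 30
    cell_area_mm2: float = 0.13
    scale_px_per_mm: float = 100.0
    costa_width_px: int = 7
    margin_px: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_longitudinal < 2 or self.n_transverse < 2:
            raise ValueError("grid needs at least 2 costae each way")
        if self.cell_area_mm2 <= 0 or self.scale_px_per_mm <= 0:
            raise ValueError("cell area and scale must be positive")
        for region in ("humeral", "middle", "apical", "costa"):
            if region not in self.region_lab:
                raise ValueError(f"region_lab missing {region!r}")

    @classmethod
    def for_pattern(cls, pattern: str, seed: int = 0, **overrides) -> "ElytronSpec":
        """Defaults for one of the four pattern categories."""
        if pattern not in _PATTERN_COLOURS:
            raise ValueError(f"unknown pattern {pattern!r}")
        kwargs = dict(
            pattern=pattern,
            region_lab=dict(_PATTERN_COLOURS[pattern]),
            seed=seed,
            **_PATTERN_GEOMETRY[pattern],
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticElytron:
    """A generated elytron image plus its complete annotation and truth."""

    image: np.ndarray  # uint8 H×W×3 sRGB
    region_polygons: dict[str, list[tuple[int, int]]]
    costa_mask: np.ndarray
    cell_mask: np.ndarray
    costa_points: list[tuple[int, int]]
    cell_points: list[tuple[int, int]]
    transect: tuple[tuple[int, int], tuple[int, int]]
    truth: dict
    spec: ElytronSpec


def gen_elytron(spec: ElytronSpec) -> SyntheticElytron:
    """Render a synthetic elytron raster from its blueprint.

    The costa grid spans the raster interior; cell bottoms take the colour
    of the elevational band they fall in (humeral / middle / apical thirds
    along the elytron length), costae take the costa colour within the
    humeral band and the band colour elsewhere.  Gaussian noise is added
    per pixel in Lab space before conversion to sRGB; out-of-gamut pixels
    are clipped and the clipped fraction reported in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    cw = spec.costa_width_px
    s = int(round(math.sqrt(spec.cell_area_mm2) * spec.scale_px_per_mm))
    if s < cw:
        raise ValueError("cell size smaller than costa width: geometry infeasible")
    n_l, n_t = spec.n_longitudinal, spec.n_transverse
    m = spec.margin_px
    W = 2 * m + n_l * cw + (n_l - 1) * s
    H = 2 * m + n_t * cw + (n_t - 1) * s

    ys = np.arange(H)
    xs = np.arange(W)
    # costa band membership along each axis
    def costa_intervals(n: int) -> list[tuple[int, int]]:
        return [(m + k * (s + cw), m + k * (s + cw) + cw) for k in range(n)]

    row_iv = costa_intervals(n_t)
    col_iv = costa_intervals(n_l)
    in_costa_row = np.zeros(H, dtype=bool)
    for lo, hi in row_iv:
        in_costa_row[lo:hi] = True
    in_costa_col = np.zeros(W, dtype=bool)
    for lo, hi in col_iv:
        in_costa_col[lo:hi] = True
    in_grid_y = (ys >= m) & (ys < H - m)
    in_grid_x = (xs >= m) & (xs < W - m)

    grid = np.outer(in_grid_y, in_grid_x)
    costa_mask = grid & (in_costa_row[:, None] | in_costa_col[None, :])
    cell_mask = grid & ~costa_mask

    # elevational thirds along the elytron length
    band_of_row = np.minimum(ys * 3 // H, 2)  # 0 humeral, 1 middle, 2 apical
    band_lab = np.stack(
        [
            spec.region_lab["humeral"].as_array(),
            spec.region_lab["middle"].as_array(),
            spec.region_lab["apical"].as_array(),
        ]
    )
    lab = band_lab[band_of_row][:, None, :] * np.ones((1, W, 1))
    humeral_rows = band_of_row == 0
    costa_humeral = costa_mask & humeral_rows[:, None]
    lab[costa_humeral] = spec.region_lab["costa"].as_array()

    if spec.noise_sd > 0:
        lab = lab + rng.normal(0.0, spec.noise_sd, size=lab.shape)
        lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    rgb = _skcolor.lab2rgb(lab)
    clip_fraction = float(np.mean((rgb <= 0.0) | (rgb >= 1.0)))
    image = np.round(np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)

    band_h = H // 3
    inset = 4

    def band_rect(b: int) -> list[tuple[int, int]]:
        y0 = b * band_h + inset
        y1 = (b + 1) * band_h - inset
        return [(m, y0), (W - m - 1, y0), (W - m - 1, y1), (m, y1)]

    region_polygons = {
        "humeral": band_rect(0),
        "middle": band_rect(1),
        "apical": band_rect(2),
    }

    # sampling points inside the humeral band: costa intersections and
    # mid-segments (both at least costa_width wide) and five points per cell
    costa_points: list[tuple[int, int]] = []
    cell_points: list[tuple[int, int]] = []
    row_centres = [lo + cw // 2 for lo, hi in row_iv]
    col_centres = [lo + cw // 2 for lo, hi in col_iv]
    for yc in row_centres:
        if yc >= band_h - inset:
            continue
        for xc in col_centres:
            costa_points.append((xc, yc))
        for k in range(n_l - 1):  # horizontal costa mid-segments
            costa_points.append((col_iv[k][1] + s // 2, yc))
    for j in range(n_t - 1):
        y0 = row_iv[j][1]
        yc = y0 + s // 2
        if yc + s // 4 >= band_h - inset:
            continue
        for k in range(n_l - 1):
            xc = col_iv[k][1] + s // 2
            q = max(3, s // 4)
            for dx, dy in ((0, 0), (-q, 0), (q, 0), (0, -q), (0, q)):
                cell_points.append((xc + dx, yc + dy))

    transect_x = col_iv[0][1] + s // 2  # down the first cell column
    transect = ((transect_x, m // 2), (transect_x, H - m // 2 - 1))

    truth = {
        "pattern": spec.pattern,
        "region_lab": {k: (v.L, v.a, v.b) for k, v in spec.region_lab.items()},
        "n_longitudinal": n_l,
        "n_transverse": n_t,
        "n_cells": (n_t - 1) * (n_l - 1),
        "cell_area_mm2_requested": spec.cell_area_mm2,
        "cell_area_mm2_realised": (s / spec.scale_px_per_mm) ** 2,
        "cell_side_px": s,
        "scale_px_per_mm": spec.scale_px_per_mm,
        "clip_fraction": clip_fraction,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return SyntheticElytron(
        image=image,
        region_polygons=region_polygons,
        costa_mask=costa_mask,
        cell_mask=cell_mask,
        costa_points=costa_points,
        cell_points=cell_points,
        transect=transect,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# sequences


def jc_p_from_d(d: float) -> float:
    """Expected uncorrected p-distance after d substitutions/site (Jukes–Cantor)."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_d_from_p(p: float) -> float:
    """Jukes–Cantor divergence giving expected p-distance p."""
    if not 0 <= p < 0.75:
        raise ValueError("p must lie in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class SeqSimSpec:
    """Planted-partition sequence simulation: OTUs as star-of-stars clades."""

    n_otus: int = 20
    seqs_per_otu: int = 3
    within_divergence: float = jc_d_from_p(0.01)
    between_divergence: float = jc_d_from_p(0.08)
    sites: Mapping[str, int] = field(default_factory=lambda: {"cox1": 1000})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_divergence >= self.between_divergence:
            raise ValueError("within_divergence must be < between_divergence")
        if any(n < 1 for n in self.sites.values()):
            raise ValueError("site counts must be >= 1")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes–Cantor branch: each site changes with prob ¾(1−e^(−4d/3))."""
    p_change = jc_p_from_d(d)
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    if hit.any():
        # a changed site takes one of the three other bases uniformly
        current = np.searchsorted(_BASES, seq[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = _BASES[(current + shift) % 4]
    return out


def gen_sequences(spec: SeqSimSpec):
    """Simulate per-gene alignments with a planted OTU partition.

    Each OTU's ancestor sits ``between_divergence/2`` from a shared root;
    each member a further ``within_divergence/2`` from its ancestor.  The
    expected p-distance is therefore ¾(1 − e^(−4d/3)) of d = within
    divergence inside an OTU and d = between + within across OTUs.

    Returns ``(seqs_by_gene, truth)`` where truth maps seq_id → otu index.
    """
    rng = np.random.default_rng(spec.seed)
    pad = len(str(spec.n_otus))
    seqs_by_gene: dict[str, list[AlignedSeq]] = {g: [] for g in spec.sites}
    truth: dict[str, int] = {}
    for gene, n_sites in spec.sites.items():
        root = _BASES[rng.integers(0, 4, size=n_sites)]
        for k in range(spec.n_otus):
            ancestor = _evolve(root, spec.between_divergence / 2, rng)
            for j in range(spec.seqs_per_otu):
                member = _evolve(ancestor, spec.within_divergence / 2, rng)
                sid = f"otu{str(k + 1).zfill(pad)}_seq{j + 1}"
                seqs_by_gene[gene].append(
                    AlignedSeq(seq_id=sid, gene=gene, residues=member.tobytes().decode())
                )
                truth[sid] = k
    return seqs_by_gene, truth


# ---------------------------------------------------------------------------
# clock trees


@dataclass(frozen=True)
class ClockSimSpec:
    """Yule clock-tree simulation with planted ages and focal leaf states."""

    n_leaves: int = 20
    crown_age: float = 15.0  # My
    rates: RateTable = PAPER_RATE_TABLE
    poisson_noise: bool = False
    n_focal_origins: int = 0
    focal_state: str = "B"
    background_state: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crown_age <= 0:
            raise ValueError("crown_age must be > 0")
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if not 0 <= self.n_focal_origins <= self.n_leaves:
            raise ValueError("n_focal_origins must be <= n_leaves")


@dataclass(frozen=True)
class ClockSim:
    """A simulated clock tree with its planted truth."""

    pattern_tree: PatternTree
    true_time_tree: dendropy.Tree
    focal_leaves: tuple[str, ...]
    spec: ClockSimSpec


def _yule_times(n: int, rng: np.random.Generator) -> tuple[list[float], float]:
    """Split times of a Yule process started from 2 crown lineages."""
    times = []
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        times.append(t)
    present = t + rng.exponential(1.0 / n)
    return times, present


def _path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], int]:
    """Topological (edge-count) distance between every leaf pair."""
    leaves = list(tree.leaf_node_iter())
    parents: dict = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            parents[ch] = node

    def ancestors(node):
        out = [node]
        while node in parents:
            node = parents[node]
            out.append(node)
        return out

    dist = {}
    anc = {lf: ancestors(lf) for lf in leaves}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            sa = {id(n): k for k, n in enumerate(anc[a])}
            for k_b, n in enumerate(anc[b]):
                if id(n) in sa:
                    d = sa[id(n)] + k_b
                    break
            key = tuple(sorted((a.taxon.label, b.taxon.label)))
            dist[key] = d
    return dist


def gen_clock_tree(spec: ClockSimSpec) -> ClockSim:
    """Simulate an ultrametric Yule tree with per-partition branch lengths.

    Edge lengths in substitutions/site are ℓ_g = r_g·t exactly when
    ``poisson_noise`` is off, or Poisson(r_g·t·n_g)/n_g when on.  Focal
    states are planted on ``n_focal_origins`` leaves chosen (and verified
    by the parsimony machinery itself) so that every focal leaf requires
    its own origin; all other leaves carry the background state.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_leaves
    taxa = [f"t{str(i + 1).zfill(len(str(n)))}" for i in range(n)]

    # grow the topology forward in time, then rescale to the crown age
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    split_times, present = _yule_times(n, rng)
    root = tree.seed_node
    root.sim_time = 0.0
    active = []
    for _ in range(2):
        ch = root.new_child()
        ch.sim_time = 0.0
        active.append(ch)
    for t_split in split_times:
        node = active.pop(int(rng.integers(len(active))))
        node.sim_time = t_split
        for _ in range(2):
            ch = node.new_child()
            active.append(ch)
    order = rng.permutation(n)
    for node, k in zip(active, order):
        node.taxon = tns.get_taxon(taxa[int(k)])
        node.sim_time = present
    scale = spec.crown_age / present

    true_time = dendropy.Tree(tree)
    for node_src, node_out in zip(
        tree.preorder_node_iter(), true_time.preorder_node_iter()
    ):
        if node_src.parent_node is None:
            node_out.edge.length = None
        else:
            node_out.edge.length = (
                node_src.sim_time - node_src.parent_node.sim_time
            ) * scale

    for node in tree.preorder_node_iter():
        node.partition_lengths = {}
        if node.parent_node is None:
            continue
        t_edge = (node.sim_time - node.parent_node.sim_time) * scale
        for g, r in spec.rates.rates.items():
            if spec.poisson_noise:
                n_g = spec.rates.sites[g]
                node.partition_lengths[g] = float(
                    rng.poisson(r * t_edge * n_g) / n_g
                )
            else:
                node.partition_lengths[g] = r * t_edge

    leaf_states = {lab: spec.background_state for lab in taxa}
    focal: list[str] = []
    if spec.n_focal_origins > 0:
        dist = _path_lengths(tree)
        for attempt in range(200):
            candidates = list(rng.permutation(taxa))
            chosen: list[str] = []
            for c in candidates:
                if all(dist[tuple(sorted((c, f)))] >= 4 for f in chosen):
                    chosen.append(c)
                if len(chosen) == spec.n_focal_origins:
                    break
            if len(chosen) == spec.n_focal_origins:
                trial = dict(leaf_states)
                for c in chosen:
                    trial[c] = spec.focal_state
                ptree_trial = PatternTree(tree, trial)
                rep = min_origins(ptree_trial, spec.focal_state)
                if rep.min_origins == spec.n_focal_origins:
                    focal = sorted(chosen)
                    leaf_states = trial
                    break
        else:
            raise ValueError(
                f"could not plant {spec.n_focal_origins} independent origins "
                f"on a {n}-leaf topology"
            )

    ptree = PatternTree(tree, leaf_states)
    return ClockSim(
        pattern_tree=ptree,
        true_time_tree=true_time,
        focal_leaves=tuple(focal),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# communities


#: Published per-pattern parameter ranges used to draw synthetic specimens.
PATTERN_RANGES: dict[str, dict] = {
    "A": dict(
        delta_ha=(15.7, 20.3), delta_hm=(3.0, 13.0), n_longitudinal=9,
        n_transverse=(31, 40), cell_area=(0.10, 0.26), humeral_L=(35.0, 55.0),
    ),
    "B": dict(
        delta_ha=(52.5, 69.7), delta_hm=(3.3, 22.2), n_longitudinal=9,
        n_transverse=(28, 35), cell_area=(0.10, 0.26), humeral_L=(45.0, 60.0),
    ),
    "C": dict(
        delta_ha=(10.0, 35.0), delta_hm=(2.0, 15.0), n_longitudinal=4,
        n_transverse=(8, 15), cell_area=(0.29, 0.48), humeral_L=(25.0, 55.0),
        delta_cc=(25.0, 40.9),
    ),
    "BLACK": dict(
        delta_ha=(0.0, 5.0), delta_hm=(0.0, 4.0), n_longitudinal=9,
        n_transverse=(31, 40), cell_area=(0.10, 0.26), humeral_L=(5.0, 15.0),
    ),
}


def sample_specimen(
    pattern: str,
    rng: np.random.Generator,
    specimen_id: str = "spec",
    taxon: str = "sp",
    tribe: str = "Metriorrhynchini",
    sex: str = "unknown",
    site: str = "",
    elevation: float = 0.0,
) -> SpecimenRecord:
    """Draw one specimen with parameters inside its pattern's published ranges."""
    if pattern not in PATTERN_RANGES:
        raise ValueError(f"unknown pattern {pattern!r}")
    rg = PATTERN_RANGES[pattern]

    def u(lo_hi):
        lo, hi = lo_hi
        return float(rng.uniform(lo, hi))

    d_cc = u(rg["delta_cc"]) if "delta_cc" in rg else None
    n_trans = int(rng.integers(rg["n_transverse"][0], rg["n_transverse"][1] + 1))
    mean_area = u(rg["cell_area"])
    areas = tuple(
        float(max(0.01, mean_area + rng.normal(0, 0.01))) for _ in range(6)
    )
    # keep the mean on the planted side of the range by re-centring
    areas = tuple(float(a - (np.mean(areas) - mean_area)) for a in areas)
    hum_L = u(rg["humeral_L"])
    return SpecimenRecord(
        specimen_id=specimen_id,
        taxon=taxon,
        tribe=tribe,
        sex=sex,
        site=site,
        elevation=elevation,
        contrasts=ContrastProfile(
            delta_humeral_apical=u(rg["delta_ha"]),
            delta_humeral_middle=u(rg["delta_hm"]),
            delta_costa_cell=d_cc,
        ),
        morphology=ElytronMorphology(
            n_longitudinal=rg["n_longitudinal"],
            n_transverse=n_trans,
            cell_areas_mm2=areas,
            scale_px_per_mm=100.0,
        ),
        humeral_mean_lab=LabColour(hum_L, 15.0, 15.0),
        pattern=None,
    )


@dataclass(frozen=True)
class BandSpec:
    """One elevation band of a synthetic community."""

    name: str
    elevation_range: tuple[float, float]
    n: int
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        total = sum(self.proportions.values())
        if self.n > 0 and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"band {self.name!r}: proportions sum to {total}, not 1")


def default_community_bands() -> list[BandSpec]:
    """Two-band community mirroring the surveyed structure: pattern A
    dominates the lowlands; in the mountains (≥ 1,500 m) the reticulate
    pattern C reaches ~30% of individuals and yellow/black B ~50%."""
    return [
        BandSpec("lowland", (200.0, 1400.0), 100, {"A": 0.85, "B": 0.05, "BLACK": 0.10}),
        BandSpec(
            "mountain", (1500.0, 2800.0), 100,
            {"A": 0.15, "B": 0.50, "C": 0.30, "BLACK": 0.05},
        ),
    ]


def _largest_remainder(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    keys = sorted(proportions)
    raw = {k: proportions[k] * n for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def gen_community(
    bands: Sequence[BandSpec] | None = None,
    n_taxa: Mapping[str, int] | None = None,
    dimorphic: Mapping[str, Mapping[str, str]] | None = None,
    seed: int = 0,
):
    """Generate a specimen table with planted patterns per elevation band.

    Pattern counts per band follow the planted proportions exactly
    (largest-remainder rounding); taxa are assigned cyclically from
    per-pattern pools of ``n_taxa`` names (defaults: A 20, B 13, C 4,
    BLACK 4 — thirteen yellow/black species mirrors the surveyed mountain
    community).  ``dimorphic`` maps a taxon to its sex-specific patterns
    (default: *Micronychus pardus*, female C / male B); each dimorphic
    taxon claims one female slot of its female pattern and one male slot
    of its male pattern in the highest band, so planted proportions are
    unchanged.

    Returns ``(records, truth)``: classified-pattern-free SpecimenRecords
    with the planted pattern set, and a DataFrame of the planted truth.
    """
    import pandas as pd

    bands = list(bands) if bands is not None else default_community_bands()
    n_taxa = dict(n_taxa or {"A": 20, "B": 13, "C": 4, "BLACK": 4})
    if dimorphic is None:
        dimorphic = {"Micronychus_pardus": {"female": "C", "male": "B"}}
    rng = np.random.default_rng(seed)
    # n_taxa counts taxa *displaying* each pattern, so a dimorphic taxon
    # reserves one species slot in each of its sex-specific patterns
    reserved: dict[str, int] = {}
    for mapping in dimorphic.values():
        for patt in set(mapping.values()):
            reserved[patt] = reserved.get(patt, 0) + 1
    pools = {
        p: [f"{p}_sp{str(i + 1).zfill(2)}" for i in range(max(k - reserved.get(p, 0), 1))]
        for p, k in n_taxa.items()
    }
    records: list[SpecimenRecord] = []
    truth_rows = []
    sid = 0
    top_band = max(bands, key=lambda b: b.elevation_range[0]) if bands else None
    for band in bands:
        counts = _largest_remainder(band.n, band.proportions)
        dim_slots: list[tuple[str, str, str]] = []  # (taxon, sex, pattern)
        if band is top_band:
            for taxon, mapping in sorted(dimorphic.items()):
                for sex in ("female", "male"):
                    patt = mapping[sex]
                    if counts.get(patt, 0) < 1:
                        raise ValueError(
                            f"band {band.name!r} lacks a {patt!r} slot for "
                            f"dimorphic taxon {taxon!r}"
                        )
                    counts[patt] -= 1
                    dim_slots.append((taxon, sex, patt))
        assignments: list[tuple[str, str, str]] = list(dim_slots)
        for pattern in sorted(counts):
            pool = pools.get(pattern) or [f"{pattern}_sp01"]
            for j in range(counts[pattern]):
                taxon = pool[j % len(pool)]
                sex = "female" if rng.random() < 0.5 else "male"
                assignments.append((taxon, sex, pattern))
        for taxon, sex, pattern in assignments:
            sid += 1
            elev = float(rng.uniform(*band.elevation_range))
            rec = sample_specimen(
                pattern,
                rng,
                specimen_id=f"s{str(sid).zfill(4)}",
                taxon=taxon,
                sex=sex,
                site=band.name,
                elevation=elev,
            )
            rec = replace(rec, pattern=pattern)
            records.append(rec)
            truth_rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "band": band.name,
                    "taxon": taxon,
                    "sex": sex,
                    "elevation": elev,
                    "pattern": pattern,
                }
            )
    return records, pd.DataFrame(truth_rows)
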