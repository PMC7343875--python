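"""Assign specimens to aposematic pattern categories and summarise communities.

Bornean net-winged beetle communities carry three named mimetic patterns
plus uniformly black species:

* **A** — low-contrast brown/red on black (humeral–apical ΔE roughly
  15.7–20.3), dense reticulation (usually > 30 transverse costae).
* **B** — high-contrast yellow/black (ΔE 52.5–69.7), dense reticulation.
* **C** — the reticulate pattern: four longitudinal and at most ~20
  transverse costae enclosing large cells (0.29–0.48 mm²) with bright
  costae over dark cell bottoms.  The signal is primarily structural, so
  pattern C is decided from reticulation morphometrics, not colour.
* **BLACK** — uniformly dark elytra, no internal contrast.

The decision sequence is structural reticulation first, then contrast;
thresholds sit between the published per-pattern ranges and are fully
configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .color import ContrastProfile, LabColour
from .morphometrics import ElytronMorphology

__all__ = [
    "SpecimenRecord",
    "ClassifierConfig",
    "PATTERNS",
    "classify",
    "community_summary",
    "dimorphism_scan",
]

PATTERNS = ("A", "B", "C", "BLACK")


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected beetle with its measured colour and structure."""

    specimen_id: str
    taxon: str
    tribe: str = ""
    sex: str = "unknown"  # {male, female, unknown}
    site: str = ""
    elevation: float = 0.0
    body_length_mm: float | None = None
    contrasts: ContrastProfile | None = None
    morphology: ElytronMorphology | None = None
    humeral_mean_lab: LabColour | None = None
    pattern: str | None = None

    def __post_init__(self) -> None:
        if self.elevation < 0:
            raise ValueError("elevation must be >= 0")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"unknown sex label: {self.sex!r}")
        if self.pattern is not None and self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern label: {self.pattern!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds separating the published per-pattern ranges.

    ``t_high_contrast`` (36.4) is the midpoint of the printed pattern-A
    maximum (20.3) and pattern-B minimum (52.5); ``t_cell_area_mm2``
    (0.275) the midpoint of the non-reticulate maximum (0.26) and
    reticulate minimum (0.29).  The BLACK thresholds have no published
    range ("uniformly black") and are configurable plumbing.
    """

    t_high_contrast: float = 36.4
    t_cell_area_mm2: float = 0.275
    t_max_transverse: int = 20
    t_max_longitudinal: int = 4
    t_black_L: float = 20.0
    t_black_delta: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "t_high_contrast",
            "t_cell_area_mm2",
            "t_max_transverse",
            "t_max_longitudinal",
            "t_black_L",
            "t_black_delta",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def classify(record: SpecimenRecord, config: ClassifierConfig | None = None) -> str:
    """Assign a pattern label {A, B, C, BLACK} to one specimen.

    Decision sequence:

    1. **C** if the reticulation is structural: few longitudinal and
       transverse costae *and* large mean cell area.
    2. else **B** if the humeral–apical contrast is high.
    3. else **BLACK** if the humeral part is dark and near-contrast-free.
    4. else **A**.
    """
    cfg = config or ClassifierConfig()
    if record.contrasts is None or record.contrasts.delta_humeral_apical is None:
        raise ValueError("classify requires contrasts.delta_humeral_apical")
    if record.morphology is None:
        raise ValueError("classify requires morphology")
    m = record.morphology
    d_ha = record.contrasts.delta_humeral_apical
    mean_cell = m.mean_cell_area_mm2
    if (
        m.n_longitudinal <= cfg.t_max_longitudinal
        and m.n_transverse <= cfg.t_max_transverse
        and np.isfinite(mean_cell)
        and mean_cell >= cfg.t_cell_area_mm2
    ):
        return "C"
    if d_ha >= cfg.t_high_contrast:
        return "B"
    if (
        record.humeral_mean_lab is not None
        and record.humeral_mean_lab.L < cfg.t_black_L
        and d_ha < cfg.t_black_delta
    ):
        return "BLACK"
    return "A"


def classify_all(
    records: Iterable[SpecimenRecord], config: ClassifierConfig | None = None
) -> list[SpecimenRecord]:
    """Classify every record, returning copies with ``pattern`` set."""
    return [replace(r, pattern=classify(r, config)) for r in records]


DEFAULT_BAND_EDGES = (1500.0,)  # lowland < 1,500 m a.s.l. <= mountain


def _band_labels(edges: Sequence[float]) -> list[str]:
    edges = list(edges)
    labels = [f"<{edges[0]:g} m"]
    labels += [f"{lo:g}-{hi:g} m" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]:g} m")
    return labels


def community_summary(
    records: Sequence[SpecimenRecord],
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    by: str = "individuals",
) -> pd.DataFrame:
    """Pattern composition of the community per elevation band.

    Returns a table with one row per (band, pattern): the count and the
    proportion within the band.  ``by="individuals"`` counts records;
    ``by="species"`` deduplicates by taxon within each band (a taxon whose
    records span several patterns — e.g. a sexually dimorphic species —
    contributes to each pattern it displays).  Proportions within a
    non-empty band sum to 1; empty bands report zero counts and NaN
    proportions.
    """
    if by not in ("individuals", "species"):
        raise ValueError("by must be 'individuals' or 'species'")
    for r in records:
        if r.pattern is None:
            raise ValueError(
                f"record {r.specimen_id!r} has no pattern; run classify first"
            )
    edges = sorted(band_edges)
    labels = _band_labels(edges)
    bins = [-np.inf] + list(edges) + [np.inf]

    def band_of(elev: float) -> str:
        idx = int(np.searchsorted(edges, elev, side="right"))
        return labels[idx]

    rows = []
    for band in labels:
        in_band = [r for r in records if band_of(r.elevation) == band]
        if by == "individuals":
            counts = Counter(r.pattern for r in in_band)
            total = len(in_band)
        else:
            taxa = {(r.taxon, r.pattern) for r in in_band}
            counts = Counter(p for _, p in taxa)
            total = len(taxa)
        for pattern in PATTERNS:
            n = counts.get(pattern, 0)
            rows.append(
                {
                    "band": band,
                    "pattern": pattern,
                    "count": n,
                    "proportion": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def dimorphism_scan(records: Sequence[SpecimenRecord]) -> list[dict]:
    """Find taxa whose male and female modal patterns differ.

    Mimetic sexual dimorphism — as in *Micronychus pardus*, whose females
    adopt the reticulate pattern C while the single known male displays the
    yellow/black pattern B — is detected by comparing modal patterns per
    sex.  Taxa with only one sex represented are skipped.  Modal ties are
    reported with ``ambiguous=True`` and all tied modes listed.
    """
    by_taxon: dict[str, dict[str, list[str]]] = {}
    for r in records:
        if r.pattern is None or r.sex not in ("male", "female"):
            continue
        by_taxon.setdefault(r.taxon, {}).setdefault(r.sex, []).append(r.pattern)
    flagged = []
    for taxon in sorted(by_taxon):
        sexes = by_taxon[taxon]
        if "male" not in sexes or "female" not in sexes:
            continue
        modes = {}
        ambiguous = False
        for sex in ("female", "male"):
            counts = Counter(sexes[sex])
            top = max(counts.values())
            tied = sorted(p for p, c in counts.items() if c == top)
            modes[sex] = tied
            ambiguous |= len(tied) > 1
        if set(modes["female"]) != set(modes["male"]) or ambiguous:
            if not ambiguous and modes["female"] == modes["male"]:
                continue
            flagged.append(
                {
                    "taxon": taxon,
                    "female_mode": modes["female"][0]
                    if len(modes["female"]) == 1
                    else modes["female"],
                    "male_mode": modes["male"][0]
                    if len(modes["male"]) == 1
                    else modes["male"],
                    "ambiguous": ambiguous,
                }
            )
    return flagged
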