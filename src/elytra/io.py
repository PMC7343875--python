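"""Readers and writers for the pipeline's file formats.

Conventions: image pixel coordinates are 0-based with the origin at the
top-left, x right, y down; alignments are reported with 1-based columns;
tables are TSV with ``#``-prefixed header comments carrying the tool
version, seed and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from Bio import SeqIO

from .classifier import SpecimenRecord
from .color import ContrastProfile, LabColour
from .morphometrics import ElytronMorphology
from .otu import AlignedSeq, DistanceMatrix, OTUPartition

__version__ = "0.1.0"

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick_text",
    "read_annotation",
    "write_annotation",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_specimen_table",
    "write_specimen_table",
    "write_distance_long",
    "write_otu_table",
    "output_header",
    "config_hash",
]


def config_hash(config: Mapping) -> str:
    """Short deterministic hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(seed: int | None = None, config: Mapping | None = None) -> str:
    parts = [f"# elytra v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts)


# -- sequences ---------------------------------------------------------------


def read_fasta(path: str | Path, gene: str) -> list[AlignedSeq]:
    """Read one gene's alignment; malformed input fails with a line number."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path.name}:{lineno}: expected a '>' header before sequence data"
                )
            break
        else:
            raise ValueError(f"{path.name}: empty FASTA file")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.append(AlignedSeq(seq_id=rec.id, gene=gene, residues=str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"{path.name}: record {rec.id!r}: {exc}") from exc
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            f"{path.name}: unaligned input, sequence lengths {sorted(lengths)}"
        )
    return seqs


def write_fasta(seqs: Iterable[AlignedSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.residues}\n")


def read_newick_text(path: str | Path) -> str:
    """Read a Newick file, rejecting obviously malformed input early."""
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            if stripped.count("(") != stripped.count(")"):
                raise ValueError(
                    f"{path.name}:{lineno}: unbalanced parentheses in Newick"
                )
            return stripped
    raise ValueError(f"{path.name}: no Newick tree found")


# -- images and annotations --------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, image)


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(path) > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_annotation(annotation: Mapping, path: str | Path) -> None:
    """JSON annotation: named polygons / point lists in 0-based pixel
    coordinates (origin top-left, x right, y down)."""
    with open(path, "w") as fh:
        json.dump(annotation, fh, indent=1, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_annotation(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- specimen tables ---------------------------------------------------------

_SPECIMEN_COLUMNS = [
    "specimen_id", "taxon", "tribe", "sex", "site", "elevation",
    "body_length_mm", "delta_humeral_apical", "delta_humeral_middle",
    "delta_costa_cell", "n_longitudinal", "n_transverse", "cell_areas_mm2",
    "scale_px_per_mm", "humeral_L", "humeral_a", "humeral_b", "pattern",
]


def write_specimen_table(
    records: Sequence[SpecimenRecord],
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    rows = []
    for r in records:
        c = r.contrasts
        m = r.morphology
        h = r.humeral_mean_lab
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "taxon": r.taxon,
                "tribe": r.tribe,
                "sex": r.sex,
                "site": r.site,
                "elevation": r.elevation,
                "body_length_mm": r.body_length_mm,
                "delta_humeral_apical": c.delta_humeral_apical if c else None,
                "delta_humeral_middle": c.delta_humeral_middle if c else None,
                "delta_costa_cell": c.delta_costa_cell if c else None,
                "n_longitudinal": m.n_longitudinal if m else None,
                "n_transverse": m.n_transverse if m else None,
                "cell_areas_mm2": ";".join(f"{a:.6g}" for a in m.cell_areas_mm2)
                if m else None,
                "scale_px_per_mm": m.scale_px_per_mm if m else None,
                "humeral_L": h.L if h else None,
                "humeral_a": h.a if h else None,
                "humeral_b": h.b if h else None,
                "pattern": r.pattern,
            }
        )
    df = pd.DataFrame(rows, columns=_SPECIMEN_COLUMNS)
    with open(path, "w") as fh:
        fh.write(output_header(seed, config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        def opt(v):
            return None if pd.isna(v) else float(v)

        contrasts = None
        if not pd.isna(row.get("delta_humeral_apical")):
            contrasts = ContrastProfile(
                delta_humeral_apical=float(row["delta_humeral_apical"]),
                delta_humeral_middle=opt(row.get("delta_humeral_middle")),
                delta_costa_cell=opt(row.get("delta_costa_cell")),
            )
        morphology = None
        if not pd.isna(row.get("n_longitudinal")):
            areas_field = row.get("cell_areas_mm2")
            areas = (
                tuple(float(x) for x in str(areas_field).split(";"))
                if isinstance(areas_field, str) and areas_field
                else ()
            )
            morphology = ElytronMorphology(
                n_longitudinal=int(row["n_longitudinal"]),
                n_transverse=int(row["n_transverse"]),
                cell_areas_mm2=areas,
                scale_px_per_mm=opt(row.get("scale_px_per_mm")) or float("nan"),
            )
        hum = None
        if not pd.isna(row.get("humeral_L")):
            hum = LabColour(
                float(row["humeral_L"]), float(row["humeral_a"]), float(row["humeral_b"])
            )
        pattern = row.get("pattern")
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                taxon=str(row["taxon"]),
                tribe=str(row.get("tribe") or ""),
                sex=str(row.get("sex") or "unknown"),
                site="" if pd.isna(row.get("site")) else str(row.get("site")),
                elevation=float(row.get("elevation") or 0.0),
                body_length_mm=opt(row.get("body_length_mm")),
                contrasts=contrasts,
                morphology=morphology,
                humeral_mean_lab=hum,
                pattern=None if pd.isna(pattern) else str(pattern),
            )
        )
    return records


# -- distances and OTUs ------------------------------------------------------


def write_distance_long(
    m: DistanceMatrix,
    path: str | Path,
    gene: str = "pooled",
    seed: int | None = None,
) -> None:
    """Long-format distance table: id1, id2, gene, p, n_sites."""
    rows = []
    for i, id1 in enumerate(m.ids):
        for j in range(i + 1, len(m.ids)):
            rows.append(
                {
                    "id1": id1,
                    "id2": m.ids[j],
                    "gene": gene,
                    "p": m.d[i, j],
                    "n_sites": int(m.n_sites[i, j]),
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(output_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_otu_table(
    partition: OTUPartition, path: str | Path, seed: int | None = None
) -> None:
    rows = []
    for k, cluster in enumerate(partition.clusters):
        rep = (partition.representatives or {}).get(k)
        for sid in sorted(cluster):
            rows.append(
                {"seq_id": sid, "otu_id": k, "is_representative": sid == rep}
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(output_header(seed, {"threshold": partition.threshold}) + "\n")
        df.to_csv(fh, sep="\t", index=False)
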