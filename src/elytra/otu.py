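"""Species-level OTU delimitation by uncorrected p-distance clustering.

Aligned mitochondrial fragments (here typically rrnL, cox1 and nad5) are
compared by the uncorrected p-distance — the proportion of differing sites
among positions where both sequences carry an unambiguous A/C/G/T
(pairwise deletion of gaps and ambiguity codes).  Sequences are grouped
into operational taxonomic units (OTUs) by single-linkage transitive
closure at a distance threshold, 2.5% by default, and each OTU is pruned
to one representative for downstream phylogenetics.

Multi-gene distances pool mismatches over pooled compared sites across
genes (not an average of per-gene distances); per-gene matrices are also
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AlignedSeq",
    "DistanceMatrix",
    "OTUPartition",
    "p_distance",
    "build_distance_matrix",
    "cluster_otus",
    "select_representative",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.025
DEFAULT_MIN_OVERLAP = 100

_UNAMBIGUOUS = frozenset("ACGT")
_IUPAC = frozenset("ACGTRYSWKMBDHVN-?")


@dataclass(frozen=True)
class AlignedSeq:
    """One sequence from a per-gene alignment."""

    seq_id: str
    gene: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - _IUPAC
        if bad:
            raise ValueError(
                f"{self.seq_id}: non-IUPAC characters in alignment: {sorted(bad)}"
            )

    @property
    def n_resolved(self) -> int:
        """Number of unambiguous A/C/G/T sites."""
        return sum(1 for c in self.residues.upper() if c in _UNAMBIGUOUS)


def _encode(seqs: Sequence[AlignedSeq]) -> np.ndarray:
    """Byte matrix of upper-cased residues; raises on ragged alignments."""
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"unequal alignment lengths within one gene: {sorted(lengths)}")
    return np.frombuffer(
        "".join(s.residues.upper() for s in seqs).encode("ascii"), dtype="S1"
    ).reshape(len(seqs), -1)


def p_distance(
    s1: AlignedSeq, s2: AlignedSeq, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Uncorrected pairwise distance between two aligned sequences.

    Sites where either sequence has a gap or ambiguity code are excluded
    (pairwise deletion); the distance is mismatches / compared sites.
    Returns NaN when fewer than ``min_overlap`` sites are compared, which
    guards against spurious near-zero distances from tiny overlaps.
    """
    if len(s1.residues) != len(s2.residues):
        raise ValueError(
            f"alignment length mismatch: {len(s1.residues)} vs {len(s2.residues)}"
        )
    a = np.frombuffer(s1.residues.upper().encode("ascii"), dtype="S1")
    b = np.frombuffer(s2.residues.upper().encode("ascii"), dtype="S1")
    valid_a = np.isin(a, [b"A", b"C", b"G", b"T"])
    valid_b = np.isin(b, [b"A", b"C", b"G", b"T"])
    both = valid_a & valid_b
    n = int(both.sum())
    if n < min_overlap:
        return float("nan")
    return float((a[both] != b[both]).sum() / n)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix with compared-site counts.

    ``d[i, j]`` is NaN when the compared-site count fell below the overlap
    floor; the diagonal is exactly zero.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shapes must match id count")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = ~np.isnan(self.d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            np.where(finite, self.d, 0.0), np.where(finite, self.d, 0.0).T
        ):
            raise ValueError("matrix must be symmetric")

    def value(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.d[i, j])


def build_distance_matrix(
    seqs_by_gene: Mapping[str, Sequence[AlignedSeq]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Pooled multi-gene p-distance matrix.

    Mismatches and compared sites are pooled across genes before dividing,
    so longer fragments carry proportionally more weight.  Sequences are
    matched across genes by ``seq_id``; a sequence missing from a gene
    contributes no sites for that gene.
    """
    ids = sorted({s.seq_id for seqs in seqs_by_gene.values() for s in seqs})
    idx = {sid: k for k, sid in enumerate(ids)}
    n = len(ids)
    mism = np.zeros((n, n))
    comp = np.zeros((n, n))
    for gene, seqs in seqs_by_gene.items():
        if not seqs:
            continue
        mat = _encode(seqs)
        valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
        rows = [idx[s.seq_id] for s in seqs]
        for a in range(len(seqs)):
            for b in range(a + 1, len(seqs)):
                both = valid[a] & valid[b]
                nc = int(both.sum())
                nm = int((mat[a][both] != mat[b][both]).sum())
                i, j = rows[a], rows[b]
                comp[i, j] += nc
                comp[j, i] += nc
                mism[i, j] += nm
                mism[j, i] += nm
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comp >= min_overlap, mism / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(ids), d=d, n_sites=comp.astype(int))


@dataclass(frozen=True)
class OTUPartition:
    """Equivalence classes of sequences at a p-distance threshold."""

    clusters: tuple[frozenset[str], ...]
    threshold: float
    representatives: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        all_ids = [sid for c in self.clusters for sid in c]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("clusters must be disjoint")
        if self.representatives is not None:
            for k, rep in self.representatives.items():
                if rep not in self.clusters[k]:
                    raise ValueError(f"representative {rep!r} not in cluster {k}")

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    def otu_of(self, seq_id: str) -> int:
        for k, c in enumerate(self.clusters):
            if seq_id in c:
                return k
        raise KeyError(seq_id)


def cluster_otus(
    m: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> OTUPartition:
    """Single-linkage OTUs: transitive closure of links with d ≤ threshold.

    Two sequences share an OTU iff a chain of pairwise distances, each at
    most the threshold, connects them.  Missing (NaN) distances never form
    links.  Clusters are ordered by their lexicographically smallest
    member for determinism.
    """
    n = len(m.ids)
    adj = (m.d <= threshold) & ~np.isnan(m.d)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, set[str]] = {}
    for sid, lab in zip(m.ids, labels):
        groups.setdefault(int(lab), set()).add(sid)
    clusters = sorted((frozenset(g) for g in groups.values()), key=min)
    return OTUPartition(clusters=tuple(clusters), threshold=threshold)


def select_representative(
    cluster: Iterable[str], seqs: Sequence[AlignedSeq]
) -> str:
    """Pick the cluster member with the most resolved A/C/G/T sites.

    Resolved sites are summed over all genes present for each member; an
    exact tie is broken by the lexicographically smallest sequence id.
    """
    members = sorted(set(cluster))
    if not members:
        raise ValueError("cluster must be non-empty")
    resolved: dict[str, int] = {sid: 0 for sid in members}
    for s in seqs:
        if s.seq_id in resolved:
            resolved[s.seq_id] += s.n_resolved
    return min(members, key=lambda sid: (-resolved[sid], sid))


def assign_representatives(
    partition: OTUPartition, seqs: Sequence[AlignedSeq]
) -> OTUPartition:
    """Return a copy of the partition with one representative per OTU."""
    reps = {
        k: select_representative(c, seqs) for k, c in enumerate(partition.clusters)
    }
    return OTUPartition(
        clusters=partition.clusters,
        threshold=partition.threshold,
        representatives=reps,
    )
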