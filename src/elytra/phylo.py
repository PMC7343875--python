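"""Counting independent origins of a colour pattern and strict-clock dating.

A high-contrast mimetic pattern that appears only on isolated terminal
branches of a phylogeny ("single terminals") must have originated
independently in each of those lineages.  ``min_origins`` makes this
precise: leaves are recoded focal / non-focal, and a dynamic programme
over the tree finds — among *all* most-parsimonious reconstructions (MPRs)
of the internal states — the minimum and maximum number of origins, where
an origin is a non-focal→focal transition along an edge, plus one if the
root itself is reconstructed focal.  Restricting to MPRs matters:
unconstrained loss-heavy scenarios would trivially allow a single ancient
origin.

``time_scale`` converts per-partition branch lengths (substitutions/site)
to durations (My) with a strict molecular clock: each edge's duration is
the site-weighted mean of per-gene estimates ℓ_g / r_g.  The default rates
are the beetle mitochondrial rates 0.0115 (cox1), 0.0177 (nad5) and
0.0054 (rrnL) substitutions/site/My with fragment lengths 801, 1,359 and
831 sites.  This is an explicit strict-clock stand-in, not a relaxed-clock
Bayesian analysis; node ages from it are for parameter-recovery testing
and rough dating, not publication-grade divergence times.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

__all__ = [
    "PatternTree",
    "RateTable",
    "OriginReport",
    "PAPER_RATE_TABLE",
    "min_origins",
    "time_scale",
    "split_age",
    "node_ages",
]


@dataclass(frozen=True)
class RateTable:
    """Per-partition strict-clock rates (subs/site/My) and site counts."""

    rates: Mapping[str, float]
    sites: Mapping[str, int]

    def __post_init__(self) -> None:
        for g, r in self.rates.items():
            if r <= 0:
                raise ValueError(f"rate for {g!r} must be > 0, got {r}")
        for g, n in self.sites.items():
            if n < 1:
                raise ValueError(f"site count for {g!r} must be >= 1, got {n}")


#: Beetle mtDNA strict-clock defaults (subs/site/My; fragment lengths in sites).
PAPER_RATE_TABLE = RateTable(
    rates={"cox1": 0.0115, "nad5": 0.0177, "rrnL": 0.0054},
    sites={"cox1": 801, "nad5": 1359, "rrnL": 831},
)


@dataclass(frozen=True)
class OriginReport:
    """Origins of a focal pattern over all most-parsimonious reconstructions."""

    focal_state: str
    min_origins: int
    max_origins: int
    terminal_only: bool | None
    focal_leaf_count: int
    parsimony_cost: int


class PatternTree:
    """A rooted tree with per-partition branch lengths and leaf pattern states.

    Branch lengths are substitutions/site per partition (gene); leaf states
    are pattern labels (may be missing).  Construct from a single Newick
    (one partition) or from several Newick strings sharing a topology, one
    per gene.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        leaf_states: Mapping[str, str | None] | None = None,
    ) -> None:
        self.tree = tree
        self.leaf_states: dict[str, str | None] = dict(leaf_states or {})
        for node in tree.preorder_node_iter():
            if not hasattr(node, "partition_lengths"):
                node.partition_lengths = {}

    # -- construction -----------------------------------------------------

    @staticmethod
    def _parse(newick: str) -> dendropy.Tree:
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"malformed Newick: {exc}") from exc
        tree.is_rooted = True
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        return tree

    @classmethod
    def from_newick(
        cls,
        newick: str,
        partition: str = "all",
        leaf_states: Mapping[str, str | None] | None = None,
    ) -> "PatternTree":
        tree = cls._parse(newick)
        for node in tree.preorder_node_iter():
            node.partition_lengths = (
                {} if node.parent_node is None or node.edge.length is None
                else {partition: float(node.edge.length)}
            )
        return cls(tree, leaf_states)

    @classmethod
    def from_newicks(
        cls,
        newicks: Mapping[str, str],
        leaf_states: Mapping[str, str | None] | None = None,
    ) -> "PatternTree":
        """Merge one Newick per partition; topologies must be identical.

        Edges are matched across trees by the set of leaf labels below
        them, so the input files may order children differently.
        """
        if not newicks:
            raise ValueError("need at least one partition")
        items = sorted(newicks.items())
        base = cls._parse(items[0][1])

        def edge_map(tree: dendropy.Tree) -> dict[frozenset, float]:
            out = {}
            for node in tree.postorder_node_iter():
                if node.parent_node is None or node.edge.length is None:
                    continue
                key = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                out[key] = float(node.edge.length)
            return out

        maps = {gene: edge_map(cls._parse(nwk)) for gene, nwk in items}
        base_keys = set(edge_map(base))
        for gene, m in maps.items():
            if set(m) != base_keys:
                raise ValueError(
                    f"partition {gene!r} topology differs from the first partition"
                )
        for node in base.preorder_node_iter():
            node.partition_lengths = {}
            if node.parent_node is None:
                continue
            key = frozenset(lf.taxon.label for lf in node.leaf_iter())
            for gene, m in maps.items():
                if key in m:
                    node.partition_lengths[gene] = m[key]
        return cls(base, leaf_states)

    # -- convenience -------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def state_of(self, label: str) -> str | None:
        return self.leaf_states.get(label)


_INF = math.inf


def min_origins(
    tree: PatternTree, focal: str, root_state: str | None = None
) -> OriginReport:
    """Minimum and maximum independent origins of ``focal`` over all MPRs.

    Leaves are recoded focal / non-focal; leaves with missing state are
    wildcards.  Multifurcations are handled natively (children are summed).
    ``root_state`` may force the root to ``"focal"`` or ``"nonfocal"``,
    e.g. to encode outgroup knowledge; by default no root prior is imposed.
    """
    FOCAL, NON = 1, 0
    leaf_count = 0
    any_state = False
    for lf in tree.tree.leaf_node_iter():
        st = tree.leaf_states.get(lf.taxon.label)
        if st is not None:
            any_state = True
            if st == focal:
                leaf_count += 1
    if not any_state:
        raise ValueError("no leaf has a non-missing pattern state")

    # cost[s]: min changes in subtree given node state s;
    # omin/omax[s]: min/max origins below the node among cost-minimal choices.
    def visit(node) -> tuple[list[float], list[float], list[float]]:
        if node.is_leaf():
            st = tree.leaf_states.get(node.taxon.label)
            if st is None:
                return [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]
            s = FOCAL if st == focal else NON
            cost = [_INF, _INF]
            cost[s] = 0.0
            return cost, [0.0, 0.0], [0.0, 0.0]
        cost = [0.0, 0.0]
        omin = [0.0, 0.0]
        omax = [0.0, 0.0]
        for child in node.child_nodes():
            c_cost, c_omin, c_omax = visit(child)
            for s in (NON, FOCAL):
                options = []
                for sc in (NON, FOCAL):
                    if c_cost[sc] == _INF:
                        continue
                    w = 0 if s == sc else 1
                    gain = 1 if (s == NON and sc == FOCAL) else 0
                    options.append(
                        (c_cost[sc] + w, c_omin[sc] + gain, c_omax[sc] + gain)
                    )
                best = min(o[0] for o in options)
                cost[s] += best
                omin[s] += min(o[1] for o in options if o[0] == best)
                omax[s] += max(o[2] for o in options if o[0] == best)
        return cost, omin, omax

    root = tree.tree.seed_node
    cost, omin, omax = visit(root)
    allowed = {None: (NON, FOCAL), "focal": (FOCAL,), "nonfocal": (NON,)}[root_state]
    usable = [s for s in allowed if cost[s] < _INF]
    if not usable:
        raise ValueError("root state constraint is incompatible with leaf states")
    best_cost = min(cost[s] for s in usable)
    mins = [omin[s] + (1 if s == FOCAL else 0) for s in usable if cost[s] == best_cost]
    maxs = [omax[s] + (1 if s == FOCAL else 0) for s in usable if cost[s] == best_cost]
    mn, mx = int(min(mins)), int(max(maxs))
    terminal_only: bool | None = (mn == leaf_count) if leaf_count > 0 else None
    return OriginReport(
        focal_state=focal,
        min_origins=mn,
        max_origins=mx,
        terminal_only=terminal_only,
        focal_leaf_count=leaf_count,
        parsimony_cost=int(best_cost),
    )


def time_scale(tree: PatternTree, rates: RateTable) -> dendropy.Tree:
    """Convert substitution branch lengths to durations (My), strict clock.

    Each edge's duration is the site-weighted mean of per-partition
    estimates: t = Σ_g n_g·(ℓ_g / r_g) / Σ_g n_g over the partitions
    present on that edge.  Linear in the branch lengths.
    """
    src = tree.tree
    out = dendropy.Tree(src)  # structural copy sharing the taxon namespace
    for node_src, node_out in zip(
        src.preorder_node_iter(), out.preorder_node_iter()
    ):
        if node_src.parent_node is None:
            node_out.edge.length = None
            continue
        parts = getattr(node_src, "partition_lengths", {})
        usable = {g: l for g, l in parts.items() if l is not None}
        if not usable:
            raise ValueError(
                "edge above "
                f"{node_src.taxon.label if node_src.is_leaf() else 'internal node'}"
                " has no partition with a branch length"
            )
        num = 0.0
        den = 0.0
        for g, length in usable.items():
            if g not in rates.rates:
                raise KeyError(f"no rate for partition {g!r}")
            n_g = rates.sites.get(g, 1)
            num += n_g * (length / rates.rates[g])
            den += n_g
        node_out.edge.length = num / den
    return out


def _leaf_depths(time_tree: dendropy.Tree) -> dict:
    depths = {}
    for node in time_tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
        depths[node] = d
    return depths


def node_ages(time_tree: dendropy.Tree, mode: str = "mean") -> dict:
    """Age of every node: summarised root-to-leaf time below it.

    For a perfectly clock-like (ultrametric) tree all descendant paths
    agree; for noisy trees ``mode="mean"`` averages the descendant
    root-to-leaf paths (default) and ``mode="max"`` takes the deepest.
    Returns a dict node → age in the tree's time units; leaves have age 0.
    """
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    depths = _leaf_depths(time_tree)
    ages = {}
    for node in time_tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            spans = [depths[lf] - depths[node] for lf in node.leaf_iter()]
            ages[node] = float(
                sum(spans) / len(spans) if mode == "mean" else max(spans)
            )
    return ages


def split_age(
    time_tree: dendropy.Tree, leaf_a: str, leaf_b: str, mode: str = "mean"
) -> float:
    """Age (My) of the most recent common ancestor of two leaves.

    The MRCA's age is the mean (or max) root-to-leaf time over its
    descendant leaves; a leaf against itself has age 0.
    """
    taxa = {}
    for lf in time_tree.leaf_node_iter():
        taxa[lf.taxon.label] = lf.taxon
    for label in (leaf_a, leaf_b):
        if label not in taxa:
            raise KeyError(f"unknown leaf: {label!r}")
    if leaf_a == leaf_b:
        return 0.0
    mrca = time_tree.mrca(taxa=[taxa[leaf_a], taxa[leaf_b]])
    return node_ages(time_tree, mode=mode)[mrca]
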