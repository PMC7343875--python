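"""Parsimony origin counting against exhaustive enumeration, and
strict-clock time scaling."""

from itertools import product

import dendropy
import numpy as np
import pytest

from elytra import (
    PAPER_RATE_TABLE,
    PatternTree,
    RateTable,
    min_origins,
    node_ages,
    split_age,
    time_scale,
)
from elytra.simulate import ClockSimSpec, gen_clock_tree


def random_topology(rng, n):
    """Random binary Newick by repeated joining; leaves L0..L{n-1}."""
    nodes = [f"L{i}" for i in range(n)]
    while len(nodes) > 1:
        j, i = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        nodes.append(f"({nodes.pop(j)},{nodes.pop(i)})")
    return nodes[0] + ";"


def enumerate_origins(newick, states, focal):
    """Exhaustive oracle: try every internal labelling, keep the
    minimum-cost ones, and report (cost, min origins, max origins)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best_cost, omin, omax = None, None, None
    for bits in product((0, 1), repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), bits))

        def state(nd):
            if nd.is_leaf():
                return 1 if states[nd.taxon.label] == focal else 0
            return assign[id(nd)]

        cost = origins = 0
        for nd in tree.preorder_node_iter():
            s = state(nd)
            if nd.parent_node is None:
                origins += s == 1
                continue
            p = state(nd.parent_node)
            cost += s != p
            origins += p == 0 and s == 1
        if best_cost is None or cost < best_cost:
            best_cost, omin, omax = cost, origins, origins
        elif cost == best_cost:
            omin, omax = min(omin, origins), max(omax, origins)
    return best_cost, omin, omax


def fitch_cost(newick, states, focal):
    """Standard Fitch parsimony count on the binary recoding."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    cost = 0
    sets = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = {1 if states[nd.taxon.label] == focal else 0}
            continue
        acc = None
        for ch in nd.child_nodes():
            if acc is None:
                acc = sets[ch]
            else:
                inter = acc & sets[ch]
                if inter:
                    acc = inter
                else:
                    acc = acc | sets[ch]
                    cost += 1
        sets[nd] = acc
    return cost


class TestMinOrigins:
    def test_all_leaves_focal_single_root_origin(self):
        pt = PatternTree.from_newick(
            "((a:1,b:1):1,(c:1,d:1):1);",
            leaf_states={l: "C" for l in "abcd"},
        )
        rep = min_origins(pt, "C")
        assert rep.min_origins == 1 and rep.parsimony_cost == 0
        assert rep.terminal_only is False

    def test_two_separated_focal_leaves(self):
        """Without a root prior, a focal root with two losses ties the
        two-gains reconstruction (both cost 2), so origins span 1..2; a
        non-focal root — the outgroup situation — forces two origins.
        Both agree with the exhaustive oracle."""
        states = {"R1": "C", "R2": "C", "x": "A", "y": "A"}
        nwk = "((R1:1,x:1):1,(R2:1,y:1):1);"
        pt = PatternTree.from_newick(nwk, leaf_states=states)
        rep = min_origins(pt, "C")
        assert (rep.parsimony_cost, rep.min_origins, rep.max_origins) == (
            enumerate_origins(nwk, states, "C")
        )
        rooted = min_origins(pt, "C", root_state="nonfocal")
        assert rooted.min_origins == 2 and rooted.terminal_only is True

    def test_focal_cherry_is_one_origin_not_terminal_only(self):
        pt = PatternTree.from_newick(
            "(((R1:1,R2:1):1,x:1):1,(y:1,z:1):1);",
            leaf_states={"R1": "C", "R2": "C", "x": "A", "y": "A", "z": "A"},
        )
        rep = min_origins(pt, "C")
        assert rep.min_origins == 1
        assert rep.terminal_only is False

    def test_no_focal_leaves_flagged(self):
        pt = PatternTree.from_newick(
            "(a:1,b:1);", leaf_states={"a": "A", "b": "A"}
        )
        rep = min_origins(pt, "C")
        assert rep.min_origins == 0 and rep.terminal_only is None

    def test_missing_states_are_wildcards(self):
        pt = PatternTree.from_newick(
            "((a:1,b:1):1,c:1);", leaf_states={"a": "C", "b": None, "c": "A"}
        )
        rep = min_origins(pt, "C")
        assert rep.parsimony_cost == 1 and rep.min_origins == 1

    def test_matches_exhaustive_enumeration_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            nwk = random_topology(rng, n)
            labels = [f"L{i}" for i in range(n)]
            states = {l: ("C" if rng.random() < 0.4 else "A") for l in labels}
            pt = PatternTree.from_newick(nwk, leaf_states=states)
            rep = min_origins(pt, "C")
            cost, omin, omax = enumerate_origins(nwk, states, "C")
            assert rep.parsimony_cost == cost
            assert (rep.min_origins, rep.max_origins) == (omin, omax)
            assert rep.parsimony_cost == fitch_cost(nwk, states, "C")
            focal_n = sum(s == "C" for s in states.values())
            assert rep.focal_leaf_count == focal_n
            if focal_n:
                assert rep.terminal_only == (rep.min_origins == focal_n)

    def test_multifurcation_handled(self):
        pt = PatternTree.from_newick(
            "(a:1,b:1,c:1,(d:1,e:1):1);",
            leaf_states={"a": "C", "b": "A", "c": "C", "d": "A", "e": "A"},
        )
        rep = min_origins(pt, "C")
        cost, omin, omax = enumerate_origins(
            "(a,b,c,(d,e));",
            {"a": "C", "b": "A", "c": "C", "d": "A", "e": "A"},
            "C",
        )
        assert rep.parsimony_cost == cost
        assert (rep.min_origins, rep.max_origins) == (omin, omax)

    def test_root_state_constraint(self):
        pt = PatternTree.from_newick(
            "((a:1,b:1):1,c:1);", leaf_states={"a": "C", "b": "C", "c": "C"}
        )
        assert min_origins(pt, "C").min_origins == 1
        rep = min_origins(pt, "C", root_state="nonfocal")
        assert rep.min_origins >= 1 and rep.parsimony_cost >= 1


class TestTimeScale:
    def test_single_gene_definitional(self):
        pt = PatternTree.from_newick("(a:0.0115,b:0.0115);", partition="cox1")
        tt = time_scale(pt, PAPER_RATE_TABLE)
        lengths = [lf.edge.length for lf in tt.leaf_node_iter()]
        assert lengths == pytest.approx([1.0, 1.0])

    def test_two_genes_site_weighted(self):
        pt = PatternTree.from_newicks(
            {"g1": "(a:0.0230,b:0.0230);", "g2": "(a:0.0354,b:0.0354);"}
        )
        rates = RateTable(
            rates={"g1": 0.0115, "g2": 0.0177}, sites={"g1": 500, "g2": 500}
        )
        tt = time_scale(pt, rates)
        for lf in tt.leaf_node_iter():
            assert lf.edge.length == pytest.approx(2.0)

    def test_zero_lengths_give_zero_time(self):
        pt = PatternTree.from_newick("(a:0.0,b:0.0);", partition="cox1")
        tt = time_scale(pt, PAPER_RATE_TABLE)
        assert all(lf.edge.length == 0.0 for lf in tt.leaf_node_iter())

    def test_linearity_in_branch_lengths(self):
        sim = gen_clock_tree(ClockSimSpec(n_leaves=8, seed=4))
        tt1 = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
        for node in sim.pattern_tree.tree.preorder_node_iter():
            node.partition_lengths = {
                g: 2 * l for g, l in node.partition_lengths.items()
            }
        tt2 = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
        for n1, n2 in zip(tt1.preorder_node_iter(), tt2.preorder_node_iter()):
            if n1.edge.length is not None:
                assert n2.edge.length == pytest.approx(2 * n1.edge.length)

    def test_missing_rate_rejected(self):
        pt = PatternTree.from_newick("(a:0.1,b:0.1);", partition="mystery")
        with pytest.raises(KeyError):
            time_scale(pt, PAPER_RATE_TABLE)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            RateTable(rates={"g": 0.0}, sites={"g": 100})


class TestSplitAge:
    def test_noise_free_clock_inverts_exactly(self):
        sim = gen_clock_tree(ClockSimSpec(n_leaves=10, crown_age=12.0, seed=5))
        tt = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
        true_ages = node_ages(sim.true_time_tree)
        est_ages = node_ages(tt)
        for nt, ne in zip(
            sim.true_time_tree.preorder_node_iter(), tt.preorder_node_iter()
        ):
            assert est_ages[ne] == pytest.approx(true_ages[nt], abs=1e-9)

    def test_leaf_vs_itself_is_zero(self):
        sim = gen_clock_tree(ClockSimSpec(n_leaves=4, seed=1))
        tt = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
        leaf = sim.pattern_tree.leaf_labels[0]
        assert split_age(tt, leaf, leaf) == 0.0

    def test_unknown_leaf_rejected(self):
        sim = gen_clock_tree(ClockSimSpec(n_leaves=4, seed=1))
        tt = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
        with pytest.raises(KeyError):
            split_age(tt, "nope", sim.pattern_tree.leaf_labels[0])

    def test_planted_15my_split_recovered_under_poisson_noise(self):
        """Median relative error ≤ 10% over 100 seeds at the beetle rates
        and fragment lengths."""
        errors = []
        for s in range(100):
            sim = gen_clock_tree(
                ClockSimSpec(n_leaves=2, crown_age=15.0, poisson_noise=True, seed=s)
            )
            tt = time_scale(sim.pattern_tree, PAPER_RATE_TABLE)
            a, b = sim.pattern_tree.leaf_labels
            errors.append(abs(split_age(tt, a, b) - 15.0) / 15.0)
        assert np.median(errors) <= 0.10

    def test_age_error_shrinks_with_more_sites(self):
        def median_err(n_sites):
            rates = RateTable(rates={"g": 0.01}, sites={"g": n_sites})
            errs = []
            for s in range(40):
                sim = gen_clock_tree(
                    ClockSimSpec(
                        n_leaves=2, crown_age=10.0, rates=rates,
                        poisson_noise=True, seed=s,
                    )
                )
                tt = time_scale(sim.pattern_tree, rates)
                a, b = sim.pattern_tree.leaf_labels
                errs.append(abs(split_age(tt, a, b) - 10.0))
            return np.median(errs)

        assert median_err(5000) < median_err(500)


class TestPatternTreeIO:
    def test_from_newicks_requires_matching_topology(self):
        with pytest.raises(ValueError):
            PatternTree.from_newicks(
                {"g1": "((a:1,b:1):1,c:1);", "g2": "((a:1,c:1):1,b:1);"}
            )

    def test_from_newicks_matches_edges_across_child_order(self):
        pt = PatternTree.from_newicks(
            {"g1": "((a:1,b:2):3,c:4);", "g2": "(c:8,(b:6,a:5):7);"}
        )
        for lf in pt.tree.leaf_node_iter():
            if lf.taxon.label == "a":
                assert lf.partition_lengths == {"g1": 1.0, "g2": 5.0}

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError):
            PatternTree.from_newick("(a:1,a:1);")
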