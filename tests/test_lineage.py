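"""Lineage-tree construction, shape statistics and mutation ordering."""

import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

import clonmix as cm
from clonmix.lineage import (
    ROOT,
    TreeShapeStats,
    build_tree,
    build_trees,
    compare_tree_stats,
    mutation_order_precedes,
    star_tree_score,
    to_newick,
    tree_stats,
)

POSITIONS = [10, 20, 30, 40, 50, 60]


def _genotype_distance(a, b):
    da, db = dict(a), dict(b)
    return sum(1 for p in set(da) | set(db) if da.get(p) != db.get(p))


def _oracle_minimum(genotypes):
    """Exhaustive oracle: min spanning weight over terminals plus any subset
    of intersection-closure intermediates (scipy MST implementation)."""
    terms = [frozenset()] + sorted(
        {g for g in genotypes if g}, key=lambda g: (len(g), sorted(g))
    )
    closure = set(terms)
    while True:
        new = {
            frozenset(set(a) & set(b))
            for a, b in itertools.combinations(closure, 2)
        } - closure
        if not new:
            break
        closure |= new
    candidates = sorted(closure - set(terms), key=lambda g: (len(g), sorted(g)))
    best = None
    for r in range(0, len(terms) - 1):
        for subset in itertools.combinations(candidates, r):
            nodes = terms + list(subset)
            n = len(nodes)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    dist[i, j] = _genotype_distance(nodes[i], nodes[j])
            weight = minimum_spanning_tree(dist + dist.T).sum()
            if best is None or weight < best:
                best = weight
    return int(round(best))


def _random_clone(rng, ref, make_annotated, max_seqs=5, n_events=(1, 4)):
    """A clone sampled from a random genealogy over six positions
    (position reuse across edges allowed, so homoplasy can occur)."""
    n_seq = int(rng.integers(2, max_seqs + 1))
    genotypes, states = [], [{}]
    for _ in range(n_seq):
        parent = states[int(rng.integers(len(states)))]
        child = dict(parent)
        for _ in range(int(rng.integers(*n_events))):
            pos = POSITIONS[int(rng.integers(len(POSITIONS)))]
            current = child.get(pos, ref.base(pos))
            child[pos] = str(rng.choice([b for b in "ACGT" if b != current]))
        child = {p: b for p, b in child.items() if b != ref.base(p)}
        states.append(child)
        genotypes.append(frozenset(child.items()))
    unique = list(dict.fromkeys(genotypes))
    anns = [
        make_annotated(f"s{i:02d}", sorted(g)) for i, g in enumerate(unique)
    ]
    clone = cm.Clone(
        clone_id="c", mouse_id="m1", member_ids=[a.seq_id for a in anns],
        cdr3_len=3, representative_junction="GCTAGATAT",
        compartments=[("PP", "MEMORY")] * len(anns),
    )
    return clone, anns, unique


class TestBuildTree:
    def test_nested_mutations_give_a_chain(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(10, "C")])
        b = make_annotated("sB", [(10, "C"), (20, "A")])
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        assert to_newick(tree) == "((sB:1)sA:1)germline;"
        assert tree.total_mutations == 2

    def test_disjoint_mutations_give_a_star(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(10, "C")])
        b = make_annotated("sB", [(30, "A")])
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        assert to_newick(tree) == "(sA:1,sB:1)germline;"

    def test_shared_mutation_spawns_inferred_intermediate(
        self, ref, make_annotated, make_clone
    ):
        a = make_annotated("sA", [(10, "C"), (20, "A")])
        b = make_annotated("sB", [(10, "C"), (40, "T")])
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        assert tree.total_mutations == 3
        kinds = [d["kind"] for _, d in tree.graph.nodes(data=True)]
        assert kinds.count("inferred") == 1

    def test_unmutated_observed_sits_on_zero_edge(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [])
        b = make_annotated("sB", [(10, "C")])
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        assert tree.graph.edges[ROOT, "sA"]["mutations"] == 0

    def test_duplicates_collapse_with_multiplicity(self, ref, make_annotated, make_clone):
        anns = [make_annotated(s, [(10, "C")]) for s in ("sA", "sB", "sC")]
        tree = build_tree(make_clone("c", ["sA", "sB", "sC"]), anns, ref)
        assert tree.graph.nodes["sA"]["multiplicity"] == 3
        assert tree_stats(tree).n_leaves == 1

    def test_empty_clone_rejected(self, ref, make_clone):
        with pytest.raises(ValueError, match="no members"):
            build_tree(make_clone("c", []), [], ref)

    def test_indel_member_attached_via_flagged_edge(
        self, ref, make_annotated, make_clone
    ):
        a = make_annotated("sA", [(10, "C")])
        b = make_annotated("sB", [(20, "A")], n_indels=1)
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        assert tree.graph.edges[ROOT, "sB"]["flagged"]
        assert tree_stats(tree).n_leaves == 1  # flagged subtree excluded

    def test_matches_exhaustive_oracle_on_random_clones(self, ref, make_annotated):
        rng = np.random.default_rng(31)
        for _ in range(100):
            clone, anns, genotypes = _random_clone(rng, ref, make_annotated)
            tree = build_tree(clone, anns, ref)
            assert tree.total_mutations == _oracle_minimum(genotypes)
            assert tree.total_mutations <= star_tree_score(clone, anns)

    def test_greedy_fallback_is_valid_and_bounded(self, ref, make_annotated):
        rng = np.random.default_rng(13)
        for _ in range(50):
            clone, anns, genotypes = _random_clone(rng, ref, make_annotated)
            tree = build_tree(clone, anns, ref, exact_max_genotypes=0)
            assert tree.total_mutations <= star_tree_score(clone, anns)
            # structural invariants: observed nodes present once; edge
            # weights equal genotype distances; path sums equal distances
            observed = [
                n for n, d in tree.graph.nodes(data=True) if d["kind"] == "observed"
            ]
            assert len(observed) == len(genotypes)
            for u, v, d in tree.graph.edges(data=True):
                assert d["mutations"] == _genotype_distance(
                    tree.graph.nodes[u]["genotype"], tree.graph.nodes[v]["genotype"]
                )
            for path in tree.paths_to_leaves():
                total = sum(
                    tree.graph.edges[u, v]["mutations"]
                    for u, v in zip(path, path[1:])
                )
                leaf_genotype = tree.graph.nodes[path[-1]]["genotype"]
                # path length bounded below by direct germline distance
                assert total >= len(leaf_genotype)


class TestTreeStats:
    def test_single_sequence_chain(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(10, "C"), (20, "A"), (30, "T")])
        stats = tree_stats(build_tree(make_clone("c", ["sA"]), [a], ref))
        assert stats.pl_min == stats.pl_max == 3.0
        assert stats.unbranched and stats.trunk_length == 3.0

    def test_star_of_three(self, ref, make_annotated, make_clone):
        anns = [
            make_annotated("sA", [(10, "C")]),
            make_annotated("sB", [(20, "A")]),
            make_annotated("sC", [(30, "T")]),
        ]
        stats = tree_stats(
            build_tree(make_clone("c", ["sA", "sB", "sC"]), anns, ref)
        )
        assert stats.trunk_length == 0.0
        assert stats.pl_min == 1.0 and stats.max_out_degree == 3

    def test_invariants_over_many_random_genealogies(self, ref):
        from clonmix.annotation import AnnotatedSequence, mutation_from_parts

        cfg = cm.SimulationConfig(
            seed=19, n_mice=1, clones_per_group=3500,
            clone_size_dist=("geometric", 0.45), target_mut_mean=5.0,
            trunk_edges=1,
        )
        _, truth = cm.simulate_repertoire(cfg, ref)
        assert len(truth.clones) >= 3000
        by_clone = {}
        for sid, info in truth.sequences.items():
            by_clone.setdefault(info["clone_id"], []).append((sid, info))
        checked = 0
        for clone_id, members in by_clone.items():
            anns = []
            for sid, info in members:
                rec = cm.SequenceRecord(sid, ref.nt_seq, "m1", "PP", "MEMORY", "IgA")
                ann = AnnotatedSequence(record=rec)
                ann.mutations = [
                    mutation_from_parts(p, f, t, ref)
                    for p, f, t in info["net_mutations"]
                ]
                ann.n_mutations = len(ann.mutations)
                anns.append(ann)
            clone = cm.Clone(
                clone_id=clone_id, mouse_id="m1",
                member_ids=[a.seq_id for a in anns], cdr3_len=3,
                representative_junction="GCTAGATAT",
                compartments=[("PP", "MEMORY")] * len(anns),
            )
            stats = tree_stats(build_tree(clone, anns, ref))
            assert stats.pl_min <= stats.pl_mean <= stats.pl_max
            assert stats.trunk_length <= stats.pl_min
            checked += 1
        assert checked >= 3000

    def test_path_lengths_track_truth_loads(self, ref, long_run):
        # leaves sit at or below their genotype's germline distance, so the
        # extreme path lengths bound the recorded per-sequence loads; for
        # singleton clones (chains) pl_min equals the recorded load exactly
        by_id = {a.seq_id: a for a in long_run["dataset"]}
        truth = long_run["truth"]
        n_singletons = 0
        for clone in long_run["clones"]:
            tree = build_tree(clone, by_id, ref)
            stats = tree_stats(tree)
            loads = [
                len(truth.sequences[m]["net_mutations"]) for m in clone.member_ids
            ]
            assert stats.pl_min >= min(loads)
            assert stats.pl_max >= max(loads)
            if clone.size == 1:
                n_singletons += 1
                assert stats.pl_min == stats.pl_max == loads[0]
        assert n_singletons >= 5  # the clone-size law makes singletons common


class TestCompare:
    def _stats(self, values):
        return [
            TreeShapeStats("c", 1, 1, 0, v, v, v, v, 1, True) for v in values
        ]

    def test_identical_lists_give_p_one(self):
        stats = self._stats([2.0, 2.0, 2.0])
        assert compare_tree_stats(stats, stats, "pl_min")["p"] == 1.0

    def test_unknown_field_lists_available(self):
        with pytest.raises(ValueError, match="pl_min"):
            compare_tree_stats(self._stats([1]), self._stats([2]), "banana")

    def test_single_element_lists_warn(self):
        out = compare_tree_stats(self._stats([1.0]), self._stats([5.0]), "trunk_length")
        assert np.isfinite(out["p"]) and "uncertainty" in out["warning"]


class TestMutationOrder:
    def test_chain_orders_positions(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(98, "T")])
        b = make_annotated("sB", [(98, "T"), (102, "A")])
        tree = build_tree(make_clone("c", ["sA", "sB"]), [a, b], ref)
        out = mutation_order_precedes([tree], 98, 102)
        assert out["a_first"] == 1 and out["b_first"] == 0
        assert out["b_never_precedes_a"]

    def test_same_edge_counts_as_tie(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(98, "T"), (102, "A")])
        tree = build_tree(make_clone("c", ["sA"]), [a], ref)
        out = mutation_order_precedes([tree], 98, 102)
        assert out["same_edge"] == 1

    def test_position_outside_v_region_rejected(self, ref, make_annotated, make_clone):
        a = make_annotated("sA", [(98, "T")])
        tree = build_tree(make_clone("c", ["sA"]), [a], ref)
        with pytest.raises(ValueError, match="outside"):
            mutation_order_precedes([tree], 98, 9999)

    def test_np_select_never_mutates_102_before_98(self, ref, long_run):
        trees = build_trees(long_run["clones"], long_run["dataset"], ref)
        out = mutation_order_precedes(trees, 102, 98)
        assert out["a_never_precedes_b"]
        assert out["both_mutated"] >= 1


def test_newick_is_parseable(ref, long_run):
    from io import StringIO

    from Bio import Phylo

    trees = build_trees(long_run["clones"][:10], long_run["dataset"], ref)
    for tree in trees:
        parsed = Phylo.read(StringIO(to_newick(tree)), "newick")
        named = [c.name for c in parsed.find_clades() if c.name]
        assert "germline" in named
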