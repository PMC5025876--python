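"""Per-clone lineage trees rooted at the germline.

Every node carries a V-region genotype — the set of ``(position, base)``
substitutions relative to the germline — so edge lengths are Hamming
distances between full V sequences and the path length from the root to any
node equals that node's mutation distance from germline.  Junction
variation within a clone is not part of the tree.

Small clones are solved exactly: the builder searches for the
minimum-mutation (Steiner) tree over the observed genotypes plus candidate
intermediates drawn from the intersection closure of the observed sets.
Larger clones fall back to a greedy agglomeration that attaches each
genotype to the parent (an existing node, or a freshly inferred
shared-mutation intersection spliced into an existing edge) that adds the
fewest edge mutations.  Parallel mutations are kept as-is: no homoplasy
minimisation beyond the greedy step.

Shape statistics follow the conventions used for B-cell lineage analysis:
``pl_min``/``pl_max``/``pl_mean`` are root-to-leaf path lengths in
mutations, and ``trunk_length`` is the mutation count from the root to the
first branching node (for unbranched trees the whole root-to-leaf path,
flagged ``unbranched`` so analyses can exclude chains).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sstats

from .annotation import AnnotatedSequence
from .clonality import Clone
from .io import GermlineReference

Genotype = frozenset  # of (pos_nt, to_base) pairs

ROOT = "root"


def genotype_distance(a: Genotype, b: Genotype) -> int:
    """Hamming distance between the V sequences implied by two genotypes."""
    da, db = dict(a), dict(b)
    return sum(1 for p in set(da) | set(db) if da.get(p) != db.get(p))


def genotype_intersection(a: Genotype, b: Genotype) -> Genotype:
    return frozenset(set(a) & set(b))


@dataclass
class LineageTree:
    """Rooted mutation tree of one clone.

    ``graph`` is a directed tree whose nodes carry ``genotype`` (the
    substitution set), ``kind`` (root/observed/inferred), ``multiplicity``
    and ``seq_ids``; edge attribute ``mutations`` is the Hamming distance
    between the incident genotypes, ``flagged`` marks indel-discordant
    attachments excluded from shape statistics.
    """

    clone_id: str
    graph: nx.DiGraph
    v_length: int

    @property
    def total_mutations(self) -> int:
        return sum(
            d["mutations"] for _, _, d in self.graph.edges(data=True) if not d["flagged"]
        )

    def paths_to_leaves(self) -> list[list[str]]:
        """Root-to-leaf node paths, skipping flagged subtrees."""
        paths = []

        def walk(node: str, path: list[str]) -> None:
            children = [
                c for c in self.graph.successors(node)
                if not self.graph.edges[node, c]["flagged"]
            ]
            if not children:
                if len(path) > 1 or self.graph.nodes[node]["kind"] != "root":
                    paths.append(path)
                return
            for c in sorted(children):
                walk(c, path + [c])

        walk(ROOT, [ROOT])
        return paths


@dataclass
class TreeShapeStats:
    clone_id: str
    n_nodes: int
    n_leaves: int
    n_inferred: int
    pl_min: float
    pl_max: float
    pl_mean: float
    trunk_length: float
    max_out_degree: int
    unbranched: bool

    FIELDS = ("pl_min", "pl_max", "pl_mean", "trunk_length", "max_out_degree",
              "n_nodes", "n_leaves", "n_inferred")


# --- exact small-instance construction --------------------------------------

def _intersection_closure(terminals: Sequence[Genotype]) -> list[Genotype]:
    closure = set(terminals) | {frozenset()}
    while True:
        new = set()
        for a, b in itertools.combinations(closure, 2):
            i = genotype_intersection(a, b)
            if i not in closure:
                new.add(i)
        if not new:
            break
        closure |= new
    return sorted(closure, key=lambda g: (len(g), sorted(g)))


def _mst_weight_and_edges(nodes: Sequence[Genotype]) -> tuple[int, list[tuple[int, int]]]:
    """Prim's minimum spanning tree over genotypes under Hamming distance."""
    n = len(nodes)
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = genotype_distance(nodes[i], nodes[j])
            dist[i, j] = dist[j, i] = d
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best_from = np.zeros(n, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    total = 0
    for _ in range(n - 1):
        cand = np.where(~in_tree)[0]
        k = cand[np.argmin(best[cand])]
        total += int(best[k])
        edges.append((int(best_from[k]), int(k)))
        in_tree[k] = True
        closer = dist[k] < best
        best_from[closer & ~in_tree] = k
        best = np.where(closer & ~in_tree, dist[k], best)
    return total, edges


MAX_STEINER_CANDIDATES = 12


def _steiner_tree(terminals: Sequence[Genotype]) -> tuple[int, list[Genotype], list[tuple[int, int]]] | None:
    """Minimum-mutation tree over terminals plus intersection intermediates.

    Searches subsets of candidate intermediates (at most ``len(terminals)-2``
    are ever needed, since Steiner points have degree >= 3) and keeps the
    spanning tree of smallest total weight; ties prefer fewer intermediates.
    Returns None when the candidate set is too large for exhaustive search
    (the caller then falls back to the greedy builder).
    """
    terminals = list(terminals)
    term_set = set(terminals)
    candidates = [g for g in _intersection_closure(terminals) if g not in term_set]
    if len(candidates) > MAX_STEINER_CANDIDATES:
        return None
    max_extra = max(0, len(terminals) - 2)
    best: tuple[int, int, list[Genotype], list[tuple[int, int]]] | None = None
    for r in range(0, min(max_extra, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, r):
            nodes = terminals + list(subset)
            weight, edges = _mst_weight_and_edges(nodes)
            key = (weight, r)
            if best is None or key < (best[0], best[1]):
                best = (weight, r, nodes, edges)
    assert best is not None
    return best[0], best[2], best[3]


# --- greedy construction ------------------------------------------------------

def _greedy_tree(
    genotypes: Mapping[str, Genotype], order: Sequence[str]
) -> tuple[dict[str, Genotype], dict[str, str]]:
    """Greedy agglomeration; returns (node genotypes, parent map).

    Each genotype is attached to the candidate parent minimising added edge
    mutations: either an existing node directly, or a new inferred
    intermediate (the shared-mutation intersection with an existing node)
    spliced into that node's parent edge.  Ties prefer more shared
    mutations, then the lexicographically smaller anchor node id.
    """
    nodes: dict[str, Genotype] = {ROOT: frozenset()}
    parent: dict[str, str] = {}
    n_inferred = 0

    for name in order:
        m = genotypes[name]
        best = None  # (cost, -shared, anchor_id, plan)
        for pid, pg in nodes.items():
            cost = genotype_distance(m, pg)
            key = (cost, -len(genotype_intersection(m, pg)), pid)
            if best is None or key < best[:3]:
                best = key + (("direct", pid),)
        for pid, pg in nodes.items():
            if pid == ROOT or pid not in parent:
                continue
            qid = parent[pid]
            qg = nodes[qid]
            ig = genotype_intersection(m, pg)
            if ig == pg or ig == qg or any(g == ig for g in nodes.values()):
                continue
            cost = (
                genotype_distance(ig, qg)
                + genotype_distance(pg, ig)
                - genotype_distance(pg, qg)
                + genotype_distance(m, ig)
            )
            key = (cost, -len(ig), pid)
            if key < best[:3]:
                best = key + (("insert", pid, ig),)
        plan = best[3]
        if plan[0] == "direct":
            parent[name] = plan[1]
        else:
            _, pid, ig = plan
            n_inferred += 1
            iid = f"i{n_inferred}"
            nodes[iid] = ig
            parent[iid] = parent[pid]
            parent[pid] = iid
            parent[name] = iid
        nodes[name] = m
    return nodes, parent


# --- public API ---------------------------------------------------------------

EXACT_MAX_GENOTYPES = 6
EXACT_MAX_POSITIONS = 8


def build_tree(
    clone: Clone,
    dataset: Mapping[str, AnnotatedSequence] | Sequence[AnnotatedSequence],
    ref: GermlineReference,
    exact_max_genotypes: int = EXACT_MAX_GENOTYPES,
    exact_max_positions: int = EXACT_MAX_POSITIONS,
) -> LineageTree:
    """Build the lineage tree of one clone.

    Clones whose distinct-genotype count and mutated-position count are
    small are solved exactly (minimum total mutation count over the
    intersection-closure candidate set); larger clones use the greedy
    agglomeration.  Indel-bearing members are attached to the root via a
    flagged edge and excluded from shape statistics.
    """
    if isinstance(dataset, Mapping):
        by_id = dataset
    else:
        by_id = {a.seq_id: a for a in dataset}
    members = [by_id[m] for m in clone.member_ids]
    if not members:
        raise ValueError(f"clone {clone.clone_id}: no members")

    clean = [m for m in members if m.n_indels == 0]
    discordant = [m for m in members if m.n_indels > 0]

    geno_members: dict[Genotype, list[str]] = {}
    for m in clean:
        if m.n_mutations is None:
            raise ValueError(f"{m.seq_id}: mutations must be called before tree building")
        g = frozenset((mut.pos_nt, mut.to_base) for mut in m.mutations)
        geno_members.setdefault(g, []).append(m.seq_id)

    graph = nx.DiGraph()
    graph.add_node(ROOT, genotype=frozenset(), kind="root", multiplicity=0, seq_ids=[])

    distinct = sorted(
        (g for g in geno_members if g), key=lambda g: (len(g), sorted(g))
    )
    node_name = {g: min(geno_members[g]) for g in distinct}
    positions = {p for g in distinct for p, _ in g}

    steiner = None
    if distinct and len(distinct) <= exact_max_genotypes and len(positions) <= exact_max_positions:
        steiner = _steiner_tree([frozenset()] + list(distinct))
    if steiner is not None:
        _, nodes, edges = steiner
        undirected = nx.Graph()
        names: dict[int, str] = {}
        n_inferred = 0
        for idx, g in enumerate(nodes):
            if idx == 0:
                names[idx] = ROOT
            elif g in node_name:
                names[idx] = node_name[g]
            else:
                n_inferred += 1
                names[idx] = f"i{n_inferred}"
            if names[idx] != ROOT:
                graph.add_node(
                    names[idx],
                    genotype=g,
                    kind="observed" if g in node_name else "inferred",
                    multiplicity=len(geno_members.get(g, [])),
                    seq_ids=sorted(geno_members.get(g, [])),
                )
        for i, j in edges:
            undirected.add_edge(names[i], names[j])
        for u, v in nx.bfs_edges(undirected, ROOT):
            graph.add_edge(
                u,
                v,
                mutations=genotype_distance(
                    graph.nodes[u]["genotype"], graph.nodes[v]["genotype"]
                ),
                flagged=False,
            )
    elif distinct:
        genotypes = {node_name[g]: g for g in distinct}
        order = [node_name[g] for g in distinct]
        nodes, parent = _greedy_tree(genotypes, order)
        for name, g in nodes.items():
            if name == ROOT:
                continue
            observed = name in genotypes
            graph.add_node(
                name,
                genotype=g,
                kind="observed" if observed else "inferred",
                multiplicity=len(geno_members.get(g, [])) if observed else 0,
                seq_ids=sorted(geno_members.get(g, [])) if observed else [],
            )
        for child, par in parent.items():
            graph.add_edge(
                par,
                child,
                mutations=genotype_distance(nodes[par], nodes[child]),
                flagged=False,
            )

    # observed unmutated sequences: own node on a zero-mutation root edge
    if frozenset() in geno_members:
        ids = sorted(geno_members[frozenset()])
        graph.add_node(
            ids[0], genotype=frozenset(), kind="observed",
            multiplicity=len(ids), seq_ids=ids,
        )
        graph.add_edge(ROOT, ids[0], mutations=0, flagged=False)

    for m in discordant:
        g = frozenset((mut.pos_nt, mut.to_base) for mut in m.mutations)
        graph.add_node(
            m.seq_id, genotype=g, kind="observed", multiplicity=1, seq_ids=[m.seq_id]
        )
        graph.add_edge(ROOT, m.seq_id, mutations=len(g), flagged=True)

    return LineageTree(clone_id=clone.clone_id, graph=graph, v_length=len(ref.nt_seq))


def tree_stats(tree: LineageTree) -> TreeShapeStats:
    """Shape statistics of one lineage tree (flagged edges excluded)."""
    g = tree.graph
    depth = {ROOT: 0}
    order = [ROOT]
    for node in order:
        for child in g.successors(node):
            if g.edges[node, child]["flagged"]:
                continue
            depth[child] = depth[node] + g.edges[node, child]["mutations"]
            order.append(child)
    out_deg = {
        n: sum(1 for c in g.successors(n) if not g.edges[n, c]["flagged"])
        for n in depth
    }
    leaves = [n for n in depth if out_deg[n] == 0 and n != ROOT]
    pls = [depth[n] for n in leaves]

    trunk = 0.0
    unbranched = False
    node = ROOT
    if out_deg[ROOT] == 0:
        unbranched = True
    while out_deg[node] == 1:
        child = next(
            c for c in g.successors(node) if not g.edges[node, c]["flagged"]
        )
        trunk += g.edges[node, child]["mutations"]
        node = child
        if out_deg[node] == 0:
            unbranched = True
            break

    n_inferred = sum(1 for n in depth if g.nodes[n]["kind"] == "inferred")
    return TreeShapeStats(
        clone_id=tree.clone_id,
        n_nodes=len(depth),
        n_leaves=len(leaves),
        n_inferred=n_inferred,
        pl_min=float(min(pls)) if pls else float("nan"),
        pl_max=float(max(pls)) if pls else float("nan"),
        pl_mean=float(np.mean(pls)) if pls else float("nan"),
        trunk_length=trunk,
        max_out_degree=max(out_deg.values()) if out_deg else 0,
        unbranched=unbranched,
    )


def compare_tree_stats(
    trees_a: Sequence[TreeShapeStats],
    trees_b: Sequence[TreeShapeStats],
    statistic: str,
) -> dict:
    """Two-sided Mann-Whitney comparison of a named shape statistic."""
    if statistic not in TreeShapeStats.FIELDS:
        raise ValueError(
            f"unknown statistic {statistic!r}; available: {TreeShapeStats.FIELDS}"
        )
    if not trees_a or not trees_b:
        raise ValueError("both tree lists must be non-empty")
    a = np.array([getattr(t, statistic) for t in trees_a], dtype=float)
    b = np.array([getattr(t, statistic) for t in trees_b], dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    result = {
        "statistic": statistic,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)) if a.size else float("nan"),
        "median_b": float(np.median(b)) if b.size else float("nan"),
        "warning": "single-observation groups: p has wide uncertainty"
        if min(a.size, b.size) <= 1
        else "",
    }
    if a.size == 0 or b.size == 0:
        result["p"] = float("nan")
        return result
    if np.unique(np.concatenate([a, b])).size == 1:
        result["p"] = 1.0  # fully tied: no evidence of difference, by definition
        return result
    _, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
    result["p"] = float(p)
    return result


def mutation_order_precedes(
    trees: Sequence[LineageTree], pos_a: int, pos_b: int
) -> dict:
    """Order of first mutation at two germline positions along lineage paths.

    Counts, over all root-to-leaf paths in all trees, whether position
    ``pos_a`` first mutates before ``pos_b``, after it, on the same edge,
    or whether only one/neither mutates.  ``a_never_precedes_b`` is True
    when no path mutates ``a`` strictly before ``b`` while at least one
    path mutates both.
    """
    for pos, tree in itertools.product((pos_a, pos_b), trees[:1]):
        if not 1 <= pos <= tree.v_length:
            raise ValueError(f"position {pos} outside the V region 1..{tree.v_length}")
    counts = {
        "a_first": 0, "b_first": 0, "same_edge": 0,
        "only_a": 0, "only_b": 0, "neither": 0, "n_paths": 0,
    }
    for tree in trees:
        g = tree.graph
        for path in tree.paths_to_leaves():
            first = {pos_a: None, pos_b: None}
            for step, (u, v) in enumerate(zip(path, path[1:])):
                gu, gv = dict(g.nodes[u]["genotype"]), dict(g.nodes[v]["genotype"])
                for pos in (pos_a, pos_b):
                    if first[pos] is None and gu.get(pos) != gv.get(pos):
                        first[pos] = step
            fa, fb = first[pos_a], first[pos_b]
            counts["n_paths"] += 1
            if fa is None and fb is None:
                counts["neither"] += 1
            elif fb is None:
                counts["only_a"] += 1
            elif fa is None:
                counts["only_b"] += 1
            elif fa < fb:
                counts["a_first"] += 1
            elif fb < fa:
                counts["b_first"] += 1
            else:
                counts["same_edge"] += 1
    both = counts["a_first"] + counts["b_first"] + counts["same_edge"]
    counts["both_mutated"] = both
    counts["a_never_precedes_b"] = counts["a_first"] == 0 and both >= 1
    counts["b_never_precedes_a"] = counts["b_first"] == 0 and both >= 1
    return counts


def star_tree_score(clone: Clone, dataset) -> int:
    """Sum of member distances to germline (the no-sharing upper bound)."""
    if not isinstance(dataset, Mapping):
        dataset = {a.seq_id: a for a in dataset}
    seen: set[Genotype] = set()
    total = 0
    for mid in clone.member_ids:
        ann = dataset[mid]
        g = frozenset((m.pos_nt, m.to_base) for m in ann.mutations)
        if g not in seen:
            seen.add(g)
            total += len(g)
    return total


def to_newick(tree: LineageTree) -> str:
    """Newick export with edge lengths in mutations; inferred nodes keep i#."""
    g = tree.graph

    def render(node: str) -> str:
        children = sorted(g.successors(node))
        label = "germline" if node == ROOT else node
        if not children:
            return label
        inner = ",".join(
            f"{render(c)}:{g.edges[node, c]['mutations']}" for c in children
        )
        return f"({inner}){label}"

    return render(ROOT) + ";"


def build_trees(
    clones: Sequence[Clone],
    dataset: Sequence[AnnotatedSequence],
    ref: GermlineReference,
    min_size: int = 1,
) -> list[LineageTree]:
    by_id = {a.seq_id: a for a in dataset}
    return [
        build_tree(c, by_id, ref) for c in clones if c.size >= min_size
    ]
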