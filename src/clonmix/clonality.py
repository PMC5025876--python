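"""Clonal grouping and the mixed-clone bootstrap null model.

Sequences from one mouse belong to the same clone when they share CDR3
amino-acid length and their junction nucleotide identity reaches the
clustering threshold (single linkage, default 0.90; threshold 1.0 gives the
strict shared-rearrangement definition used for low-throughput data).

The central statistic is the number of *mixed clones* — clones holding
members of two compartments or cell subsets (e.g. memory B cells and
long-lived plasma cells).  Its significance is assessed against a random
partition null: each bootstrap run keeps the observed cell counts and clone
counts per mouse group, reassigns cells to clones at random, and counts
mixed clones; the observed count is then compared with the null by a
two-sided z-test (normal approximation), with the empirical tail fraction
reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .annotation import AnnotatedSequence

MODE_PRESERVE_SIZES = "PRESERVE_SIZES"
MODE_UNIFORM_PARTITION = "UNIFORM_PARTITION"

VERDICT_FEWER = "FEWER_MIXED_THAN_NULL"
VERDICT_MORE = "MORE_MIXED_THAN_NULL"
VERDICT_NULL = "CONSISTENT_WITH_NULL"

UNASSIGNED = "unassigned"


@dataclass
class Clone:
    """A set of sequences sharing a V(D)J rearrangement."""

    clone_id: str
    mouse_id: str
    member_ids: list[str]
    cdr3_len: int
    representative_junction: str
    # multiset of (compartment, subset) labels over members
    compartments: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def count(self, key: str, label: str) -> int:
        idx = 0 if key == "compartment" else 1
        return sum(1 for pair in self.compartments if pair[idx] == label)

    def is_mixed(self, label_a: str, label_b: str, key: str = "subset") -> bool:
        return self.count(key, label_a) > 0 and self.count(key, label_b) > 0


def junction_identity(a: str, b: str) -> float:
    """Fraction of identical nucleotides between equal-length junctions."""
    if len(a) != len(b):
        raise ValueError("junction identity requires equal lengths")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_clones(
    dataset: Sequence[AnnotatedSequence], threshold: float = 0.90
) -> tuple[list[Clone], list[str]]:
    """Single-linkage clonal grouping within each mouse.

    Returns ``(clones, unassigned_ids)``; sequences without a defined CDR3
    land in the unassigned pool, never silently dropped.  Output is
    deterministic for any input order: members are sorted by seq_id and
    clone ids are assigned per mouse by sorted representative.
    """
    unassigned: list[str] = []
    eligible: dict[tuple[str, int], list[AnnotatedSequence]] = {}
    for ann in dataset:
        if not ann.usable or not ann.cdr3_nt:
            unassigned.append(ann.seq_id)
            continue
        eligible.setdefault((ann.record.mouse_id, len(ann.cdr3_aa)), []).append(ann)

    proto: list[tuple[str, list[AnnotatedSequence]]] = []  # (mouse, members)
    for (mouse, _), members in eligible.items():
        members = sorted(members, key=lambda a: a.seq_id)
        uf = _UnionFind(len(members))
        for i, j in itertools.combinations(range(len(members)), 2):
            if junction_identity(members[i].cdr3_nt, members[j].cdr3_nt) >= threshold:
                uf.union(i, j)
        groups: dict[int, list[AnnotatedSequence]] = {}
        for i, m in enumerate(members):
            groups.setdefault(uf.find(i), []).append(m)
        for g in groups.values():
            proto.append((mouse, g))

    clones: list[Clone] = []
    by_mouse: dict[str, list[tuple[str, list[AnnotatedSequence]]]] = {}
    for mouse, g in proto:
        by_mouse.setdefault(mouse, []).append((g[0].seq_id, g))
    for mouse in sorted(by_mouse):
        for i, (_, g) in enumerate(sorted(by_mouse[mouse]), start=1):
            clone = Clone(
                clone_id=f"{mouse}_c{i:03d}",
                mouse_id=mouse,
                member_ids=[m.seq_id for m in g],
                cdr3_len=len(g[0].cdr3_aa),
                representative_junction=g[0].cdr3_nt,
                compartments=[(m.record.compartment, m.record.subset) for m in g],
            )
            for m in g:
                m.clone_id = clone.clone_id
            clones.append(clone)
    return clones, sorted(unassigned)


def count_mixed(
    clones: Iterable[Clone], label_a: str, label_b: str, key: str = "subset"
) -> int:
    return sum(1 for c in clones if c.is_mixed(label_a, label_b, key=key))


def overlap_table(
    clones: Sequence[Clone], label_a: str, label_b: str, key: str = "subset"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-compartment clone composition, per mouse.

    Returns ``(summary, detail)``: the summary has one row per mouse with
    mixed-clone counts and the fraction of axis-a sequences residing in
    mixed clones; the detail has one row per mixed clone with the fraction
    of each axis's sequences it contains.  A label absent from a mouse
    yields a zero row, not an exception.
    """
    mice = sorted({c.mouse_id for c in clones})
    summary_rows, detail_rows = [], []
    for mouse in mice:
        mine = [c for c in clones if c.mouse_id == mouse]
        n_a = sum(c.count(key, label_a) for c in mine)
        n_b = sum(c.count(key, label_b) for c in mine)
        mixed = [c for c in mine if c.is_mixed(label_a, label_b, key=key)]
        a_in_mixed = sum(c.count(key, label_a) for c in mixed)
        b_in_mixed = sum(c.count(key, label_b) for c in mixed)
        summary_rows.append(
            {
                "mouse_id": mouse,
                "n_clones": len(mine),
                "n_mixed": len(mixed),
                f"n_{label_a}": n_a,
                f"n_{label_b}": n_b,
                f"n_{label_a}_in_mixed": a_in_mixed,
                f"frac_{label_a}_in_mixed": a_in_mixed / n_a if n_a else 0.0,
                f"frac_{label_b}_in_mixed": b_in_mixed / n_b if n_b else 0.0,
            }
        )
        for c in mixed:
            detail_rows.append(
                {
                    "mouse_id": mouse,
                    "clone_id": c.clone_id,
                    "size": c.size,
                    f"n_{label_a}": c.count(key, label_a),
                    f"n_{label_b}": c.count(key, label_b),
                    f"frac_of_{label_a}": c.count(key, label_a) / n_a if n_a else 0.0,
                    f"frac_of_{label_b}": c.count(key, label_b) / n_b if n_b else 0.0,
                }
            )
    summary = pd.DataFrame(summary_rows)
    detail = pd.DataFrame(
        detail_rows,
        columns=[
            "mouse_id",
            "clone_id",
            "size",
            f"n_{label_a}",
            f"n_{label_b}",
            f"frac_of_{label_a}",
            f"frac_of_{label_b}",
        ],
    )
    return summary, detail


@dataclass
class BootstrapResult:
    """Observed mixed-clone count against the random-partition null."""

    observed_mixed: int
    null_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    empirical_p: float
    n_runs: int
    seed: int
    mode: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_mixed": self.observed_mixed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "empirical_p": self.empirical_p,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "mode": self.mode,
            "degenerate": self.degenerate,
        }


def _simulate_null_counts(
    groups: Mapping[str, np.ndarray],
    sizes: Mapping[str, Sequence[int]],
    n_runs: int,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null mixed-clone counts per run, summed over groups.

    ``groups[g]`` is a boolean array marking which cells of group ``g``
    carry the axis-a label; ``sizes[g]`` the clone-size multiset
    (PRESERVE_SIZES) or just the clone count (UNIFORM_PARTITION).
    """
    total = np.zeros(n_runs, dtype=np.int64)
    for g in sorted(groups):
        is_a = np.asarray(groups[g], dtype=bool)
        n = is_a.size
        if mode == MODE_PRESERVE_SIZES:
            clone_sizes = np.asarray(sizes[g], dtype=np.int64)
            offsets = np.concatenate([[0], np.cumsum(clone_sizes)[:-1]])
            # batch permutations: argsort of random keys row-wise
            keys = rng.random((n_runs, n))
            perm = np.argsort(keys, axis=1, kind="stable")
            shuffled = is_a[perm]
            counts_a = np.add.reduceat(shuffled, offsets, axis=1)
            mixed = (counts_a > 0) & (counts_a < clone_sizes)
            total += mixed.sum(axis=1)
        elif mode == MODE_UNIFORM_PARTITION:
            k = int(sizes[g])
            for r in range(n_runs):
                while True:  # uniform surjective assignment by rejection
                    assign = rng.integers(0, k, size=n)
                    if np.unique(assign).size == k:
                        break
                counts_a = np.bincount(assign[is_a], minlength=k)
                counts = np.bincount(assign, minlength=k)
                total[r] += int(((counts_a > 0) & (counts_a < counts)).sum())
        else:
            raise ValueError(f"unknown bootstrap mode {mode!r}")
    return total


def bootstrap_mixed_clones(
    cells: Sequence[tuple[str, str]],
    observed_mixed: int,
    clone_sizes_per_group: Mapping[str, Sequence[int]] | None = None,
    n_clones_per_group: Mapping[str, int] | None = None,
    n_runs: int = 10_000,
    mode: str = MODE_PRESERVE_SIZES,
    seed: int = 0,
    axis_labels: tuple[str, str] | None = None,
) -> BootstrapResult:
    """Random-partition null for the mixed-clone count.

    ``cells`` holds one ``(group, compartment_label)`` pair per sequence;
    each run re-partitions every group's cells into the experiment's clone
    structure (PRESERVE_SIZES: a permutation over the empirical clone-size
    multiset; UNIFORM_PARTITION: a uniformly random surjection onto the
    observed number of clones) and counts clones containing both axis
    labels.  Fully reproducible from ``seed``.
    """
    if mode == MODE_PRESERVE_SIZES:
        if clone_sizes_per_group is None:
            raise ValueError("PRESERVE_SIZES requires clone_sizes_per_group")
        sizes: Mapping = clone_sizes_per_group
    else:
        if n_clones_per_group is None:
            if clone_sizes_per_group is None:
                raise ValueError("UNIFORM_PARTITION requires n_clones_per_group")
            n_clones_per_group = {
                g: len(s) for g, s in clone_sizes_per_group.items()
            }
        sizes = n_clones_per_group

    labels = sorted({lab for _, lab in cells}) if axis_labels is None else list(axis_labels)
    if len(labels) != 2:
        raise ValueError(f"exactly two axis labels required, got {labels}")
    groups: dict[str, np.ndarray] = {}
    for g in sorted({grp for grp, _ in cells}):
        glabels = [lab for grp, lab in cells if grp == g]
        groups[g] = np.array([lab == labels[0] for lab in glabels])
        if mode == MODE_PRESERVE_SIZES:
            group_sizes = sizes[g]
            if len(group_sizes) > len(glabels):
                raise ValueError(f"group {g!r}: more clones than cells")
            if sum(group_sizes) != len(glabels):
                raise ValueError(
                    f"group {g!r}: clone sizes sum to {sum(group_sizes)}, "
                    f"but {len(glabels)} cells supplied"
                )
        else:
            if not 1 <= int(sizes[g]) <= len(glabels):
                raise ValueError(f"group {g!r}: clone count must be in 1..n_cells")

    rng = np.random.default_rng(seed)
    null = _simulate_null_counts(groups, sizes, n_runs, mode, rng)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_runs > 1 else 0.0
    degenerate = sd == 0.0
    if degenerate:
        z = 0.0 if observed_mixed == mean else float("inf") * np.sign(observed_mixed - mean)
        p = float("nan")
    else:
        z = (observed_mixed - mean) / sd
        p = 2.0 * float(sstats.norm.sf(abs(z)))
    lo = float((null <= observed_mixed).mean())
    hi = float((null >= observed_mixed).mean())
    empirical_p = min(1.0, 2.0 * min(lo, hi))
    return BootstrapResult(
        observed_mixed=int(observed_mixed),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p_two_sided=p,
        empirical_p=empirical_p,
        n_runs=n_runs,
        seed=seed,
        mode=mode,
        degenerate=degenerate,
    )


def exact_preserve_sizes_null(
    labels: Sequence[bool], clone_sizes: Sequence[int]
) -> tuple[float, float]:
    """Exact null mean and sd of the mixed-clone count for one group.

    Enumerates all distinct arrangements of the cell labels over the fixed
    clone-size partition (feasible for small groups; intended for <=10
    cells).  Uniformity over distinct arrangements equals uniformity over
    label permutations because every arrangement has the same multiplicity.
    """
    labels = tuple(bool(x) for x in labels)
    sizes = np.asarray(clone_sizes, dtype=int)
    if sizes.sum() != len(labels):
        raise ValueError("clone sizes must sum to the number of cells")
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    counts = []
    for arrangement in set(itertools.permutations(labels)):
        arr = np.array(arrangement)
        counts_a = np.add.reduceat(arr, offsets)
        counts.append(int(((counts_a > 0) & (counts_a < sizes)).sum()))
    counts = np.array(counts, dtype=float)
    return float(counts.mean()), float(counts.std())


def relatedness_verdict(result: BootstrapResult, alpha: float = 0.05) -> str:
    """Classify the observed mixed-clone count against the null."""
    if result.degenerate:
        return VERDICT_NULL
    if result.p_two_sided < alpha:
        return VERDICT_FEWER if result.z < 0 else VERDICT_MORE
    return VERDICT_NULL


def clone_table(clones: Sequence[Clone]) -> pd.DataFrame:
    """Flat clone table (TSV-ready)."""
    rows = []
    for c in clones:
        compartment_counts = pd.Series([p[0] for p in c.compartments]).value_counts()
        subset_counts = pd.Series([p[1] for p in c.compartments]).value_counts()
        rows.append(
            {
                "clone_id": c.clone_id,
                "mouse_id": c.mouse_id,
                "size": c.size,
                "cdr3_len": c.cdr3_len,
                "junction": c.representative_junction,
                "members": ";".join(c.member_ids),
                "compartments": ";".join(
                    f"{k}:{v}" for k, v in sorted(compartment_counts.items())
                ),
                "subsets": ";".join(f"{k}:{v}" for k, v in sorted(subset_counts.items())),
            }
        )
    return pd.DataFrame(rows)
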