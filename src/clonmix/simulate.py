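"""Synthetic germinal-centre repertoires with complete ground truth.

The generator emulates the statistical structure the analysis assumes:

* clones descend from a single germline V rearrangement; each clone grows a
  random branching genealogy (Yule-type: repeatedly pick a uniform existing
  node and add a child) optionally preceded by a trunk of unsampled
  intermediates, mimicking the early maturation phase before sampling;
* somatic hypermutation places Poisson-distributed substitutions on each
  genealogy edge at positions drawn from a hotspot-weighted profile; the
  per-branch rate is calibrated per mouse group so the expected
  per-sequence V-region load matches ``target_mut_mean`` (mutation-count
  dispersion is Poisson — group means are what the study regimes fix);
* affinity selection is modelled explicitly: a chosen fraction of
  NP-binding sequences carries the W33->L CDR1 mutation (nt 98 G->T) as a
  cell-private event, the counter-selected position 102 mutates at
  different rates in NP vs non-NP sequences and — under ``np_select`` —
  only in cells that already carry the position-98 mutation;
* junctions are built from templates that satisfy or violate the
  CDR3-composition NP rule exactly, so classifier recovery can be asserted
  at 100%; junction noise is confined to codons that cannot affect the rule;
* compartment mixing operates at clone level: with probability
  ``mixing_param`` a (multi-member) clone spans both cell subsets of the
  configured axis, and its members split between them.

Everything is reproducible bit-for-bit from the config seed, and the
emitted truth table reconstructs every sequence exactly by replaying its
recorded events on the germline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    GermlineReference,
    SequenceRecord,
    default_germline,
    write_fasta_manifest,
)

J_TAIL = "TGGGGCCAAGGGACCACGGTCACC"  # W G Q G T T V T

# junction amino-acid alphabet: no C (would mimic the FR3 anchor), no W
# (would mimic the J motif), no stops
JUNCTION_AA = "ADEFGHIKLMNPQRSTVY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "Y": ["TAT", "TAC"],
}

SELECTION_MODES = ("none", "np_select", "counter_select_102")

SUBSET_COMPARTMENTS = {
    "MEMORY": (("PP", 0.6), ("MLN", 0.2), ("SPL", 0.2)),
    "LONGLIVED_PC": (("SI_LP", 0.6), ("BM", 0.4)),
    "RESPONDING_MEM": (("PP", 0.7), ("MLN", 0.3)),
    "BOOST_PC": (("SI_LP", 0.5), ("BM", 0.3), ("SPL", 0.2)),
    "OTHER": (("SPL", 1.0),),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_mice: int = 3
    clones_per_group: int = 20
    # ("geometric", p) with mean 1/p; ("fixed", k); ("zipf", s, cap)
    clone_size_dist: tuple = ("geometric", 0.4)
    target_mut_mean: float = 5.0
    mutation_rate_per_branch: float | None = None  # overrides calibration
    hotspot_weights: dict[int, float] | None = None
    selection_mode: str = "none"
    high_affinity_fraction: float = 0.0  # of NP sequences forced to carry W33->L
    yg_fraction: float = 0.0  # of W33L carriers also given a junction Y->G
    pos102_fraction_np: float = 0.275
    pos102_fraction_non_np: float = 0.42
    mixing_param: float = 0.0
    np_fraction: float = 1.0
    subset_a: str = "MEMORY"
    subset_b: str = "LONGLIVED_PC"
    trunk_edges: int = 0
    junction_mut_prob: float = 0.0  # per-sequence chance of one safe junction substitution
    junction_separation: tuple[float, float] | None = None  # (intra_min, inter_max)
    isotype_probs: tuple = (("IgA", 0.8), ("IgM", 0.1), ("IgG1", 0.1))
    sequencing_error_rate: float = 0.0  # uniform per-nt V-region substitution errors

    def __post_init__(self) -> None:
        for name in (
            "high_affinity_fraction", "yg_fraction", "pos102_fraction_np",
            "pos102_fraction_non_np", "mixing_param", "np_fraction",
            "junction_mut_prob", "sequencing_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(f"selection_mode must be one of {SELECTION_MODES}")
        if self.clone_size_dist[0] not in ("geometric", "fixed", "zipf"):
            raise ValueError(f"unknown clone size distribution {self.clone_size_dist}")
        if self.selection_mode == "np_select" and (
            self.pos102_fraction_np > self.high_affinity_fraction
        ):
            raise ValueError(
                "np_select orders position 102 after 98: pos102_fraction_np "
                "cannot exceed high_affinity_fraction"
            )


def paper_scale_preset(regime: str, seed: int = 0) -> SimulationConfig:
    """Study-condition presets at low-throughput (Sanger-arm) scale.

    ``long``: resting repertoires one year after priming — mean V load 5,
    ~50% of sequences with the high-affinity CDR1 mutation, weak
    memory/plasma-cell mixing.  ``boost``: repertoires after an oral
    booster — mean load 10, ~75% high-affinity, strong mixing and an
    extended pre-sampling trunk phase.
    """
    common = dict(
        seed=seed,
        n_mice=3,
        clones_per_group=20,
        clone_size_dist=("geometric", 0.4),
        selection_mode="np_select",
        np_fraction=1.0,
        junction_mut_prob=0.1,
    )
    if regime == "long":
        return SimulationConfig(
            target_mut_mean=5.0,
            high_affinity_fraction=0.5,
            yg_fraction=0.1,
            mixing_param=0.1,
            subset_a="MEMORY",
            subset_b="LONGLIVED_PC",
            trunk_edges=1,
            **common,
        )
    if regime == "boost":
        return SimulationConfig(
            target_mut_mean=10.0,
            high_affinity_fraction=0.75,
            yg_fraction=0.2,
            mixing_param=0.7,
            subset_a="RESPONDING_MEM",
            subset_b="BOOST_PC",
            trunk_edges=3,
            **common,
        )
    raise ValueError(f"unknown regime {regime!r}; use 'long' or 'boost'")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated repertoire."""

    config: dict
    germline_name: str
    # per sequence: clone_id, mouse_id, subset, compartment, isotype,
    # np_label, depth, net_mutations [(pos, from, to)], v_events
    # [(branch, pos, from, to)], junction_nt, junction_events, has_w33l,
    # has_pos102, has_cdr3_yg
    sequences: dict = field(default_factory=dict)
    # per clone: mouse_id, members, np_label, mixed, junction_nt,
    # parent_map, node_depths
    clones: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)

    def replay(self, seq_id: str, ref: GermlineReference) -> str:
        """Rebuild one emitted read from its recorded events."""
        info = self.sequences[seq_id]
        v = list(ref.nt_seq)
        for pos, frm, to in info["net_mutations"]:
            assert v[pos - 1] == frm
            v[pos - 1] = to
        junction = list(self.clones[info["clone_id"]]["junction_nt"])
        for idx, frm, to in info["junction_events"]:
            assert junction[idx] == frm
            junction[idx] = to
        return "".join(v) + "".join(junction) + J_TAIL

    def clone_partition(self) -> dict[str, str]:
        """seq_id -> true clone id (for grouping-recovery checks)."""
        return {sid: info["clone_id"] for sid, info in self.sequences.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "germline_name": self.germline_name,
                    "sequences": self.sequences,
                    "clones": self.clones,
                    "realized": self.realized,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls(config=raw["config"], germline_name=raw["germline_name"])
        truth.sequences = {
            sid: {
                **info,
                "net_mutations": [tuple(m) for m in info["net_mutations"]],
                "v_events": [tuple(e) for e in info["v_events"]],
                "junction_events": [tuple(e) for e in info["junction_events"]],
            }
            for sid, info in raw["sequences"].items()
        }
        truth.clones = raw["clones"]
        truth.realized = raw["realized"]
        return truth


def default_hotspot_weights(
    ref: GermlineReference, hotspot_every: int = 19, hotspot_weight: float = 6.0
) -> np.ndarray:
    """Per-position mutability multipliers over the V region (index 1..L).

    A flat baseline with regularly spaced strong hotspots stands in for the
    clustered SHM-motif mutability of real V genes.  Structurally conserved
    codons are excluded from the general pool: codon 1, codons 33-34
    (positions 97-102 carry their own explicit selection model) and the
    final three codons (the FR3 anchor the junction extraction depends on).
    """
    n = len(ref.nt_seq)
    w = np.ones(n + 1)
    w[0] = 0.0
    w[1:4] = 0.0
    w[97:103] = 0.0
    w[n - 8 :] = 0.0
    for pos in range(5, n - 8, hotspot_every):
        if w[pos] > 0:
            w[pos] = hotspot_weight
    return w


def _draw_clone_size(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    kind = cfg.clone_size_dist[0]
    if kind == "fixed":
        return int(cfg.clone_size_dist[1])
    if kind == "geometric":
        return int(rng.geometric(cfg.clone_size_dist[1]))
    s, cap = cfg.clone_size_dist[1], cfg.clone_size_dist[2]
    sizes = np.arange(1, cap + 1)
    p = sizes**-float(s)
    return int(rng.choice(sizes, p=p / p.sum()))


def _weighted_choice(rng: np.random.Generator, pairs: Sequence[tuple[str, float]]) -> str:
    labels = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _aa_to_nt(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa)


def _np_junction_aa(cfg, rng: np.random.Generator, need_late_y: bool) -> str:
    """A CDR3 satisfying the NP rule: length 9-11, Y anchor, >=2 Y window."""
    length = int(rng.integers(9, 12))
    aa = [JUNCTION_AA[i] for i in rng.integers(0, len(JUNCTION_AA), size=length)]
    aa[2] = "Y"
    window = [3, 4, 5]
    y_slots = rng.choice(window, size=2, replace=False)
    for i in window:
        aa[i] = "Y" if i in y_slots else rng.choice([a for a in JUNCTION_AA if a != "Y"])
    if need_late_y:
        aa[int(rng.integers(6, length))] = "Y"
    return "".join(aa)


def _non_np_junction_aa(rng: np.random.Generator) -> str:
    """A CDR3 violating the NP rule exactly (bad length or bad anchor/window)."""
    if rng.random() < 0.4:
        length = int(rng.choice([7, 8, 12, 13]))
        aa = [JUNCTION_AA[i] for i in rng.integers(0, len(JUNCTION_AA), size=length)]
    else:
        length = int(rng.integers(9, 12))
        aa = [JUNCTION_AA[i] for i in rng.integers(0, len(JUNCTION_AA), size=length)]
        aa[2] = rng.choice([a for a in JUNCTION_AA if a != "Y"])
        window_y = rng.choice([3, 4, 5])  # at most one Y in the window
        for i in (3, 4, 5):
            aa[i] = "Y" if i == window_y else rng.choice(
                [a for a in JUNCTION_AA if a != "Y"]
            )
    return "".join(aa)


def _nt_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def simulate_repertoire(
    cfg: SimulationConfig,
    ref: GermlineReference | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Generate a repertoire plus ground truth; optionally write files.

    Writes ``sequences.fasta``, ``manifest.tsv`` and ``truth.json`` under
    ``outdir`` when given.  Identical configs (including seed) produce
    bit-identical output.
    """
    ref = ref or default_germline()
    rng = np.random.default_rng(cfg.seed)
    n_v = len(ref.nt_seq)
    weights = (
        np.asarray(
            [cfg.hotspot_weights.get(i, 0.0) for i in range(n_v + 1)], dtype=float
        )
        if cfg.hotspot_weights is not None
        else default_hotspot_weights(ref)
    )
    pool = np.where(weights > 0)[0]
    pool_p = weights[pool] / weights[pool].sum()

    truth = SimulationTruth(
        config={**asdict(cfg), "clone_size_dist": list(cfg.clone_size_dist)},
        germline_name=ref.name,
    )
    records: list[SequenceRecord] = []

    # ---- clone skeletons per mouse ----------------------------------------
    mice = [f"m{i + 1}" for i in range(cfg.n_mice)]
    skeletons = []  # (mouse, clone_id, parent_map, depths, members, np_label, junction)
    junctions_by_len: dict[int, list[str]] = {}
    for mouse in mice:
        for ci in range(1, cfg.clones_per_group + 1):
            clone_id = f"{mouse}_tc{ci:03d}"
            size = _draw_clone_size(cfg, rng)
            np_label = bool(rng.random() < cfg.np_fraction)

            for _attempt in range(200):
                aa = (
                    _np_junction_aa(cfg, rng, need_late_y=cfg.yg_fraction > 0)
                    if np_label
                    else _non_np_junction_aa(rng)
                )
                junction = _aa_to_nt(aa, rng)
                if cfg.junction_separation is None:
                    break
                peers = junctions_by_len.get(len(junction), [])
                if all(
                    _nt_identity(junction, p) <= cfg.junction_separation[1]
                    for p in peers
                ):
                    break
            else:
                raise RuntimeError(
                    "could not draw a junction satisfying the separation constraint"
                )
            junctions_by_len.setdefault(len(junction), []).append(junction)

            # genealogy topology: trunk chain, then Yule attachment
            parent_map: dict[str, str] = {}
            depths: dict[str, int] = {"germline": 0}
            prev = "germline"
            for t in range(1, cfg.trunk_edges + 1):
                node = f"t{t}"
                parent_map[node] = prev
                depths[node] = depths[prev] + 1
                prev = node
            attach = [prev]
            members = []
            for ni in range(1, size + 1):
                node = f"{clone_id}_{ni:02d}"
                par = attach[int(rng.integers(len(attach)))]
                parent_map[node] = par
                depths[node] = depths[par] + 1
                attach.append(node)
                members.append(node)
            skeletons.append(
                (mouse, clone_id, parent_map, depths, members, np_label, junction)
            )

    # ---- forced selection events (per mouse group) ------------------------
    w33l_carriers: set[str] = set()
    pos102_carriers: set[str] = set()
    yg_carriers: set[str] = set()
    for mouse in mice:
        mine = [s for s in skeletons if s[0] == mouse]
        np_seqs = sorted(m for s in mine if s[5] for m in s[4])
        non_np_seqs = sorted(m for s in mine if not s[5] for m in s[4])
        if cfg.selection_mode == "np_select":
            n_ha = round(cfg.high_affinity_fraction * len(np_seqs))
            carriers = list(
                rng.choice(np_seqs, size=n_ha, replace=False) if n_ha else []
            )
            w33l_carriers.update(carriers)
            n_102 = round(cfg.pos102_fraction_np * len(np_seqs))
            # position 102 mutates only in cells already carrying 98
            pos102_carriers.update(
                rng.choice(sorted(carriers), size=min(n_102, len(carriers)), replace=False)
                if n_102 and carriers
                else []
            )
            n_yg = round(cfg.yg_fraction * len(carriers))
            yg_carriers.update(
                rng.choice(sorted(carriers), size=n_yg, replace=False) if n_yg else []
            )
        elif cfg.selection_mode == "counter_select_102":
            n_np102 = round(cfg.pos102_fraction_np * len(np_seqs))
            pos102_carriers.update(
                rng.choice(np_seqs, size=n_np102, replace=False) if n_np102 else []
            )
        if cfg.selection_mode in ("np_select", "counter_select_102"):
            n_non = round(cfg.pos102_fraction_non_np * len(non_np_seqs))
            pos102_carriers.update(
                rng.choice(non_np_seqs, size=n_non, replace=False) if n_non else []
            )

    # ---- per-branch mutation rate calibrated per mouse group --------------
    rates: dict[str, float] = {}
    for mouse in mice:
        mine = [s for s in skeletons if s[0] == mouse]
        all_members = [m for s in mine for m in s[4]]
        depths_flat = [s[3][m] for s in mine for m in s[4]]
        forced = [
            (m in w33l_carriers) + (m in pos102_carriers) for m in all_members
        ]
        if cfg.mutation_rate_per_branch is not None:
            rates[mouse] = cfg.mutation_rate_per_branch
        else:
            mean_depth = float(np.mean(depths_flat)) if depths_flat else 1.0
            rates[mouse] = max(
                0.0, (cfg.target_mut_mean - float(np.mean(forced))) / max(mean_depth, 1e-9)
            )

    # ---- mutate along genealogies and emit --------------------------------
    germ = ref.nt_seq
    bases = "ACGT"
    for mouse, clone_id, parent_map, depths, members, np_label, junction in skeletons:
        rate = rates[mouse]
        genotype: dict[str, dict[int, str]] = {"germline": {}}
        events: dict[str, list[tuple[int, int, str, str]]] = {"germline": []}
        edge_events: dict[str, list[tuple[int, str, str]]] = {}
        topo = sorted(parent_map, key=lambda n: depths[n])
        for node in topo:
            par = parent_map[node]
            state = dict(genotype[par])
            ev = list(events[par])
            edge_ev: list[tuple[int, str, str]] = []
            k = int(rng.poisson(rate))
            if k:
                chosen = rng.choice(pool, size=min(k, pool.size), replace=False, p=pool_p)
                for pos in sorted(int(p) for p in chosen):
                    current = state.get(pos, germ[pos - 1])
                    to = bases[int(rng.integers(4))]
                    while to == current:
                        to = bases[int(rng.integers(4))]
                    ev.append((depths[node], pos, current, to))
                    edge_ev.append((pos, current, to))
                    state[pos] = to
            genotype[node] = state
            events[node] = ev
            edge_events[node] = edge_ev

        # clone-level compartment mixing
        if len(members) >= 2 and rng.random() < cfg.mixing_param:
            while True:
                assign = rng.integers(0, 2, size=len(members))
                if 0 < assign.sum() < len(members):
                    break
            subsets = [cfg.subset_b if a else cfg.subset_a for a in assign]
            mixed = True
        else:
            label = cfg.subset_a if rng.random() < 0.5 else cfg.subset_b
            subsets = [label] * len(members)
            mixed = False

        truth.clones[clone_id] = {
            "mouse_id": mouse,
            "members": list(members),
            "np_label": np_label,
            "mixed": mixed,
            "junction_nt": junction,
            "parent_map": dict(parent_map),
            "node_depths": {n: depths[n] for n in parent_map},
            # one entry per genealogy edge: the independent SHM draws
            "edge_events": {n: list(edge_events[n]) for n in parent_map},
        }

        for node, subset in zip(members, subsets):
            state = dict(genotype[node])
            ev = list(events[node])
            private_branch = depths[node] + 1
            if node in w33l_carriers:
                cur = state.get(98, germ[97])
                ev.append((private_branch, 98, cur, "T"))
                state[98] = "T"
            if node in pos102_carriers:
                cur = state.get(102, germ[101])
                to = "A" if cur != "A" else "C"
                ev.append((private_branch, 102, cur, to))
                state[102] = to
            if cfg.sequencing_error_rate > 0:
                n_err = int(rng.binomial(n_v, cfg.sequencing_error_rate))
                for pos in rng.choice(n_v, size=n_err, replace=False) + 1:
                    pos = int(pos)
                    cur = state.get(pos, germ[pos - 1])
                    to = bases[int(rng.integers(4))]
                    while to == cur:
                        to = bases[int(rng.integers(4))]
                    ev.append((private_branch, pos, cur, to))
                    state[pos] = to

            junction_events: list[tuple[int, str, str]] = []
            jnt = list(junction)
            aa_len = len(junction) // 3
            if node in yg_carriers:
                aa = ["".join(jnt[i : i + 3]) for i in range(0, len(jnt), 3)]
                late_ys = [
                    i for i in range(6, aa_len) if aa[i] in _CODONS["Y"]
                ]
                if late_ys:
                    ci = late_ys[int(rng.integers(len(late_ys)))]
                    new_codon = _CODONS["G"][int(rng.integers(4))]
                    for off in range(3):
                        if jnt[3 * ci + off] != new_codon[off]:
                            junction_events.append(
                                (3 * ci + off, jnt[3 * ci + off], new_codon[off])
                            )
                            jnt[3 * ci + off] = new_codon[off]
            if cfg.junction_mut_prob > 0 and rng.random() < cfg.junction_mut_prob:
                # safe noise: synonymous-ish third-base change in a late codon
                safe_codons = [i for i in range(6, aa_len)]
                if safe_codons:
                    ci = safe_codons[int(rng.integers(len(safe_codons)))]
                    aa_here = "".join(junction[3 * ci : 3 * ci + 3])
                    aa_letter = next(
                        (a for a, cods in _CODONS.items() if aa_here in cods), None
                    )
                    if aa_letter and len(_CODONS[aa_letter]) > 1:
                        current_codon = "".join(jnt[3 * ci : 3 * ci + 3])
                        # single-nt synonymous changes only: keeps intra-clone
                        # junction identity >= 1 - 1/len(junction)
                        options = [
                            c
                            for c in _CODONS[aa_letter]
                            if sum(x != y for x, y in zip(c, current_codon)) == 1
                        ]
                        if options:
                            new_codon = options[int(rng.integers(len(options)))]
                            for off in range(3):
                                if jnt[3 * ci + off] != new_codon[off]:
                                    junction_events.append(
                                        (3 * ci + off, jnt[3 * ci + off], new_codon[off])
                                    )
                                    jnt[3 * ci + off] = new_codon[off]

            net = sorted(
                (pos, germ[pos - 1], b) for pos, b in state.items() if b != germ[pos - 1]
            )
            v_seq = list(germ)
            for pos, _, b in net:
                v_seq[pos - 1] = b
            full = "".join(v_seq) + "".join(jnt) + J_TAIL

            compartment = _weighted_choice(rng, SUBSET_COMPARTMENTS[subset])
            isotype = _weighted_choice(rng, cfg.isotype_probs)
            records.append(
                SequenceRecord(
                    seq_id=node,
                    nt_seq=full,
                    mouse_id=mouse,
                    compartment=compartment,
                    subset=subset,
                    isotype=isotype,
                )
            )
            truth.sequences[node] = {
                "clone_id": clone_id,
                "mouse_id": mouse,
                "subset": subset,
                "compartment": compartment,
                "isotype": isotype,
                "np_label": np_label,
                "depth": depths[node],
                "net_mutations": net,
                "v_events": ev,
                "junction_events": junction_events,
                "has_w33l": node in w33l_carriers,
                "has_pos102": node in pos102_carriers,
                "has_cdr3_yg": node in yg_carriers and bool(junction_events),
            }

    # ---- realized summaries ------------------------------------------------
    loads = np.array(
        [len(info["net_mutations"]) for info in truth.sequences.values()], dtype=float
    )
    np_loads = np.array(
        [
            len(info["net_mutations"])
            for info in truth.sequences.values()
            if info["np_label"]
        ],
        dtype=float,
    )
    n_np = max(1, sum(1 for i in truth.sequences.values() if i["np_label"]))
    truth.realized = {
        "n_sequences": len(truth.sequences),
        "n_clones": len(truth.clones),
        "mut_mean": float(loads.mean()) if loads.size else 0.0,
        "mut_mean_np": float(np_loads.mean()) if np_loads.size else 0.0,
        "frac_w33l_np": sum(
            1 for i in truth.sequences.values() if i["np_label"] and i["has_w33l"]
        )
        / n_np,
        "frac_high_affinity_np": sum(
            1
            for i in truth.sequences.values()
            if i["np_label"] and (i["has_w33l"] or i["has_cdr3_yg"])
        )
        / n_np,
        "n_mixed_clones": sum(1 for c in truth.clones.values() if c["mixed"]),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta_manifest(
            records, outdir / "sequences.fasta", outdir / "manifest.tsv"
        )
        truth.to_json(outdir / "truth.json")
    return records, truth
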