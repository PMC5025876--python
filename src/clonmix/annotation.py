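"""Germline-anchored annotation of heavy-chain reads.

Each read is globally aligned (free end gaps) to the single germline V
reference, somatic substitutions are called in germline coordinates, the
CDR3 junction is extracted between the conserved FR3 cysteine and the
J-region tryptophan motif, and NP-hapten binding is classified from CDR3
composition alone.

The affinity-relevant calls follow the canonical VH186.2 conventions:

* ``has_w33l`` — a substitution at nucleotide 98 converting codon 33
  TGG (W) to a leucine codon, the classic affinity-enhancing CDR1 mutation;
* ``has_pos102`` — any substitution at nucleotide 102, the counter-selected
  neighbour position;
* ``has_cdr3_yg`` — a Y->G replacement in the CDR3 relative to the clone's
  inferred unmutated junction (requires clonal grouping, see
  :func:`flag_clonal_cdr3_changes`).

Mutation counts (``n_mutations``) cover V-region substitutions only
(FR1..FR3): the junction is templated by the rearrangement, not the
germline V, so CDR3 differences are never counted as V mutations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from scipy import stats as sstats

from .io import GermlineReference, SequenceRecord, to_zero_based

# status codes for reads excluded from downstream stages
STATUS_OK = "ok"
STATUS_TOO_SHORT = "too_short"
STATUS_LOW_IDENTITY = "non_vh"


@dataclass
class AlignConfig:
    """Alignment scoring and acceptance thresholds.

    Defaults accept heavily mutated reads (~10 substitutions is only 3-4%
    divergence over a ~300 nt V region) while rejecting non-target
    amplicons well below the identity floor.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_identity: float = 0.70
    min_coverage: float = 0.80


@dataclass
class NPClassifierConfig:
    """CDR3-composition rule for NP binding.

    A sequence is NP-binding iff the CDR3 is 9-11 amino acids long, the
    residue at the configurable anchor offset (default: the third CDR3
    residue, the package's reading of antibody-numbering "position 99")
    is tyrosine, and at least two of the three following residues are
    tyrosines.
    """

    anchor_offset: int = 2  # 0-based index into the CDR3 string
    min_len: int = 9
    max_len: int = 11
    window: int = 3
    min_window_y: int = 2


@dataclass
class CDR3Config:
    """Anchor motifs delimiting the junction (both exclusive)."""

    cys_pattern: str = "YYC$"  # FR3 must end with this, read-side
    j_pattern: str = "WG"  # first J-region tryptophan motif


@dataclass(frozen=True)
class Mutation:
    """One somatic substitution in germline V coordinates (1-based)."""

    pos_nt: int
    from_base: str
    to_base: str
    region: str
    codon_index: int
    aa_from: str | None = None
    aa_to: str | None = None

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError(f"mutation at {self.pos_nt}: from == to ({self.from_base})")

    @property
    def is_silent(self) -> bool | None:
        if self.aa_from is None or self.aa_to is None:
            return None
        return self.aa_from == self.aa_to

    def __str__(self) -> str:
        return f"{self.pos_nt}:{self.from_base}>{self.to_base}"


def mutation_from_parts(
    pos: int, from_base: str, to_base: str, ref: GermlineReference | None
) -> Mutation:
    """Rebuild a Mutation from its serialized form.

    The amino-acid change is inferred assuming this is the only substitution
    in its codon; full multi-substitution context is only available at
    calling time.
    """
    if ref is None:
        return Mutation(pos, from_base, to_base, region="", codon_index=0)
    if ref.base(pos) != from_base:
        raise ValueError(
            f"mutation {pos}:{from_base}>{to_base} contradicts germline base "
            f"{ref.base(pos)!r}"
        )
    k = ref.codon_of_nt(pos)
    germ_codon = ref.codon(k)
    within = (pos - ref.reading_frame_offset - 1) % 3
    read_codon = germ_codon[:within] + to_base + germ_codon[within + 1 :]
    return Mutation(
        pos,
        from_base,
        to_base,
        region=ref.region_of(pos),
        codon_index=k,
        aa_from=str(Seq(germ_codon).translate()),
        aa_to=str(Seq(read_codon).translate()),
    )


@dataclass
class AnnotatedSequence:
    """A read plus everything the pipeline derives from it."""

    record: SequenceRecord
    status: str = STATUS_OK
    identity: float | None = None
    coverage: float | None = None
    score: float | None = None
    # germ_to_read[p] = 0-based read index aligned to germline position p
    # (1-based), or -1 where the germline position is uncovered/deleted
    germ_to_read: np.ndarray | None = None
    indel_codons: frozenset[int] = frozenset()
    n_indels: int = 0
    n_ns: int = 0
    mutations: list[Mutation] = field(default_factory=list)
    n_mutations: int | None = None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    np_binding: bool | None = None
    nonproductive: bool | None = None
    has_w33l: bool | None = None
    has_pos102: bool | None = None
    has_cdr3_yg: bool | None = None
    clone_id: str | None = None

    @property
    def seq_id(self) -> str:
        return self.record.seq_id

    @property
    def usable(self) -> bool:
        return self.status == STATUS_OK


def _make_aligner(cfg: AlignConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    # free end gaps: the junction/J tail of the read hangs off the 3' end
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # Biopython < 1.86 attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def align_to_germline(
    record: SequenceRecord, ref: GermlineReference, cfg: AlignConfig | None = None
) -> AnnotatedSequence:
    """Globally align a read to the germline V region (free end gaps).

    Reads covering less than ``min_coverage`` of the germline are rejected
    with status ``too_short``; reads below the identity floor are flagged
    ``non_vh`` (not a target-gene rearrangement) and excluded downstream.
    Rejection is a reason code on the returned object, never an exception.
    """
    cfg = cfg or AlignConfig()
    ann = AnnotatedSequence(record=record)
    n_ref = len(ref.nt_seq)
    if len(record.nt_seq) < cfg.min_coverage * n_ref:
        ann.status = STATUS_TOO_SHORT
        return ann

    aligner = _make_aligner(cfg)
    alignment = aligner.align(ref.nt_seq, record.nt_seq)[0]
    ann.score = alignment.score

    germ_to_read = np.full(n_ref + 1, -1, dtype=np.int64)
    matches = 0
    aligned_cols = 0
    blocks_t, blocks_q = alignment.aligned
    indel_codons: set[int] = set()
    n_indels = 0
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            # an internal gap on one side between consecutive blocks
            t_gap = t0 - prev_t_end
            q_gap = q0 - prev_q_end
            n_indels += abs(t_gap) + abs(q_gap)
            for p in range(prev_t_end + 1, t0 + 1):  # deleted germline nt
                indel_codons.add(ref.codon_of_nt(p))
            if q_gap:  # insertion in the read: flag the flanking codon
                indel_codons.add(ref.codon_of_nt(min(t0 + 1, n_ref)))
        idx = np.arange(t0, t1)
        germ_to_read[idx + 1] = np.arange(q0, q1)
        read_chunk = np.frombuffer(record.nt_seq[q0:q1].encode(), dtype="S1")
        ref_chunk = np.frombuffer(ref.nt_seq[t0:t1].encode(), dtype="S1")
        matches += int((read_chunk == ref_chunk).sum())
        aligned_cols += t1 - t0
        prev_t_end, prev_q_end = t1, q1

    ann.germ_to_read = germ_to_read
    ann.indel_codons = frozenset(indel_codons)
    ann.n_indels = n_indels
    ann.coverage = aligned_cols / n_ref
    ann.identity = matches / aligned_cols if aligned_cols else 0.0
    # short reads were rejected before alignment, so a coverage shortfall
    # here means the alignment could not be extended over the V region —
    # divergence, not length: flag as non-target alongside the identity floor
    if ann.identity < cfg.min_identity or ann.coverage < cfg.min_coverage:
        ann.status = STATUS_LOW_IDENTITY
    return ann


def call_mutations(ann: AnnotatedSequence, ref: GermlineReference) -> AnnotatedSequence:
    """List every V-region substitution of an aligned read.

    Positions opposite N bases are skipped (and tallied in ``n_ns``);
    codons containing indels are excluded from amino-acid inference but
    counted in the per-sequence indel tally made at alignment time.
    """
    if ann.germ_to_read is None:
        raise ValueError(f"{ann.seq_id}: alignment required before mutation calling")
    if not ann.usable:
        return ann
    read = ann.record.nt_seq
    muts: list[Mutation] = []
    n_ns = 0
    for pos in range(1, len(ref.nt_seq) + 1):
        ridx = ann.germ_to_read[pos]
        if ridx < 0:
            continue
        base = read[ridx]
        if base == "N":
            n_ns += 1
            continue
        germ = ref.base(pos)
        if base == germ:
            continue
        k = ref.codon_of_nt(pos)
        aa_from = aa_to = None
        if k not in ann.indel_codons:
            germ_codon = ref.codon(k)
            start = ref.reading_frame_offset + 3 * (k - 1) + 1
            read_codon = ""
            for p in range(start, start + 3):
                j = ann.germ_to_read[p]
                read_codon += read[j] if j >= 0 else "?"
            if "?" not in read_codon and "N" not in read_codon:
                aa_from = str(Seq(germ_codon).translate())
                aa_to = str(Seq(read_codon).translate())
        muts.append(
            Mutation(
                pos_nt=pos,
                from_base=germ,
                to_base=base,
                region=ref.region_of(pos),
                codon_index=k,
                aa_from=aa_from,
                aa_to=aa_to,
            )
        )
    ann.mutations = muts
    ann.n_mutations = len(muts)
    ann.n_ns = n_ns
    ann.has_w33l = any(
        m.pos_nt == 98 and m.aa_from == "W" and m.aa_to == "L" for m in muts
    )
    ann.has_pos102 = any(m.pos_nt == 102 for m in muts)
    return ann


def apply_mutations(ref: GermlineReference, mutations: Iterable[Mutation]) -> str:
    """Replay substitutions onto the germline (the calling involution)."""
    seq = list(ref.nt_seq)
    for m in mutations:
        if seq[to_zero_based(m.pos_nt)] != m.from_base:
            raise ValueError(f"mutation {m} does not match germline state")
        seq[to_zero_based(m.pos_nt)] = m.to_base
    return "".join(seq)


def extract_cdr3(
    ann: AnnotatedSequence, ref: GermlineReference, cfg: CDR3Config | None = None
) -> AnnotatedSequence:
    """Extract the translated junction between FR3 cysteine and J tryptophan.

    Both anchors are located by motif search (configurable patterns); the
    returned CDR3 excludes them.  Failure to find an anchor leaves the CDR3
    undefined with a reason code in ``status`` untouched fields — the read
    is then excluded from NP classification.
    """
    cfg = cfg or CDR3Config()
    if ann.germ_to_read is None or not ann.usable:
        return ann
    read = ann.record.nt_seq
    n_ref = len(ref.nt_seq)
    v_end = int(ann.germ_to_read[n_ref])
    if v_end < 0:
        ann.cdr3_aa = None
        ann.np_binding = None
        return ann  # alignment does not reach the 3' end of FR3

    # verify the read-side FR3 anchor (last three codons before the junction)
    anchor_start = ann.germ_to_read[n_ref - 8]
    if anchor_start >= 0 and v_end - anchor_start == 8:
        anchor_aa = str(Seq(read[anchor_start : v_end + 1]).translate())
    else:
        anchor_aa = ""
    if not re.search(cfg.cys_pattern, anchor_aa):
        ann.cdr3_aa = None
        ann.np_binding = None
        return ann  # conserved cysteine anchor not found

    tail = read[v_end + 1 :]
    tail = tail[: len(tail) - len(tail) % 3]
    if not tail:
        return ann  # no junction appended
    tail_aa = str(Seq(tail).translate())
    match = re.search(cfg.j_pattern, tail_aa)
    if match is None or match.start() == 0:
        return ann  # J-region tryptophan motif not found
    j = match.start()
    ann.cdr3_aa = tail_aa[:j]
    ann.cdr3_nt = tail[: 3 * j]
    ann.nonproductive = "*" in ann.cdr3_aa
    return ann


def classify_np_binding(cdr3_aa: str, cfg: NPClassifierConfig | None = None) -> bool:
    """Decide NP binding from CDR3 composition.

    Pure and total over arbitrary strings: sequences containing a stop
    codon, out-of-range lengths or a non-tyrosine anchor all classify False.
    """
    cfg = cfg or NPClassifierConfig()
    if "*" in cdr3_aa:
        return False
    if not cfg.min_len <= len(cdr3_aa) <= cfg.max_len:
        return False
    if cfg.anchor_offset >= len(cdr3_aa) or cdr3_aa[cfg.anchor_offset] != "Y":
        return False
    window = cdr3_aa[cfg.anchor_offset + 1 : cfg.anchor_offset + 1 + cfg.window]
    return window.count("Y") >= cfg.min_window_y


def annotate(
    records: Sequence[SequenceRecord],
    ref: GermlineReference,
    align_cfg: AlignConfig | None = None,
    cdr3_cfg: CDR3Config | None = None,
    np_cfg: NPClassifierConfig | None = None,
) -> list[AnnotatedSequence]:
    """Full per-read annotation: align, call mutations, extract CDR3, classify."""
    out = []
    for rec in records:
        ann = align_to_germline(rec, ref, align_cfg)
        if ann.usable:
            call_mutations(ann, ref)
            extract_cdr3(ann, ref, cdr3_cfg)
            if ann.cdr3_aa is not None:
                ann.np_binding = classify_np_binding(ann.cdr3_aa, np_cfg)
        out.append(ann)
    return out


def flag_clonal_cdr3_changes(dataset: Sequence[AnnotatedSequence], clones) -> None:
    """Flag Y->G junction replacements against each clone's majority junction.

    The inferred unmutated junction of a clone is its most common member
    junction (ties broken lexicographically); a member has ``has_cdr3_yg``
    when the majority junction carries Y where the member carries G.
    """
    by_id = {a.seq_id: a for a in dataset}
    for ann in dataset:
        if ann.has_cdr3_yg is None and ann.cdr3_aa is not None:
            ann.has_cdr3_yg = False
    for clone in clones:
        members = [by_id[m] for m in clone.member_ids if m in by_id]
        junctions = [m.cdr3_nt for m in members if m.cdr3_nt]
        if not junctions:
            continue
        counts = pd.Series(junctions).value_counts()
        top = counts[counts == counts.max()].index.min()
        ancestral_aa = str(Seq(top).translate())
        for m in members:
            if not m.cdr3_aa or len(m.cdr3_aa) != len(ancestral_aa):
                continue
            m.has_cdr3_yg = any(
                a == "Y" and b == "G" for a, b in zip(ancestral_aa, m.cdr3_aa)
            )


def _high_affinity(ann: AnnotatedSequence) -> bool:
    return bool(ann.has_w33l) or bool(ann.has_cdr3_yg)


def mutation_summary(
    dataset: Sequence[AnnotatedSequence],
    group_by: Sequence[str] = ("subset",),
    groups: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Per-group mutation-load and affinity-mutation summary.

    ``group_by`` names SequenceRecord metadata fields.  Groups listed in
    ``groups`` but absent from the data yield an n=0 row with NaN statistics
    rather than an exception.
    """
    usable = [a for a in dataset if a.usable and a.n_mutations is not None]
    keyed: dict[tuple, list[AnnotatedSequence]] = {}
    for ann in usable:
        key = tuple(getattr(ann.record, g) for g in group_by)
        keyed.setdefault(key, []).append(ann)
    all_keys = sorted(keyed)
    if groups is not None:
        all_keys = [tuple(g) if not isinstance(g, tuple) else g for g in groups]
    rows = []
    for key in all_keys:
        members = keyed.get(key, [])
        n = len(members)
        counts = np.array([m.n_mutations for m in members], dtype=float)
        rows.append(
            {
                **dict(zip(group_by, key)),
                "n": n,
                "mut_mean": counts.mean() if n else np.nan,
                "mut_median": float(np.median(counts)) if n else np.nan,
                "frac_high_affinity": np.mean([_high_affinity(m) for m in members])
                if n
                else np.nan,
                "frac_w33l": np.mean([bool(m.has_w33l) for m in members]) if n else np.nan,
                "frac_cdr3_yg": np.mean([bool(m.has_cdr3_yg) for m in members])
                if n
                else np.nan,
                "frac_pos102": np.mean([bool(m.has_pos102) for m in members])
                if n
                else np.nan,
                "frac_np_binding": np.mean([bool(m.np_binding) for m in members])
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def position_spectrum(
    dataset: Sequence[AnnotatedSequence], ref: GermlineReference
) -> pd.DataFrame:
    """Per-position mutation counts and frequencies over the V region."""
    usable = [a for a in dataset if a.usable and a.n_mutations is not None]
    counts = np.zeros(len(ref.nt_seq) + 1, dtype=int)
    for ann in usable:
        for m in ann.mutations:
            counts[m.pos_nt] += 1
    n = len(usable)
    rows = [
        {
            "position": pos,
            "region": ref.region_of(pos),
            "count": int(counts[pos]),
            "frequency": counts[pos] / n if n else np.nan,
        }
        for pos in range(1, len(ref.nt_seq) + 1)
    ]
    return pd.DataFrame(rows)


def compare_mutation_counts(
    dataset: Sequence[AnnotatedSequence], key: str, group_a, group_b
) -> dict:
    """Two-sided Mann-Whitney comparison of mutation loads between groups."""
    a = [x.n_mutations for x in dataset if x.usable and getattr(x.record, key) == group_a]
    b = [x.n_mutations for x in dataset if x.usable and getattr(x.record, key) == group_b]
    if not a or not b:
        return {"p": np.nan, "n_a": len(a), "n_b": len(b)}
    stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "p": float(p),
        "U": float(stat),
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
    }
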