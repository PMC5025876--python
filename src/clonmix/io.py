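"""Reading and writing of repertoire data.

Sequences travel as FASTA plus a tab-separated metadata manifest keyed by
``seq_id``; annotated repertoires are written as AIRR-style TSV tables.
The germline V-gene reference (sequence + region map) is bundled as a
FASTA/JSON pair and validated on load.

Coordinate convention: nucleotide positions on the germline V region are
1-based and inclusive everywhere in this package.  ``to_zero_based`` /
``to_one_based`` are the only sanctioned conversion points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

COMPARTMENTS = ("PP", "MLN", "SPL", "SI_LP", "COLON", "BM")
SUBSETS = ("MEMORY", "LONGLIVED_PC", "RESPONDING_MEM", "BOOST_PC", "OTHER")
ISOTYPES = ("IgM", "IgG1", "IgG_other", "IgA", "UNKNOWN")

REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

MANIFEST_COLUMNS = ("seq_id", "mouse_id", "compartment", "subset", "isotype")


def to_zero_based(pos: int) -> int:
    """1-based inclusive nucleotide position -> 0-based index."""
    return pos - 1


def to_one_based(idx: int) -> int:
    """0-based index -> 1-based inclusive nucleotide position."""
    return idx + 1


class RepertoireIOError(ValueError):
    """Raised for malformed sequence files, manifests or references."""


@dataclass(frozen=True)
class GermlineReference:
    """A single germline V-region reference with region annotations.

    ``region_map`` holds ``(label, start_nt, end_nt)`` triples in 1-based
    inclusive coordinates that tile the V region without gaps or overlap.
    ``reading_frame_offset`` is the number of leading nucleotides to skip so
    that codon ``k`` spans nucleotides ``offset + 3k-2 .. offset + 3k``.
    Codon 33 must encode tryptophan (TGG): this anchors the convention that
    a G->T substitution at nucleotide 98 is the affinity-enhancing W33->L
    CDR1 mutation, and that nucleotide 102 (third base of codon 34) is the
    counter-selected neighbour position.
    """

    name: str
    nt_seq: str
    region_map: tuple[tuple[str, int, int], ...]
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.nt_seq.upper()
        object.__setattr__(self, "nt_seq", seq)
        if not seq or set(seq) - set("ACGT"):
            raise RepertoireIOError(
                f"germline {self.name!r}: sequence must be non-empty A/C/G/T"
            )
        off = self.reading_frame_offset
        if off < 0 or (len(seq) - off) % 3 != 0:
            raise RepertoireIOError(
                f"germline {self.name!r}: length after frame offset {off} "
                "is not a whole number of codons"
            )
        self._check_regions()
        if self.codon(33) != "TGG":
            raise RepertoireIOError(
                f"germline {self.name!r}: codon 33 is {self.codon(33)!r}, "
                "expected TGG (tryptophan) under the declared reading frame; "
                "the W33->L coordinate convention is broken"
            )

    def _check_regions(self) -> None:
        regions = tuple((str(l), int(s), int(e)) for l, s, e in self.region_map)
        object.__setattr__(self, "region_map", regions)
        if not regions:
            raise RepertoireIOError("region_map is empty")
        expected_start = 1
        for label, start, end in regions:
            if label not in REGION_LABELS:
                raise RepertoireIOError(
                    f"unknown region label {label!r}; permitted: {REGION_LABELS}"
                )
            if start != expected_start:
                raise RepertoireIOError(
                    f"region {label} starts at {start}, expected {expected_start}: "
                    "region_map must tile the V region without gaps or overlaps"
                )
            if end < start:
                raise RepertoireIOError(f"region {label}: end {end} < start {start}")
            expected_start = end + 1
        if expected_start != len(self.nt_seq) + 1:
            raise RepertoireIOError(
                f"region_map ends at {expected_start - 1}, sequence has "
                f"{len(self.nt_seq)} nt"
            )

    # --- coordinate helpers -------------------------------------------------
    @property
    def n_codons(self) -> int:
        return (len(self.nt_seq) - self.reading_frame_offset) // 3

    def codon(self, k: int) -> str:
        """Nucleotide triplet of codon ``k`` (1-based) under the frame."""
        if not 1 <= k <= self.n_codons:
            raise IndexError(f"codon {k} outside 1..{self.n_codons}")
        start = self.reading_frame_offset + 3 * (k - 1)
        return self.nt_seq[start : start + 3]

    def codon_of_nt(self, pos: int) -> int:
        """Codon index (1-based) containing nucleotide position ``pos``."""
        if not self.reading_frame_offset < pos <= len(self.nt_seq):
            raise IndexError(f"nt position {pos} outside the framed V region")
        return (pos - self.reading_frame_offset - 1) // 3 + 1

    def region_of(self, pos: int) -> str:
        for label, start, end in self.region_map:
            if start <= pos <= end:
                return label
        raise IndexError(f"nt position {pos} outside the V region")

    def base(self, pos: int) -> str:
        return self.nt_seq[to_zero_based(pos)]

    def translate(self) -> str:
        framed = self.nt_seq[self.reading_frame_offset :]
        return str(Seq(framed).translate())


@dataclass
class SequenceRecord:
    """One heavy-chain read with its cell-level metadata."""

    seq_id: str
    nt_seq: str
    mouse_id: str
    compartment: str
    subset: str
    isotype: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        if not self.seq_id:
            raise RepertoireIOError("empty seq_id")
        if not self.nt_seq or set(self.nt_seq) - set("ACGTN"):
            raise RepertoireIOError(
                f"sequence {self.seq_id!r}: must be non-empty A/C/G/T/N"
            )
        for attr, allowed in (
            ("compartment", COMPARTMENTS),
            ("subset", SUBSETS),
            ("isotype", ISOTYPES),
        ):
            value = getattr(self, attr)
            if value not in allowed:
                raise RepertoireIOError(
                    f"sequence {self.seq_id!r}: unknown {attr} {value!r}; "
                    f"permitted values: {', '.join(allowed)}"
                )


def read_fasta(fasta_path: str | Path, manifest_path: str | Path) -> list[SequenceRecord]:
    """Pair FASTA entries with manifest rows, preserving FASTA order.

    The manifest is a tab-separated table with at least the columns
    ``seq_id, mouse_id, compartment, subset, isotype``; unknown extra columns
    are carried through untouched on each record.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise RepertoireIOError(f"manifest lacks columns: {missing_cols}")
    if manifest["seq_id"].duplicated().any():
        dup = manifest.loc[manifest["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise RepertoireIOError(f"duplicate seq_id {dup!r} in manifest")
    meta = manifest.set_index("seq_id")
    extra_cols = [c for c in manifest.columns if c not in MANIFEST_COLUMNS]

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        sid = entry.id
        if sid in seen:
            raise RepertoireIOError(f"duplicate seq_id {sid!r} in FASTA")
        seen.add(sid)
        if sid not in meta.index:
            raise RepertoireIOError(f"seq_id {sid!r} present in FASTA but absent from manifest")
        row = meta.loc[sid]
        records.append(
            SequenceRecord(
                seq_id=sid,
                nt_seq=str(entry.seq).upper(),
                mouse_id=row["mouse_id"],
                compartment=row["compartment"],
                subset=row["subset"],
                isotype=row["isotype"],
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_fasta_manifest(
    records: Iterable[SequenceRecord], fasta_path: str | Path, manifest_path: str | Path
) -> None:
    records = list(records)
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.nt_seq), 60):
                fh.write(rec.nt_seq[i : i + 60] + "\n")
    extra_cols = sorted({k for rec in records for k in rec.extra})
    rows = [
        {
            "seq_id": rec.seq_id,
            "mouse_id": rec.mouse_id,
            "compartment": rec.compartment,
            "subset": rec.subset,
            "isotype": rec.isotype,
            **{c: rec.extra.get(c, "") for c in extra_cols},
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS) + extra_cols).to_csv(
        manifest_path, sep="\t", index=False
    )


def load_germline(
    fasta_path: str | Path, regions_path: str | Path | None = None
) -> GermlineReference:
    """Load a germline reference from FASTA plus a JSON region map.

    When ``regions_path`` is omitted it is derived by replacing the FASTA
    suffix with ``.regions.json``.  All ``GermlineReference`` invariants,
    including the codon-33 = TGG anchor, are verified at load time.
    """
    fasta_path = Path(fasta_path)
    if regions_path is None:
        regions_path = fasta_path.parent / (fasta_path.stem + ".regions.json")
    entries = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(entries) != 1:
        raise RepertoireIOError(
            f"germline FASTA {fasta_path} must hold exactly one sequence"
        )
    spec = json.loads(Path(regions_path).read_text())
    return GermlineReference(
        name=spec.get("name", entries[0].id),
        nt_seq=str(entries[0].seq),
        region_map=tuple(tuple(r) for r in spec["regions"]),
        reading_frame_offset=int(spec.get("reading_frame_offset", 0)),
    )


def write_germline(ref: GermlineReference, fasta_path: str | Path) -> None:
    """Write a reference as the FASTA/JSON pair ``load_germline`` reads."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.nt_seq), 60):
            fh.write(ref.nt_seq[i : i + 60] + "\n")
    regions_path = fasta_path.parent / (fasta_path.stem + ".regions.json")
    regions_path.write_text(
        json.dumps(
            {
                "name": ref.name,
                "reading_frame_offset": ref.reading_frame_offset,
                "regions": [list(r) for r in ref.region_map],
            },
            indent=2,
        )
        + "\n"
    )


def default_germline() -> GermlineReference:
    """The bundled synthetic VH186.2-convention reference.

    This is a synthetic stand-in sequence, not a database allele: it is
    engineered to satisfy every coordinate convention the analysis relies on
    (codon 33 = TGG, nucleotide 102 = G ending codon 34, FR3 terminating in
    the conserved Y-Y-C anchor) so that positions 98/102 and the W33->L call
    carry their canonical meaning.
    """
    data = resources.files("clonmix") / "data"
    with resources.as_file(data / "vh186_synthetic.fasta") as fp, resources.as_file(
        data / "vh186_synthetic.regions.json"
    ) as rp:
        return load_germline(fp, rp)


# --- annotated-repertoire TSV ----------------------------------------------

ANNOTATION_COLUMNS = (
    "seq_id",
    "mouse_id",
    "compartment",
    "subset",
    "isotype",
    "nt_seq",
    "status",
    "n_mutations",
    "mutations",
    "n_ns",
    "n_indels",
    "cdr3_nt",
    "cdr3_aa",
    "np_binding",
    "nonproductive",
    "has_w33l",
    "has_pos102",
    "has_cdr3_yg",
    "clone_id",
)


def _bool_to_tsv(value: bool | None) -> str:
    return "" if value is None else ("T" if value else "F")


def _tsv_to_bool(text: str) -> bool | None:
    return None if text == "" else text == "T"


def write_annotations(records: Sequence, path: str | Path) -> None:
    """Write annotated sequences as an AIRR-style TSV (one row per read).

    Mutations are serialized as ``pos:from>to`` joined by semicolons;
    ``read_annotations`` inverts the table losslessly.
    """
    rows = []
    for ann in records:
        rec = ann.record
        rows.append(
            {
                "seq_id": rec.seq_id,
                "mouse_id": rec.mouse_id,
                "compartment": rec.compartment,
                "subset": rec.subset,
                "isotype": rec.isotype,
                "nt_seq": rec.nt_seq,
                "status": ann.status,
                "n_mutations": ann.n_mutations if ann.n_mutations is not None else "",
                "mutations": ";".join(
                    f"{m.pos_nt}:{m.from_base}>{m.to_base}" for m in ann.mutations
                ),
                "n_ns": ann.n_ns,
                "n_indels": ann.n_indels,
                "cdr3_nt": ann.cdr3_nt or "",
                "cdr3_aa": ann.cdr3_aa or "",
                "np_binding": _bool_to_tsv(ann.np_binding),
                "nonproductive": _bool_to_tsv(ann.nonproductive),
                "has_w33l": _bool_to_tsv(ann.has_w33l),
                "has_pos102": _bool_to_tsv(ann.has_pos102),
                "has_cdr3_yg": _bool_to_tsv(ann.has_cdr3_yg),
                "clone_id": ann.clone_id or "",
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path, ref: GermlineReference | None = None) -> list:
    """Invert :func:`write_annotations`.

    With a reference supplied, full ``Mutation`` objects (region, codon,
    amino-acid change) are rebuilt from the serialized ``pos:from>to`` form.
    """
    from .annotation import AnnotatedSequence, mutation_from_parts

    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_filter=False
    )
    out: list[AnnotatedSequence] = []
    for _, row in table.iterrows():
        rec = SequenceRecord(
            seq_id=row["seq_id"],
            nt_seq=row["nt_seq"],
            mouse_id=row["mouse_id"],
            compartment=row["compartment"],
            subset=row["subset"],
            isotype=row["isotype"],
        )
        muts = []
        if row["mutations"]:
            for token in row["mutations"].split(";"):
                pos_s, change = token.split(":")
                frm, to = change.split(">")
                muts.append(mutation_from_parts(int(pos_s), frm, to, ref))
        ann = AnnotatedSequence(record=rec, status=row["status"])
        ann.mutations = muts
        ann.n_mutations = int(row["n_mutations"]) if row["n_mutations"] != "" else None
        ann.n_ns = int(row["n_ns"])
        ann.n_indels = int(row["n_indels"])
        ann.cdr3_nt = row["cdr3_nt"] or None
        ann.cdr3_aa = row["cdr3_aa"] or None
        ann.np_binding = _tsv_to_bool(row["np_binding"])
        ann.nonproductive = _tsv_to_bool(row["nonproductive"])
        ann.has_w33l = _tsv_to_bool(row["has_w33l"])
        ann.has_pos102 = _tsv_to_bool(row["has_pos102"])
        ann.has_cdr3_yg = _tsv_to_bool(row["has_cdr3_yg"])
        ann.clone_id = row["clone_id"] or None
        out.append(ann)
    return out
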