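"""End-to-end pipeline: import -> annotate -> clones -> trees -> overlap/bootstrap.

The pipeline is a DAG of pure file transformations: every stage reads the
previous stage's artifact, writes its own, and appends a log entry with
parameters and record counts so filter attrition is auditable.  All
randomness flows from the single config seed; re-running an identical
config reproduces every artifact byte-for-byte (the timestamped
``pipeline.log`` is the one exception and carries no analysis content).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import clonality, lineage
from .io import (
    default_germline,
    load_germline,
    read_fasta,
    write_annotations,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and reason."""


@dataclass
class PipelineConfig:
    fasta: str
    manifest: str
    outdir: str
    germline_fasta: str | None = None  # None -> bundled reference
    germline_regions: str | None = None
    clustering_threshold: float = 0.90
    np_anchor_offset: int = 2
    min_identity: float = 0.70
    min_coverage: float = 0.80
    axis_key: str = "subset"
    axis_a: str = "MEMORY"
    axis_b: str = "LONGLIVED_PC"
    bootstrap_runs: int = 10_000
    bootstrap_seed: int | None = None  # mandatory: the only stochastic stage
    tree_compare_stat: str = "trunk_length"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("fasta", "manifest"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError(f"config: {name} path {p!r} not resolvable")
        if self.germline_fasta and not Path(self.germline_fasta).exists():
            raise PipelineError(
                f"config: germline_fasta {self.germline_fasta!r} not resolvable"
            )
        if self.bootstrap_seed is None:
            raise PipelineError(
                "config: bootstrap_seed is mandatory (every stochastic stage is seeded)"
            )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns artifact paths and in-memory results."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    log_lines: list[str] = []

    def log(stage: str, **info) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp}\t{stage}\t" + json.dumps(info, sort_keys=True))
        log_path.write_text("\n".join(log_lines) + "\n")

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # halt with stage name; artifacts kept
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrap

    (outdir / "effective_config.yaml").write_text(
        yaml.safe_dump(asdict(cfg), sort_keys=True)
    )

    ref = stage("germline")(
        lambda: load_germline(cfg.germline_fasta, cfg.germline_regions)
        if cfg.germline_fasta
        else default_germline()
    )
    log("germline", name=ref.name, length=len(ref.nt_seq))

    records = stage("import")(lambda: read_fasta(cfg.fasta, cfg.manifest))
    log("import", n_records=len(records))

    align_cfg = ann_mod.AlignConfig(
        min_identity=cfg.min_identity, min_coverage=cfg.min_coverage
    )
    np_cfg = ann_mod.NPClassifierConfig(anchor_offset=cfg.np_anchor_offset)
    dataset = stage("annotate")(
        lambda: ann_mod.annotate(records, ref, align_cfg=align_cfg, np_cfg=np_cfg)
    )
    n_ok = sum(1 for a in dataset if a.usable)
    log("annotate", n_in=len(records), n_usable=n_ok)

    clones, unassigned = stage("clones")(
        lambda: clonality.group_clones(dataset, threshold=cfg.clustering_threshold)
    )
    ann_mod.flag_clonal_cdr3_changes(dataset, clones)
    log("clones", n_clones=len(clones), n_unassigned=len(unassigned))

    annotations_path = outdir / "annotations.tsv"
    write_annotations(dataset, annotations_path)
    clonality.clone_table(clones).to_csv(outdir / "clone_table.tsv", sep="\t", index=False)

    summary = ann_mod.mutation_summary(dataset, group_by=("subset",))
    summary.to_csv(outdir / "mutation_summary.tsv", sep="\t", index=False)
    spectrum = ann_mod.position_spectrum(dataset, ref)
    spectrum.to_csv(outdir / "position_spectrum.tsv", sep="\t", index=False)
    log("summaries", groups=len(summary))

    trees = stage("trees")(lambda: lineage.build_trees(clones, dataset, ref))
    stats = [lineage.tree_stats(t) for t in trees]
    pd.DataFrame([asdict(s) for s in stats]).to_csv(
        outdir / "tree_stats.tsv", sep="\t", index=False
    )
    with open(outdir / "trees.nwk", "w") as fh:
        for t in trees:
            fh.write(f"# {t.clone_id}\n{lineage.to_newick(t)}\n")
    log("trees", n_trees=len(trees))

    overlap_summary, overlap_detail = stage("overlap")(
        lambda: clonality.overlap_table(clones, cfg.axis_a, cfg.axis_b, key=cfg.axis_key)
    )
    overlap_summary.to_csv(outdir / "overlap_summary.tsv", sep="\t", index=False)
    overlap_detail.to_csv(outdir / "overlap_detail.tsv", sep="\t", index=False)

    def _bootstrap() -> dict:
        cells, sizes = bootstrap_inputs(
            clones, cfg.axis_a, cfg.axis_b, key=cfg.axis_key
        )
        observed = clonality.count_mixed(clones, cfg.axis_a, cfg.axis_b, key=cfg.axis_key)
        out = {}
        for mode in (clonality.MODE_PRESERVE_SIZES, clonality.MODE_UNIFORM_PARTITION):
            result = clonality.bootstrap_mixed_clones(
                cells,
                observed_mixed=observed,
                clone_sizes_per_group=sizes,
                n_runs=cfg.bootstrap_runs,
                mode=mode,
                seed=cfg.bootstrap_seed,
                axis_labels=(cfg.axis_a, cfg.axis_b),
            )
            out[mode] = {
                **result.to_dict(),
                "verdict": clonality.relatedness_verdict(result),
            }
        return out

    bootstrap_report = stage("bootstrap")(_bootstrap)
    (outdir / "bootstrap.json").write_text(json.dumps(bootstrap_report, indent=2) + "\n")
    log("bootstrap", **{m: r["verdict"] for m, r in bootstrap_report.items()})

    report = [
        f"sequences: {len(records)} ({n_ok} usable)",
        f"clones: {len(clones)} (+{len(unassigned)} unassigned sequences)",
        f"mixed clones {cfg.axis_a} vs {cfg.axis_b}: "
        f"{bootstrap_report[clonality.MODE_PRESERVE_SIZES]['observed_mixed']}",
        f"bootstrap ({clonality.MODE_PRESERVE_SIZES}): "
        f"z={bootstrap_report[clonality.MODE_PRESERVE_SIZES]['z']:.3f} "
        f"p={bootstrap_report[clonality.MODE_PRESERVE_SIZES]['p_two_sided']:.4g} "
        f"verdict={bootstrap_report[clonality.MODE_PRESERVE_SIZES]['verdict']}",
        f"bootstrap ({clonality.MODE_UNIFORM_PARTITION}): "
        f"z={bootstrap_report[clonality.MODE_UNIFORM_PARTITION]['z']:.3f} "
        f"verdict={bootstrap_report[clonality.MODE_UNIFORM_PARTITION]['verdict']}",
    ]
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    log("report", done=True)

    return {
        "outdir": str(outdir),
        "dataset": dataset,
        "clones": clones,
        "unassigned": unassigned,
        "trees": trees,
        "tree_stats": stats,
        "summary": summary,
        "overlap": overlap_summary,
        "bootstrap": bootstrap_report,
        "germline": ref,
    }


def bootstrap_inputs(
    clones, label_a: str, label_b: str, key: str = "subset"
) -> tuple[list[tuple[str, str]], dict[str, list[int]]]:
    """Cells and clone-size multisets for the bootstrap, per mouse group.

    Only cells carrying one of the two axis labels enter the null model
    (off-axis cells can never make a clone mixed); clones with no axis
    member contribute no cells.
    """
    cells: list[tuple[str, str]] = []
    sizes: dict[str, list[int]] = {}
    for clone in clones:
        idx = 0 if key == "compartment" else 1
        labels = [p[idx] for p in clone.compartments if p[idx] in (label_a, label_b)]
        if not labels:
            continue
        cells.extend((clone.mouse_id, lab) for lab in labels)
        sizes.setdefault(clone.mouse_id, []).append(len(labels))
    return cells, sizes
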