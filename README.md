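# clonmix

Clonal-relatedness analysis of antibody heavy-chain repertoires.

After oral immunization, gut IgA memory B cells and long-lived plasma cells
can be profiled by sequencing rearrangements of a single dominant V gene
(VH186.2 in the anti-NP response of C57BL/6 mice). The scientific question
is whether the two compartments descend from the same germinal-centre
clones. `clonmix` implements the complete computational path from raw
V-region reads to that answer:

* **germline-anchored mutation profiling** — each read is aligned to the
  VH186.2 germline and somatic substitutions are called in 1-based germline
  nucleotide coordinates, including the canonical affinity-enhancing CDR1
  mutation W33→L (nt 98, codon 33 TGG→TTG) and the counter-selected
  neighbour position nt 102;
* **NP-binding classification** from CDR3 composition alone: a sequence is
  NP-binding iff its CDR3 is 9–11 amino acids long, carries tyrosine at the
  anchor residue ("position 99"; by default the third CDR3 residue, a
  configurable offset), and has ≥2 further tyrosines in the following three
  residues;
* **clonal grouping** — single-linkage clustering within each mouse of
  sequences sharing CDR3 length with junction nucleotide identity ≥ 0.90
  (1.0 = strict shared-rearrangement mode);
* **lineage trees** — minimum-mutation (parsimony) trees rooted at the
  germline with inferred intermediate ancestors, Newick export, shape
  statistics (PL_min, trunk length, …) and mutation-ordering queries
  (e.g. "is nt 102 ever mutated before nt 98?");
* **the mixed-clone bootstrap** — the number of clones spanning two
  compartments/subsets is compared against a random-partition null: each of
  *n* runs (default 10,000) keeps the observed cell and clone counts per
  mouse, reassigns cells to clones at random, and counts mixed clones; the
  observed count is tested with a two-sided z-test,
  z = (observed − null mean)/null sd;
* **a synthetic germinal-centre repertoire generator** with complete ground
  truth (clone identities, genealogies, mutation events, mixing structure),
  so every stage of the pipeline is testable end-to-end without external
  data.

The bundled germline reference is a synthetic stand-in sequence engineered
to satisfy the VH186.2 coordinate conventions (codon 33 = TGG, nt 102 ends
codon 34, FR3 terminating in the conserved Y-Y-C anchor); see
`docs/methods.md`.

## Worked example

Simulate a resting-regime repertoire (three mice, ~20 clones each, mean
V-region load 5, ~50% of sequences carrying the high-affinity CDR1
mutation, weak memory/plasma-cell mixing) and run the full pipeline:

```bash
clonmix simulate --preset long --seed 7 -o demo/sim
cat > demo/config.yaml <<EOF
fasta: demo/sim/sequences.fasta
manifest: demo/sim/manifest.tsv
outdir: demo/run
bootstrap_runs: 10000
bootstrap_seed: 17
EOF
clonmix run --config demo/config.yaml
```

which prints

```
sequences: 126 (126 usable)
clones: 60 (+0 unassigned sequences)
mixed clones MEMORY vs LONGLIVED_PC: 4
bootstrap (PRESERVE_SIZES): z=-6.556 p=5.511e-11 verdict=FEWER_MIXED_THAN_NULL
bootstrap (UNIFORM_PARTITION): z=-6.926 verdict=FEWER_MIXED_THAN_NULL
```

Reading the output: 126 reads grouped into 60 clones, of which 4 contain
both memory and plasma-cell sequences. Under random assignment of the same
cells to the same clone structure, far more mixed clones would be expected
— the observed count is 6.6 standard deviations below the null, so the two
compartments are *less* clonally related than chance would produce, the
study's central observation. The run directory also holds the per-read
annotation table, clone table, per-subset mutation summary
(`mutation_summary.tsv`: mean load ≈ 5, high-affinity fraction 0.50 in this
run), the per-position mutation spectrum, per-clone Newick trees and tree
shape statistics.

The library surface mirrors the pipeline
(`clonmix.annotate`, `clonmix.group_clones`, `clonmix.build_trees`,
`clonmix.bootstrap_mixed_clones`, `clonmix.simulate_repertoire`, …); see
the module docstrings.

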