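# Methods

This note documents the models, conventions and numerical choices behind
`clonmix`, and what the synthetic-data tests do and do not demonstrate
about real repertoires.

## Coordinate conventions and the germline reference

All positions are 1-based inclusive nucleotide coordinates on the germline
V region; 0-based indices appear only inside the two conversion helpers in
`clonmix.io`. Codon *k* spans nucleotides 3k−2…3k after the declared
reading-frame offset.

Positions 98 and 102 are interpreted as nucleotide positions: codon 33
spans nt 97–99, so a G→T at nt 98 converts TGG (W) to TTG (L) — the
canonical affinity-enhancing CDR1 mutation W33→L — and nt 102 is the third
base of codon 34, the counter-selected neighbour position. This is the only
reading under which the codon-level name (W33→L) and the nucleotide-level
positions (98, 102) are mutually consistent, and the loader enforces it:
a reference whose codon 33 is not TGG is rejected.

The bundled reference (`data/vh186_synthetic.fasta`) is **synthetic**: a
294-nt, 98-codon sequence engineered to satisfy every convention the
analysis relies on (codon 33 = TGG; nt 102 = G; FR3 ending in the conserved
Y-Y-C anchor; no internal stop codons, no second tryptophan or Y-Y-C motif
that could confuse junction extraction; region map FR1 1–75, CDR1 76–105,
FR2 106–147, CDR2 148–171, FR3 172–294). It is not a database allele;
analyses of real data should supply the appropriate germline FASTA/JSON
pair, which `load_germline` validates identically.

## Alignment and mutation calling

Reads are aligned globally with free end gaps (Biopython
`PairwiseAligner`): match +1, mismatch −2, gap open −4, gap extend −1. Free
end gaps let the junction + J tail hang off the 3′ end of the germline.
Reads shorter than 80% of the V region are rejected (`too_short`); aligned
reads below 70% identity — or whose alignment cannot be extended over 80%
of the V — are flagged `non_vh` and excluded downstream. The defaults
accept heavily mutated reads (a load of 10 is only ~3.4% divergence here)
while rejecting unrelated amplicons, whose gapless identity to the
reference is ~25%.

Mutation counts cover V-region substitutions only (FR1–FR3). The CDR3 is
templated by the V(D)J rearrangement, not the germline V, so junction
differences are never counted as V mutations; CDR3 Y→G replacements are
instead detected against the clone's inferred unmutated junction (the
majority junction among members, ties broken lexicographically). Positions
opposite N bases are skipped and tallied; codons containing indels are
excluded from amino-acid inference and tallied separately. "High-affinity"
means W33→L **or** CDR3 Y→G; both are also reported separately.

An optional per-clone minimum-recurrence filter (a mutation must be seen in
≥k members) exists as a sequencing-error guard but defaults to off (k=1).

## CDR3 extraction and NP classification

The junction is the translated region between the conserved FR3 cysteine
(exclusive; the read-side FR3 must end with the configurable anchor motif,
default `YYC`) and the first J-region tryptophan motif (default `WG`,
exclusive). Reads whose alignment does not reach the FR3 end, or where an
anchor cannot be found, get an undefined CDR3 and are excluded from NP
classification rather than guessed.

NP binding is decided from CDR3 composition alone: length 9–11 amino
acids, tyrosine at the anchor residue, and ≥2 tyrosines among the three
following residues. The anchor ("position 99" in antibody numbering, which
the source convention does not pin to a scheme) is implemented as a
configurable 0-based offset into the CDR3, default 2 (the third residue,
matching the canonical B1-8 junction layout). The classifier is pure and
total: stop codons, out-of-range lengths and non-tyrosine anchors all
classify negative.

## Clonal grouping

Within each mouse, sequences sharing CDR3 amino-acid length are
single-linkage clustered with junction nucleotide identity ≥ 0.90
(default). This threshold is a reconstruction — the low-throughput arm of
such studies typically requires identical shared rearrangements, available
here as threshold 1.0 — and downstream clone-level numbers are sensitive to
it. Sequences without a defined CDR3 go to an explicit unassigned pool;
output is deterministic under input reordering (members sorted by id,
clone ids assigned by sorted representative).

## The mixed-clone bootstrap

A *mixed clone* contains members of both labels of a chosen axis (default:
subset MEMORY vs LONGLIVED_PC; compartment axes selectable). Significance
of the observed mixed-clone count uses a random-partition null: each run
keeps, per mouse, the observed number of cells and clones, reassigns cells
to clones at random, and counts mixed clones; after n runs (default
10,000) the observed count is tested with a two-sided z-test against the
null mean and sd, exactly in the normal-approximation form the procedure
is usually quoted in; the empirical two-sided tail fraction is reported
alongside for transparency.

Two partition modes are provided because the source procedure does not say
whether clone sizes are preserved: `PRESERVE_SIZES` (default) permutes cell
labels over the empirical clone-size multiset — a permutation test
conditioning on the observed size spectrum, the more conservative and
conventional choice — and `UNIFORM_PARTITION` draws a uniformly random
surjective assignment onto the observed clone count. Only cells carrying
one of the two axis labels enter the null model; off-axis cells cannot make
a clone mixed. For ≤10 cells an exact enumeration
(`exact_preserve_sizes_null`) gives the null mean and sd; the mean also has
a closed form by linearity over clones with hypergeometric tail
probabilities, used as an independent oracle in the tests. Degenerate nulls
(sd = 0) are flagged and never converted into a verdict. Everything is
reproducible bit-for-bit from the seed.

Calibration caveat: the z-test is a normal approximation to a discrete
count. At the scale used here (groups of ~50 cells in ~20 clones) the
two-sided type-I error at α = 0.05 measures 0.03–0.06; for very small
groups or clone counts the approximation coarsens and the empirical tail
fraction should be preferred.

## Lineage trees

Trees are built per clone on V-region genotypes (substitution sets), rooted
at the germline, with edge lengths equal to Hamming distances; junction
variation is not part of the tree. Small clones (≤6 distinct genotypes, ≤8
mutated positions, ≤12 candidate intermediates) are solved exactly: the
minimum-weight spanning structure over the observed genotypes plus any
subset of intersection-closure intermediates (at most t−2 of them can help,
as Steiner points need degree ≥3). Larger clones use a documented greedy
agglomeration: genotypes are attached in order of increasing load to the
parent minimizing added edge mutations, where the parent may be an existing
node or a freshly inferred shared-mutation intersection spliced into an
existing edge; ties prefer more shared mutations, then the smaller node id.
The greedy score never exceeds the star-tree bound; on small instances the
builder provably equals the exhaustive minimum (tested against an
independent enumeration oracle). No homoplasy minimisation is attempted
beyond this — parallel mutations may force inferred intermediates, a known
limitation.

Observed duplicate sequences collapse into one node with a multiplicity
that does not affect shape statistics; an observed unmutated sequence sits
on a zero-length root edge; indel-discordant members attach to the root via
a flagged edge excluded from statistics.

Shape statistics: PL_min/PL_max/PL_mean are root-to-leaf path lengths in
mutations; trunk length is the mutation count from the root to the first
node with out-degree ≥2. For unbranched trees (chains) the trunk equals the
whole path and the tree is flagged `unbranched` so analyses can exclude
chains; these definitions are reconstructions of the usual lineage-tree
statistics and are stated here precisely because the upstream convention is
not visible. Mutation-ordering queries count, over all root-to-leaf paths,
whether one position's first state change precedes another's, follows it,
or shares its edge.

## The repertoire generator

The generator produces the statistical structure the analysis assumes,
with complete ground truth (per-sequence events, genealogies, clone
identities, mixing structure; the truth replays every emitted read
byte-for-byte).

* **Genealogy**: per clone, an optional trunk of unsampled intermediates
  (the pre-sampling maturation phase) followed by Yule-type growth — add a
  child to a uniformly chosen existing node — until the clone size drawn
  from the configured law (default geometric, p = 0.4, mean 2.5) is
  reached. All genealogy nodes are emitted as sequences. This is not an
  explicit dark-zone/light-zone germinal-centre model; it is the minimal
  process producing the load and tree-shape structure the analysis probes.
* **SHM**: each edge receives Poisson-many substitutions at positions drawn
  from a hotspot-weighted profile (flat baseline with regularly spaced
  strong hotspots standing in for clustered SHM motifs). Structurally
  conserved codons (codon 1, codons 33–34, the final three codons carrying
  the FR3 anchor) are excluded from the general pool. The per-branch rate
  is calibrated per mouse group so the expected per-sequence load equals
  `target_mut_mean`; dispersion is Poisson, a stated assumption — the
  source regimes fix group means only.
* **Selection**: under `np_select`, an exact fraction of NP-binding
  sequences (`high_affinity_fraction`) receives W33→L as a cell-private
  event; position 102 mutates at different rates in NP (27.5%) vs non-NP
  (42%) sequences and, in NP sequences, only in cells already carrying the
  98 mutation — encoding the observed counter-selection and ordering. A
  fraction of W33→L carriers additionally gains a junction Y→G (so the
  high-affinity fraction stays exactly the configured value).
* **Junctions**: per clone, built from templates that satisfy or violate
  the NP rule exactly, using an amino-acid alphabet without C or W (which
  would mimic the extraction anchors); junction noise is restricted to
  single-nucleotide synonymous changes in codons beyond the rule window, so
  classifier labels and clone co-membership are never perturbed (noise
  keeps intra-clone junction identity ≥ 1 − 1/len). With
  `junction_separation` set, inter-clone identity is capped by rejection
  sampling.
* **Mixing**: with probability `mixing_param` a multi-member clone spans
  both subsets of the configured axis (members split uniformly, both sides
  guaranteed non-empty); otherwise the whole clone takes one subset.
  Compartments are drawn per subset from fixed tissue distributions.

Presets encode the two study regimes at low-throughput scale (3 mice, ~20
clones and ~50 sequences per mouse): `long` — mean load 5, high-affinity
fraction 0.50, mixing 0.1, trunk 1; `boost` — mean load 10, fraction 0.75,
mixing 0.7, trunk 3.

**What passing tests show — and do not.** Truth-recovery results (exact
mutation calls, 100% classifier recovery, ARI = 1 clone grouping) hold
under the generator's idealisations: substitution-only SHM (no indels), no
sequencing error by default (a uniform substitution-error option exists),
rule-exact junction templates, and junction separation between clones. Real
amplicon data violate all of these to some degree — notably primer-site
constraints that under-sample highly mutated reads — so these results
certify the correctness of the implementation, not the error rate of the
method on real repertoires.

## Statistical reporting choices

Group comparisons of mutation loads and tree statistics use the two-sided
Mann–Whitney test (SciPy); fully tied inputs return p = 1 by definition,
and single-observation groups carry an explicit wide-uncertainty warning.
Group mutation means from clonal data are cluster-correlated (members share
genealogy edges); where the tests check regime means they use a
clone-cluster–robust standard error and pool replicate experiments, since
the naive independent-sample SE understates the dispersion of the group
mean by ~40% at this scale.

## Problem sizes used in the automated checks

The test suite and acceptance script run at the preset (low-throughput)
scale: 1,000-sequence datasets for exact-recovery checks, 200 random small
clones for the parsimony oracle, complete enumeration of all 480
bootstrap instances with ≤8 cells, 1,000 calibration replicates at 2,000
bootstrap runs, and 100 replicates each for the mixed-clone and tree-shape
power studies at 10,000 bootstrap runs. These sizes were chosen to make the
checks statistically meaningful at interactive runtimes.

## Pipeline determinism

Every stochastic stage takes the single config seed; re-running an
identical config reproduces all analysis artifacts byte-for-byte. The
stage log (`pipeline.log`) carries wall-clock timestamps for auditability
and is the one non-reproducible file; it contains no analysis content.

## Known limitations

* Insertion/deletion SHM is not simulated; indel-bearing reads are handled
  (flagged, excluded from amino-acid inference and tree statistics) but not
  exercised at scale.
* The greedy tree builder is a heuristic above the exact-solver thresholds;
  no guarantee of global parsimony there.
* The NP rule's residue numbering and the clone-definition threshold are
  reconstructions (configurable), and clone-level results are sensitive to
  the latter.
* The bootstrap's z-test inherits normal-approximation error for very
  small groups; the empirical tail is reported alongside.
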