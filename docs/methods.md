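# Methods

This note documents the models, rules and numerical choices behind
`proloop`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Coordinate and alphabet conventions

All internal coordinates are 0-based half-open; every user-facing report is
1-based inclusive, matching the residue numbering used for reference
structures (e.g. GLIC R192). Both `-` and `.` are gap characters; readers
normalise to `-` and upcase residues. `X` (unknown residue) counts as a
residue for gap fractions but is excluded from both numerator and
denominator of conservation, so fragmentary or low-quality sequences do not
dilute column statistics.

## Motif annotation

The Pro-loop detector returns the leftmost `[FY]P.D` match on the gapless
sequence; only if no canonical match exists does it fall back to the
leftmost `[FY]P.E` acidic variant (flagged), because D is by far the more
common form. Absence of the motif is a result, not an error.

Cys-loop status is decided by searching for cysteines in two windows around
a motif hit: 4–14 residues upstream of the motif start and 3–12 residues
downstream of the motif end (both inclusive, truncated at sequence
boundaries). No published window exists for this test; the defaults bracket
the known Cys-loop geometry — in GABA_A β3 the cysteines sit ~8 residues
before and ~6 after the motif — with slack for indels, and both windows are
configurable. Both cysteines found → `cys_loop`; neither → `cys_less`;
exactly one → `single_cys`, which is reported distinctly but treated as
Cys-less wherever the rule is "lacks one or both cysteines" (e.g. the
balanced-set completion step).

Selectivity is called from the M2 −2′/−1′/0′ triplet: `.E[KR]` → cationic
type, `.A[RK]` → anionic type, anything else → undetermined, with a
separate flag for a basic 0′ residue. The −2′ residue is deliberately not
required (G and P/A dominate but vary); a gapped triplet is undetermined
with a `gapped` flag. The calls are mutually exclusive and exhaustive.

## Prime numbering

Helices are numbered from the cytoplasmic toward the extracellular side.
Anchors are located as alignment columns by mapping stated 1-based residue
numbers of a reference row (for GLIC: R192 = M1 26′, P204 = M1 14′, W217 =
M1 1′, T253 = M3 29′) through its gap structure. Primes are then assigned
**per sequence by counting that sequence's own ungapped residues** from the
residue it carries in the anchor column — not by alignment column — because
indels in the M1M2 linker (prokaryotes, 5HT3) would otherwise shift M2
numbering. M1 and M3 primes decrease along the sequence (these helices run
extracellular→cytoplasmic); M2 primes increase from 0′, extended to 25′
with labels above a configurable cut (default 20′) tagged `M2M3`, since
indels appear beyond that point in some sequences. M4 is deliberately left
unnumbered: its conservation is too low for a global scheme.

A sequence gapped at an anchor column receives no annotation for that helix
plus a per-sequence flag; secondary M1 anchors (P14′, W1′) are used as a
self-consistency check, and disagreement sets an indel flag rather than
failing. No residue ever carries two annotations; would-be collisions are
skipped and flagged. The M2 0′ anchor has no universal sequence rule (the
basic residue is only ~79% conserved), so it is always user-supplied
configuration, never guessed.

## Conservation statistics

Column conservation is the modal residue's frequency among non-gap, non-X
symbols; gap content is measured over all rows. The conserved-cluster
report lists columns with gap content strictly below 2% whose conservation
— single-residue or summed over a similarity group — is strictly above 80%.
The similarity groups are {F,Y,W}, {D,E}, {R,K}, {I,L,V,M}, {P,G}
(aromatics, acidics, basics, aliphatics, helix-breakers); "similar
residues" has no canonical definition, and these groups are configurable.
Substitutions at ≥2% frequency are listed per column. Reports round
percentages half-away-from-zero to integers; internal values are unrounded.
Modal-residue ties break deterministically (higher count, then
alphabetical).

The pre-phylogeny column filter removes columns with **strictly more than**
50% gaps; exactly-50% columns are retained. It is idempotent and commutes
with row reordering. TM-block QC reports, per declared block of columns,
the fraction of sequences containing at least one gap inside the block —
trustworthy alignments have indel-free TM helices — against a configurable
ceiling (default 10%).

## Hit validation

A candidate is accepted when it satisfies at least 2 of 3 criteria:

1. **Reverse search** — whether a reverse homology search returns known
   pLGICs. This requires external databases, so it enters as injected
   evidence (a boolean per sequence); when absent it counts as
   *unsatisfied*, never satisfied.
2. **Topology** — the predicted membrane topology is pLGIC-compatible. The
   scorer is pluggable (any per-residue score in [0,1]); the built-in
   default is a 19-residue sliding-window Kyte–Doolittle profile rescaled
   affinely per sequence so the most hydrophobic window maps to 1 and the
   most hydrophilic to 0 (a flat profile maps to all zeros). Residues
   scoring ≥ 0.2 form candidate segments, merged across sub-threshold gaps
   of ≤3 residues and kept at ≥15 residues. The layout check requires ≥3
   segments (pore-facing M2 is less hydrophobic and not consistently
   detected) all within the C-terminal 60%, plus an N-terminal segment-free
   stretch ≥100 residues (the ECD); a truncated-sequence mode relaxes the
   ECD requirement for fragments.
3. **Alignment** — the sequence aligns well with known pLGICs: global
   BLOSUM62 alignment (gap open −11, extend −1) against a reference panel,
   satisfied at identity ≥ 0.15 with ≥60% of candidate residues aligned.
   The permissive identity default reflects that pLGICs share <20%
   identity across kingdoms; both knobs are configuration.

Terminal trimming cuts a candidate to `[ecd_start, m4_end)`, with the
boundaries taken from where it begins aligning to a reference ECD and from
the end of the last predicted TM segment.

## Balanced dataset construction

Protein databases over-represent metazoan pLGICs, which biases profiles and
alignments. The balanced set is: all non-metazoan sequences ∪ a uniform
random without-replacement sample of metazoan sequences (default 200,
seeded; numpy PCG64) ∪ all metazoan sequences whose Pro loop is not fully
Cys-loop, deduplicated by id. Non-metazoans are never dropped, completion
sequences are never lost to subsampling, and output membership and order
are a deterministic function of input order and seed.

## Duplication–loss rooting

Gene trees are reconciled against a rooted binary species tree by the
classic LCA mapping: leaves map through the leaf map, internal nodes to the
LCA of their children's images. A gene node is a duplication iff its image
equals the image of ≥1 child. Losses are summed per gene edge (u → c) from
species-tree depths: `depth(M(c)) − depth(M(u)) − 1` below a speciation,
`depth(M(c)) − depth(M(u))` below a duplication. Rooting tries **every**
edge of the unrooted tree, scores `w_dup·dups + w_loss·losses` (default
weights 1/1, since the objective is the plain number of duplications and
losses; Notung-style 1.5/1.0 is available), and reports all per-edge costs
plus the complete set of minimum-cost edges — for divergent families many
edges can tie for the best score, and collapsing ties would hide real root
uncertainty. Edges are identified by leaf-set bipartitions so results are
representation-independent. Multifurcating inputs are rejected rather than
silently resolved, because any resolution policy changes the costs.

## Synthetic data generators

**Alignments.** Families are generated *pre-aligned*: blocks are columns,
and loop-length variation is realised as gap padding, so no external
aligner enters the test surface. The template is: hydrophilic ECD with the
planted motif (±flanking cysteines by group, plus an occasional acidic
`[F/Y]PxE` variant among Cys-less metazoans), pre-M1 R, M1 with W1′/P14′,
an M1M2 linker whose last two columns carry the −2′/−1′ residues, M2 with
the group-appropriate triplet (GE[K/R] / [P]A[R/K] / basic-but-neither),
Leu 9′ and the M2M3-loop proline, M3 with its 29′ anchor and aromatic-rich
24′, a variable-length polar M3M4 loop (Gaussian length, short for
microbes), and a hydrophobic M4. Default group counts follow the
cross-kingdom survey composition (561 = 218 metazoan incl. 69 Cys-less +
193 bacterial + 24 archaeal + 126 protist); prokaryotic/protist-Cys-less
rows also have a 30-column shorter ECD, which (with the loop padding)
produces the planted majority-gap columns. TM residues draw from
{L,I,V,F,M,A}; M2 receives a configurable polar fraction (default 0.35) to
exercise the weak-M2 topology path. Substitution noise is applied per
region class (anchor / conserved / variable; defaults 0/0/0) drawing from a
pool that excludes P and C so planted motif and cysteine truths stay
well-defined. At zero anchor noise the generator self-checks that the
annotators recover its truth exactly. Not emulated: real substitution
processes on a phylogeny, indel evolution, alignment error, fragmentary
sequences — so passing recovery tests demonstrates rule correctness, not
robustness to alignment artefacts.

**Gene families.** A lineage entering each species-tree edge is lost with
probability `loss_rate`, else duplicates with probability `dup_rate` (both
copies continuing from the edge's child); every event is logged with its
edge. The observed tree is the true tree with extinct lineages pruned and
unary nodes suppressed, returned unrooted along with the true root edge as
a bipartition. The logged history is one feasible reconciliation of the
observed tree, so the scan's optimal cost can never exceed the true event
cost — asserted family-wise. Families with <3 surviving leaves are
discarded and regenerated with an incremented sub-seed (attempt count
reported).

## Problem sizes and tolerances

The default test and acceptance runs use: 500–561-sequence synthetic
alignments (~530 columns); 100 random gene/species pairs of ≤7 leaves for
oracle equivalence; 200 simulated families on a 10-species tree at rates
0.2/0.1 plus 10–20 event-free families for root recovery; 200 synthetic
positives/negatives for the topology validator; 20 random pairs for the
alignment-score cross-check. These sizes make every property decidable
exactly (error counts of zero, rates of 1.0) while keeping a full run in
seconds. Pairwise-alignment cross-checks assert exact score equality; the
identity *fraction* is compared only on homologous pairs (and within 0.05),
because co-optimal alignments of unrelated sequences can legitimately
differ in identity while sharing the optimal score.

## Known limitations

- The topology criterion is a hydropathy-based scorer behind the fixed
  contract (scores in [0,1], threshold 0.2, minimum length, gap merging);
  it is not a hidden-state membrane-topology model, and its absolute
  per-residue scores are per-sequence normalised, not posterior
  probabilities.
- Reverse homology search, database retrieval, multiple-alignment
  inference, model selection and maximum-likelihood tree building are out
  of scope; the package consumes their outputs.
- The duplication–loss model ignores lateral gene transfer, which is
  discussed for this superfamily but outside the DL objective.
- The "well-aligned" vs "gap-rich" distinction inside the M3M4 region has
  no formal definition; the package exposes gap-fraction profiles but
  asserts no boundary.
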