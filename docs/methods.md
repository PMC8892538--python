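# Methods

`scaffotype3d` implements 3D comparative scaffotyping (3DCS): identifying
and naming orthologous chromosome-scale scaffolds (C-scaffolds) across
related species by combining three layers of evidence — homologous synteny
blocks from whole-genome alignment, classification of the chromosome
rearrangements that separate the species, and comparison of Hi-C
A/B-compartment eigenvectors at orthologous positions.  This note records
the models, parameter choices and numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Homologous synteny blocks

Input is pairwise alignment blocks between a target assembly and a
reference (7-column BED-pair TSV, or UCSC chain files which are decomposed
into their gap-free segments; minus-strand chain coordinates are flipped to
forward strand via `pos' = L - pos`).  All coordinates are 0-based
half-open internally; target coordinates are always forward-strand, with
the aligned orientation stored separately on the block.

Scaffolds shorter than `min_scaffold_len` (default 50 kb) are removed
before analysis; the boundary is inclusive-keep (a 50 000 bp scaffold is
retained).

Chaining is greedy colinear merging at a single `resolution` parameter
(default 300 kb): blocks sharing (reference chromosome, target scaffold,
orientation), consistent in diagonal order on both genomes, and separated
by less than one resolution unit on both genomes are merged; merged blocks
spanning less than the resolution on either genome are discarded;
surviving blocks that overlap on the reference are resolved by keeping the
longer ref-span block and trimming the other (ties to the smaller start).
Because trimming can itself create sub-resolution blocks or open mergeable
gaps, the merge/filter/trim pass is iterated to a fixed point, which makes
the operation idempotent.  This is deliberately *not* a reimplementation of
an A-Bruijn-graph synteny-block builder; at the scales involved
(megabase-sized blocks, breakpoints far apart relative to the resolution)
greedy chaining produces the same block sets, and its semantics are simple
enough to verify against an independent oracle exhaustively on small
inputs.

Known limitation: homologous-block *coverage* at a coarser resolution is
not always a subset of the coverage at a finer one for arbitrary inputs
(small blocks separated by intermediate gaps can survive coarse chaining
as a merged block while failing the fine min-span filter individually);
the subset property does hold on gap-free block sets such as the
simulator's truth blocks, and is tested there.

## Rearrangement classification

A *segment map* groups consecutive HSBs on a target scaffold that share a
reference chromosome into segments, regardless of orientation; each
segment records a majority orientation weighted by reference span.

* **Fusions / fissions** come from karyotype accounting over the segment
  map: with `N_seg` segments on `N_tgt` distinct scaffolds mapping to
  `N_ref` reference chromosomes, `n_fusions = N_seg - N_tgt` and
  `n_fissions = N_seg - N_ref`, so `N_tgt = N_ref - n_fusions + n_fissions`
  always holds.  For a dog-like 38-autosome reference reduced to a red-fox-
  like karyotype this reads 38 − 26 + 4 = 16 autosomal scaffolds.  The X
  chromosome is excluded from the accounting by default and handled
  separately.
* **Inversions** are maximal runs of HSBs whose orientation opposes their
  segment's majority.  A segment that is entirely minus-orientation is a
  whole-fragment strand assignment, not an inversion.  Event size is the
  reference span of the run; summaries report the <1 Mb size class.
* **Translocations** (internal rearrangements) are reported on two
  signatures: the same reference chromosome appearing in non-adjacent
  segments of one scaffold, or a break in the monotone reference order of
  the majority-orientation HSBs within one segment (a transposed piece).
* **Shared inversions** across species are collapsed when their reference
  intervals overlap reciprocally by ≥ 50% (transitively, via union-find).
  The 50% threshold is a declared choice; no published rule exists for it.

## Hi-C compartment eigenvectors

Per scaffold, at a fixed bin size (default 500 kb):

1. **Loading.** Sparse upper-triangle triplets (or a cooler-dialect HDF5
   container) are mirrored into a symmetric matrix.  Bins whose raw
   marginal falls below the 5th percentile of nonzero marginals are masked.
2. **Balancing.** The matrix is scaled to the Knight–Ruiz fixed point
   (equal row sums, `M' = D M D`) by symmetric Sinkhorn iteration,
   tolerance 1e-6 on the relative row-sum spread, cap 3000 iterations;
   rows that cannot be balanced are masked.  Sinkhorn converges to the
   same fixed point as the Newton-type KR scheme and its progress is
   trivial to monitor.
3. **Distance normalisation.** Each entry is divided by the mean valid
   entry at its genomic distance (observed/expected).
4. **Correlation.** Pearson correlation of the O/E rows over valid bins
   (at least 3 required); constant rows are masked.
5. **PC1.** The compartment profile is the leading eigenvector of the
   *centered* correlation matrix.  Centering is double-centering (row and
   column means removed, grand mean restored): it is the symmetric way to
   remove the constant component, so a real symmetric eigensolver applies
   and the result equals PC1 of the correlation matrix treated as data.
   The profile has unit norm over valid bins; the explained fraction is
   λ₁ / Σ|λ|.
6. **Sign.** The eigenvector sign is intrinsically arbitrary.  With an
   anchor profile (the reference species on lifted coordinates) the sign
   making the correlation with the anchor non-negative is chosen;
   otherwise the first valid bin is made non-negative.  A = positive by
   convention after anchoring.

The heat-map display cap (counts clipped to [1, 1000]) applies to plot
export only, never to computation.

## Cross-species profile comparison

Target eigenvectors are lifted through HSBs onto reference bins by bin-
midpoint mapping: a reference bin takes the value of the target bin its
midpoint maps to, provided an HSB covers at least half the bin.  Sub-bin
interpolation would be illusory precision at equal bin sizes, hence
midpoints.  Within minus-orientation HSBs the bin order is reversed but
values are *not* negated — which compartment a locus occupies does not
depend on assembly strand.

Per-segment similarity is the Pearson correlation over overlapping valid
bins (segments with fewer than 10 such bins are "not assessed").
Compartment shifts are maximal runs of at least `min_run` bins (default 2,
i.e. 1 Mb) where the two species' signs disagree; the direction is read
off the reference sign.  The run threshold is a declared choice — the
visual shift calls it automates have no published numeric criterion.

## Orthology table and naming

Each segment becomes one table fragment; fragments are listed per
reference chromosome in reference order and rendered joined by `+`
("3a+7a+8a").  A scaffold with a single segment is unlettered; with k ≥ 2
segments the letters a…(k) follow ascending target position (after `z`
come `aa`, `ab`, …), so names are a permutation-stable function of the
coordinates.  Overlapping reference claims from one species are an error,
not silently resolved: assignments are supposed to be unambiguous.
The table text format round-trips losslessly; the parser tolerates the
inconsistent whitespace of the transcribed carnivore table.

Naming recommendation rules: the reference genome must have > 90% of its
sequence anchored to chromosomes; reference nomenclature may be adopted
only when every reference chromosome is a 1:1 whole-scaffold ortholog in
every species; otherwise scaffolds are named by size rank and related
through the table.

The package ships the carnivore orthology table (11 species against the
cat reference, with diploid numbers) as a transcribed TSV fixture; its
summary statistics (18 felid 1:1 autosomes, 3 ursid 1:1 autosomes, 1–9
canid and 1–5 ursid fragments per cat chromosome) are recomputed from the
fixture, never hard-coded.

## Synthetic-data generator (karyosim)

The generator provides exact ground truth for every analysis stage.

* **Genome.** A few chromosomes, by default 60–120 bins of 500 kb
  (30–60 Mb) — modest but chromosome-like.  The planted compartment
  profile is a ±1 block signal with geometric block lengths (mean 8 bins)
  and alternating sign; a chromosome is redrawn until each state covers at
  least 20% of bins (`min_state_fraction`), because a near-single-state
  chromosome carries no recoverable checkerboard and does not resemble a
  real autosome.
* **Rearrangements.** Inversions, fusions, fissions and within-scaffold
  translocations are applied sequentially to piece lists; truth alignment
  blocks (maximal conserved segments with orientation) tile every scaffold
  exactly.  Scripted histories accept any bin-aligned coordinates.  The
  *random* history sampler additionally enforces recoverability
  preconditions: every cut is at least one spacing unit (default two bins)
  from existing breakpoints, events are planted on forward-strand pieces,
  fissions keep forward-strand material in the strict majority for every
  chromosome on both products, inversions stay shorter than half their
  piece, and fusions never place material of one ancestor chromosome twice
  on a scaffold.  Violating proposals are re-drawn.  Under these
  conditions event-count recovery by the classifier is exact (tested over
  hundreds of seeded histories); without them single events can masquerade
  as combinations (e.g. a fission through an inverted region splits one
  inversion into two).
* **Hi-C.** Counts are Poisson draws around
  `λ_ij = R · max(|i−j|,1)^(−α) · (1 + c·a_i·a_j)` with decay exponent
  α = 1 (generic polymer scaling), compartment strength c (default 0.3)
  and R the expected count between adjacent bins (default 50).  This is
  the simplest generative model whose correlation-matrix PC1 provably
  aligns with the planted profile.  All randomness flows through one
  seeded PCG64 generator; outputs are bit-reproducible.

What the simulator does **not** emulate: read-level noise and mapping
artefacts, restriction-fragment geometry, trans contacts, copy-number and
repeat-driven coverage structure, centromeres/telomeres, and the
sequence-level alignment noise of real LastZ chains (truth blocks are
exact).  Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated model, not performance on raw sequencing data.

## Numerical and degenerate-input conventions

Balancing tolerance 1e-6 (row-sum spread), 3000-iteration cap,
non-converged rows masked with a warning.  Compartment analysis requires
≥ 3 valid bins; constant correlation matrices are rejected as degenerate.
Eigenvectors are deterministic up to sign, fixed by the anchoring rule;
a zero anchor correlation falls back to the first-bin rule with a warning.
Chaining ties (equal ref spans competing for reference territory) break
toward the smaller start coordinate.  Fragment letters are derived only
from target coordinates, so table naming is invariant under input order.

## Problem sizes used in the shipped checks

The automated checks run entirely on synthetic data and the packaged
table: 200 random 10-event histories on 5-chromosome genomes for event
recovery, 20 seeds of a 100-bin chromosome at c = 0.3 and 50 reads/bin for
compartment recovery, matrices up to 50 bins for the eigensolver
cross-check, and a scripted 38-chromosome history with 26 fusions and 4
fissions for the karyotype-accounting identity.  These sizes were chosen
so the full suite completes in seconds while still exercising every code
path at chromosome-like scale.
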