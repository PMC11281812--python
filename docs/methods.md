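# Methods

## Overview

The pipeline quantifies collagen-family expression per (phase, cell type)
population in the mammary gland across the pregnancy–lactation cycle and
scores directed collagen → collagen-binding interactions between
populations. Because its claims are categorical, validation is built on a
synthetic scRNA-seq generator with planted, known structure: every stage is
tested for exact recovery of that structure, and for silence under a null
model with no planted signal.

## Synthetic data model

Counts are negative binomial, sampled as gamma–Poisson with a shared size
parameter `dispersion` (variance = μ + μ²/size). The mean of gene *g* in
cell *c* is

    μ_gc = base_mean · rel_g · fold_gc · depth_c

with the following components:

- **Per-cell depth** `depth_c ~ LogNormal(log(library_size_mean),
  library_size_sd)` (defaults 1.0, 0.35) — makes depth normalization
  non-trivial.
- **Per-gene baseline** `rel_g`: 1 for collagen and marker genes,
  `binding_fold` (12) for collagen-binding genes, and
  `LogNormal(0, background_lognorm_sigma)` (σ = 2) for background genes.
  The heavy tail concentrates the library in a few abundant genes, as in
  real cells; the median library is ≈170 counts, drop-seq-shallow.
- **Per-type programs** (`type_de_fraction` = 0.1, `type_de_sigma` = 1.0):
  each cell type multiplies a random 10% of background genes by lognormal
  factors, shared across phases. This is the standard group-DE device of
  scRNA-seq simulators; without it, cell types would differ in only their
  3 marker genes — a degenerate geometry under which no clustering method
  can attain realistic accuracy, and which real tissues do not exhibit.
- **Marker programs**: each type's 3 canonical markers (e.g. *Cd3e/Cd3d/
  Lck* for T cells) are elevated `marker_fold` (40×) in all cells of that
  type, in every phase.
- **Planted collagen programs**: an "on" (phase, type, family) block
  elevates each family gene `program_fold` (20×) in a random
  `expressing_fraction_on` (0.6) subset of the block's cells — sparse,
  dot-plot-like signal, so fraction-expressing gates are genuinely
  exercised. The planted blocks are: fibroblast I/III/IV in every phase;
  T/B/myeloid I/III in pregnancy only (the ectopic program); fibroblast V
  in pregnancy only; the lactation IV block multiplied by
  `lactation_col4_reduction` (0.6 → effective 12×); the involution
  fibroblast I/III blocks multiplied by `involution_fold_boost` (2.0 →
  effective 40×), reflecting the heavy ECM remodeling of involution and
  giving the expected ordering of total interaction mass
  (pregnancy > involution > virgin/lactation). With `program_fold = 1`
  no block exists and the ground truth is empty.

**Effect-size rule.** Default group sizes put 150–300 cells in each planted
block. Defaults were chosen so that every planted block clears both default
producer thresholds by at least ~3σ of the binomial sampling noise of its
expressing fraction, and background expression (expressing fraction
≈ 0.03 at `base_mean` 0.03) sits >5σ *below* the fraction gate. This makes
the planted truth identifiable by construction rather than marginally, and
makes spurious calls vanishingly rare, which is what the recovery and
null-control guarantees require. Family III is the binding constraint: it
has a single gene (*Col3a1*), so a producer call cannot fall back on a
second gene.

Composition is the same mixture in every phase (epithelium 32%, fibroblast
20%, T 16%, myeloid 12%, B 10%, endothelium 10%); per-phase compositions
are configurable but no per-phase census exists to emulate, so a single
realistic mixture is used. Defaults simulate 1,500 cells per phase
(6,000 total) and 1,000 genes — small enough that the full multi-seed test
battery runs in ~1.5 min on one CPU while leaving ≥150 cells in the
smallest scored population.

What the generator does **not** emulate: batch effects (hence no
integration step), doublets, ambient RNA, UMI saturation, phase-dependent
composition shifts, or spatial structure. Passing tests therefore
demonstrate the pipeline's correctness and its statistical behavior at
realistic depth and sparsity — not robustness to artifacts absent from the
simulation.

## Preprocessing

- **Normalization**: `value = log(1 + scale_factor · count / total)`,
  natural log, `scale_factor` 10,000 — the convention of the mainstream
  single-cell toolchains; the per-cell linear total equals the scale factor
  exactly, which the tests assert. Zero-total cells are excluded with a
  warning, never silently zeroed; log base and all parameters are recorded
  in run metadata. Fraction-expressing statistics are always computed on
  raw counts (count > 0), so they are invariant to this choice.
- **PCA**: exact or randomized SVD (seeded, deterministic) on cells ×
  genes; loadings orthonormal to 1e-6. For clustering, genes are
  standardized to unit variance (clipped at ±10σ) first so the
  heavy-tailed abundant genes do not dominate the components; the
  unstandardized and uncentered variants remain available.
- **Clustering**: Leiden (RB configuration partition, seeded) on the
  undirected k-nearest-neighbor graph (k = 15) of the top 20 PCs,
  resolution 1.0. Resolution, k, and PC count are conventions, not
  estimates of anything; over-clustering is harmless here because labels
  are assigned per cluster.
- **Annotation**: each cluster takes the argmax over types of the mean (over
  the cluster) of the per-cell mean normalized expression of the type's
  markers. Ties break to the lexicographically first type and are flagged
  low-confidence with margin 0. Annotation is optional: every downstream
  stage consumes only the metadata table, so curated labels (as atlas
  subsets carry) bypass clustering entirely.

## Producer calling

A (phase, type) population is a producer of family *F* iff at least one
gene of *F* has `frac_expressing ≥ min_frac` (0.1) **and**
`mean_norm_expr ≥ min_mean` (0.25), both inclusive. The thresholds are
conventions made explicit — the biological claims they operationalize are
usually made from feature/violin plots without numeric cutoffs — and both
are exposed on the CLI. Raising either threshold can only remove calls
(tested as a property). The ectopic report is the producer calls restricted
to the immune types.

## CCI scoring

`score = mean_A(g_s) · mean_B(g_t)` over log-normalized expression, for
every phase, every ordered type pair (A, B) including A = B, and every
directed pair g_s → g_t with a collagen source; a row is emitted only when
both populations pass the fraction-expressing gate (defaults 0.1/0.1) and
both fractions are nonzero. The product-of-means form is the simplest
member of the mean-expression family of interaction scores
(CellPhoneDB-style); it is deliberately isolated behind one function, named
in the output metadata, and swappable. Self-interactions are included by
default (fibroblast–fibroblast collagen signaling is real) with a CLI flag
to exclude. No permutation testing is performed: the quantity of interest
is the raw score sum per phase. Pair genes absent from the matrix are
skipped with a logged count.

Totals per phase and the chord table (per phase × source type × target
type, annotated with epithelia/immune/stroma groups) are plain sums of row
scores, so additivity holds to float precision and is asserted at 1e-9.

An exhaustive-loop oracle (`oracle_score_cci`) recomputes the identical
contract with no vectorization and no sparsity shortcuts; the vectorized
scorer must match it row-for-row within 1e-9 on randomized small instances.

## Numerical conventions

- Determinism: every stochastic stage takes a seed; one run-level seed is
  propagated to simulation, PCA and Leiden. Reruns of the pipeline with an
  identical config are byte-identical (hash-checked in tests).
- Degenerate inputs: all-zero matrices, empty interaction tables, empty
  phases and unmapped types raise or warn per contract rather than
  producing silent zeros; boundary threshold values are inclusive.
- Ties in annotation break lexicographically and are flagged.

## Limitations

- The score magnitudes are convention-dependent (log base, scale factor,
  gate); only within-run comparisons (orderings, ratios) are meaningful.
- Producer thresholds are calibrated to the simulation's depth regime;
  much deeper or shallower real data would warrant re-examining
  `min_mean`.
- The generator's phase composition is constant, so phase totals are not
  confounded by composition shifts — real data would be, and the scoring
  makes no attempt to correct for composition.
- Marker-based annotation assumes each type's markers are in the matrix
  and reasonably specific; it reports margins but no uncertainty beyond
  the tie flag.
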