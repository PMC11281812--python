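# mammocci

Collagen expression profiling and directed cell–cell interaction (CCI)
scoring in the mouse mammary gland across the pregnancy–lactation cycle
(virgin → pregnancy → lactation → involution), built as a tested, fully
reproducible pipeline over synthetic single-cell RNA-seq data with a planted
ground truth.

## The scientific problem

The mammary gland is remodeled dramatically across the pregnancy–lactation
cycle, and collagen dynamics are central to that remodeling. Single-cell
transcriptomics makes it possible to ask *which cell populations produce
which collagens in which phase*, and to quantify potential collagen
signaling between populations. The questions this pipeline answers, per
(phase, cell type):

1. **Producer calling.** Is a population a producer of collagen family
   *F* ∈ {I, III, IV, V}? A population is called a producer when at least
   one of the family's genes (e.g. type I: *Col1a1*, *Col1a2*; type III:
   *Col3a1*) passes both of a dual inclusive threshold:
   `frac_expressing ≥ 0.1` (share of cells with raw count > 0) and
   `mean_norm_expr ≥ 0.25` (mean of `log(1 + 10⁴·c/total)` values).
   Of special interest are **ectopic** producers: immune populations
   (T, B, myeloid) expressing fibrillar collagens outside the canonical
   stromal-fibroblast source.
2. **CCI scoring.** For each directed interaction pair g_s → g_t (collagen
   gene → collagen-binding gene, e.g. *Col1a1* → *Itgb1*), each phase, and
   each ordered pair of cell types (A, B):

   `score(phase, A, B, g_s, g_t) = mean_A(g_s) · mean_B(g_t)`

   where means are over log-normalized expression, emitted only when both
   populations pass a fraction-expressing gate (default 0.1/0.1). Rows
   aggregate additively into chord-diagram tables (epithelia / immune /
   stroma groups) and per-phase totals.

Because the pipeline's claims are categorical (who produces what, when;
which phase carries the most interaction mass), correctness is established
against a **synthetic generator that plants the expected biology** —
fibroblast I/III programs in all phases, ectopic immune I/III programs in
pregnancy only, fibroblast-only type V in pregnancy, reduced type IV in
lactation, boosted fibroblast I/III in involution — and every downstream
stage is tested for exact recovery of that planted truth, plus a null model
(`program_fold = 1`) in which nothing may be called.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
configuration (6,000 cells: 1,500 per phase, seven cell types, 1,000 genes,
seed 0) and print what they find:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_collagen_profile.py
python analysis/04_cci.py
python analysis/05_robustness.py
```

Output (abridged) from a run of the above:

```
simulated 1000 genes x 6000 cells (seed 0)
planted producer blocks: 19
annotation accuracy vs planted truth: 0.975
producer calls: 19 (planted: 19)
missed: []
spurious: []
ectopic (immune) producers:
    phase    cell_type family
pregnancy       B cell      I
pregnancy       B cell    III
pregnancy       T cell      I
pregnancy       T cell    III
pregnancy myeloid cell      I
pregnancy myeloid cell    III
per-phase total CCI score:
  virgin         214.62
  pregnancy      605.37
  lactation      198.70
  involution     301.21
observed ordering: pregnancy > involution > virgin > lactation
immune-source chords by phase: ['pregnancy']
```

Reading this: clustering + marker annotation recovers 97.5% of planted cell
types; all 19 planted producer blocks are called with no misses or spurious
calls; the only immune (ectopic) producers are the pregnancy-phase T/B/
myeloid populations for families I and III; and the total interaction mass
is highest in pregnancy (≈2.8× virgin), with involution second — the phase
ordering planted in the generator. `05_robustness.py` repeats the chain
over 10 seeds (10/10 exact recovery, 10/10 ordering) and over 10 null-model
seeds (0 producer calls, per-phase totals identical at the default gate).

The same stages are scriptable via the CLI (`mammocci simulate|preprocess|
profile|cci|run|io validate`) or the library API (`mammocci.simulate`,
`mammocci.preprocess`, `mammocci.collagen_profile`, `mammocci.cci`,
`mammocci.pipeline`).

## Layout

- `src/mammocci/` — library: `simulate` (planted-truth generator),
  `io_matrix` (DGE/MTX/TSV readers and writers), `preprocess`
  (normalization, PCA, Leiden, annotation), `collagen_profile`
  (summaries, producer calls, ectopic report), `cci` (scoring, oracle,
  chord tables, totals), `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, parameter choices, numerical conventions and
  limitations.
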