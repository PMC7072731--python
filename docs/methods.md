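# Methods

## Problem and model

Ubiquinone (coenzyme Q) is the lipid-soluble electron carrier of the
respiratory chain; ubiquinone-binding proteins (UBPs) are the receptors that
dock it. This package implements a sequence-based binary predictor of
UBPs versus non-UBPs, plus the downstream analyses used to characterize
predicted binders (term enrichment, binding-domain window extraction).

The predictor is a pipeline of four stages:

1. **Encoding.** A protein of length L with a PSI-BLAST profile is encoded
   as an 820-dimensional vector: 20 amino-acid composition (AAC) features
   `count(a)/L`; 400 dipeptide composition (DC) features
   `count(ab)/(L-1)`; and 400 PSSM-composition features, where component
   (t, c) is the sum of profile column-c scores over positions occupied by
   residue t. AAC and DC are probability distributions (each block sums to
   1); the PSSM block is a raw sum by default.
2. **Selection.** A random forest (500 trees by default) scores each
   feature by mean Gini-impurity decrease; zero-importance features are
   dropped; incremental feature selection (IFS) evaluates nested prefixes
   of the ranking with cross-validated classification and keeps the prefix
   maximizing cross-validated MCC (smallest prefix on ties).
3. **Classification.** An XGBoost tree-booster binary model with eight
   tunable hyperparameters (defaults / search intervals in
   `ubp_pred.classifier.PARAM_BOUNDS`): learning_rate 0.10 [0, 0.5],
   n_estimators 100 [100, 2000], max_depth 3 [1, 10], subsample 1.0 (0, 1],
   colsample_bytree 1.0 (0, 1], gamma 0 [0, 1], reg_alpha 0 [0, 1],
   reg_lambda 1.0 [0, 2]. Calls use a 0.5 probability threshold.
4. **Tuning.** Multi-objective particle swarm optimization (MOPSO) over
   that 8-dimensional box. Default objectives are (sensitivity,
   specificity) — the two complementary error rates; the archive member
   with the highest MCC is the final configuration, MCC being the most
   reliable single selection metric for balanced binary problems.
   Production defaults: swarm 80, 200 iterations.

Evaluation uses stratified 5-fold cross-validation during selection and
tuning, and an independent held-out test for the final model, reporting
Sen, Spe, Pre, ACC, F1 and MCC.

## Numerical and design choices

* **PSSM block choice.** PSI-BLAST ASCII files carry a log-odds block and
  a percent-frequency block. The reader defaults to log-odds (first 20
  columns) and records which block was read (`source_kind`) in every
  matrix, since published composition pipelines rarely state which block
  they consumed. The percent block is available via a flag and is
  recovered within 0.005 of the generating frequencies (the format stores
  integer percents).
* **PSSM column order.** Taken verbatim from the file header (PSI-BLAST
  order), then mapped to the canonical alphabetical residue order through
  `column_order` when features are computed. A profile whose row residues
  disagree with the FASTA sequence is an error, not a warning.
* **PSSM normalization.** None by default (a bare sum over positions);
  `by_length` and `by_residue_count` options exist because length
  normalization is a genuinely open choice for composition-style profile
  features.
* **Dataset hygiene.** Sequences shorter than 50 residues (peptide-length
  chains) or containing non-standard letters are rejected by an explicit
  filter step with machine-readable reasons; exactly 50 residues is kept.
  The parser itself never silently alters records.
* **Degenerate metrics.** Any single ratio with a zero denominator is 0,
  and MCC with a zero factor under the root is 0 (the convention shared by
  scikit-learn, which the tests use as an independent cross-check).
* **Repeated cross-validation.** `kfold_cv` takes a `repeats` parameter
  (default 1, i.e. 5 submodels at k=5); `repeats=2` gives the
  10-submodel variant some protocols use.
* **Ranking ties.** Stable sort on (descending importance, original column
  index) makes the ranking deterministic for a fixed seed.
* **IFS step.** 1 by default (strictly one-by-one); a `step` option exists
  for very wide matrices.
* **PSO coefficients.** Fixed constriction-style values w = 0.729,
  c1 = c2 = 1.494. Boundary handling is clip-plus-velocity-zeroing on the
  clipped component. Integer parameters (n_estimators, max_depth) move in
  continuous space and are rounded only at evaluation time. The archive
  holds at most 100 entries; over capacity, the entry with the smallest
  NSGA-II crowding distance is pruned, preserving front spread. The social
  leader is drawn uniformly at random from the archive per particle per
  iteration. A particle's personal best is replaced when dominated, or
  with probability 1/2 when the new point is incomparable.
* **Fraction floors.** subsample and colsample_bytree cannot be 0 for the
  booster, so the tuner's box floors them at 0.05 (a subset of their
  nominal [0, 1] interval; the box constraint is never violated).
* **Hypergeometric tail.** `P(overlap >= m)` computed via
  `scipy.stats.hypergeom.sf(m-1, N, M, n)` (log-space internally), with
  `m = 0` giving 1 by the empty-sum convention. Significance is called on
  the raw P-value at 0.05 by default — no multiple-testing correction —
  with Benjamini–Hochberg available as an option. Terms are treated as
  flat sets (no ontology graph).
* **Windows.** Binding-site windows are 21 residues wide by default, site
  centered, 1-based inclusive coordinates. Sites within 10 residues of a
  terminus are clipped and flagged `full_width=False` rather than padded
  or discarded, so the caller decides; fragments below `min_width`
  (default 8) are excluded from the motif-discovery FASTA.
* **Seeds.** One root seed per run, expanded into per-stage seeds through
  `numpy.random.SeedSequence`; XGBoost runs single-threaded wherever
  bit-reproducibility is asserted.
* **Model serialization.** A single JSON artifact holding the
  hyperparameters, the training feature names and the booster's own JSON
  dump; save → load → predict is bit-identical.

## What the synthetic generator emulates — and what it does not

The generators produce random 20-letter proteins (length ≥ 50, uniform
residues by default), integer log-odds-like profiles with the true
residue's column up-shifted (+4) over an iid background in [-5, 5], written
in the BLAST+ ASCII dialect, balanced labeled datasets, GMT annotation
universes with one planted enriched term, and uniform binding-site tables.

The planted class signal lives in composition space: under `aac_bias` the
positive class draws residues from `(1-e)·uniform + e·biased` over a
designated residue subset (default {A, C, D}); under `dc_bias` biased
residues are additionally duplicated into adjacent pairs; under
`pssm_bias` designated profile columns are shifted by `round(6e)`. At
effect size e = 0 the classes are exchangeable, so any systematic
cross-validated MCC away from 0 would indicate leakage; at e = 0.8 the
classes are cleanly separable, so a working pipeline must reach test MCC
near 1.

What this does **not** emulate: real amino-acid background frequencies,
sequence-length distributions, homology structure between sequences,
PSI-BLAST's pseudocount machinery, or motif-level (positional) signal.
Passing the planted-recovery tests therefore demonstrates that the
machinery is correct and leak-free — not that any particular real-data
accuracy will be achieved, which depends on the benchmark sets and
Swiss-Prot profiles a user supplies.

## Problem sizes used by the tests and the acceptance script

Desk-scale conditions, chosen once: toy projects of 200 proteins (100 per
class, lengths 50–80), effect size 0.8 for the planted project and the
matched all-null project; IFS capped at the top 20 ranked features; MOPSO
at swarm 10 × 20 iterations for end-to-end runs and swarm 20 × 50
iterations for the analytic-surrogate convergence check; a 30% stratified
held-out split (60 test proteins). The oracle sweeps use 1,000 random
sequences (composition identities), 100 random 60×20 profiles
(PSSM-composition), 1,000 random confusion tables (metric suite), and the
complete enumeration of every hypergeometric instance with N ≤ 12.

## Known limitations

* Benchmark construction (Swiss-Prot mining, CD-HIT redundancy removal at
  30% identity) and PSI-BLAST execution are outside the package; users
  supply FASTA + ASCII PSSMs (`psiblast -num_iterations 3 -evalue 0.01
  -out_ascii_pssm`).
* Motif discovery itself is external (MEME); the package only prepares its
  input windows.
* The tuner offers reproducibility at one worker; there is no asynchronous
  parallel swarm.
* No probability calibration and no ROC analysis; the six confusion-matrix
  metrics are the evaluation surface.
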