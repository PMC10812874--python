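# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `drpcurves`.  It states no empirical results;
numbers come from running the test suite and `scripts/acceptance.py`.

## Problem formalization

A paired dataset `T_n = {(x_c,i, x_d,i, y_i)}` couples a cell-line omics
profile `x_c ∈ R^d1` with a one-hot drug encoding `x_d ∈ R^d2` and the
natural-log-transformed IC50 target `y ∈ R`.  Omics profiles are measured
once per cell line, so the same `x_c` row recurs across all of that cell
line's drugs; each (cell line, drug) pair maps to a unique target.  The drug
encoding deliberately carries no molecular descriptors, so differences
between omics modalities are not confounded by drug chemistry.

## Preprocessing

* **Zero imputation** (proteomics): missing abundances are assumed to sit
  below the limit of quantitation and are replaced with zeros.
* **Per-cell-line standard scaling** (phosphoproteomics): each cell line's
  profile is centred and scaled to unit SD using the population
  (divide-by-n) convention, correcting sample-level batch effects.
  Zero-variance rows map to all zeros rather than erroring, so degenerate
  synthetic inputs flow through.  Scaling is applied to the full matrix
  *before* feature selection, so row statistics are computed over all
  measured peptides.  It is a per-sample transform with no fitted state, so
  it cannot leak information across the cancer-blind split.
* **Landmark feature selection**: RNA-seq keeps genes in the landmark
  panel; proteomics keeps proteins coded for by landmark genes; phospho
  keeps peptides whose parent protein is landmark-coded *and* that are a
  target of a landmark gene (per the supplied gene→peptide target map).
  Mapping tables are static TSV inputs rather than live database queries,
  so runs are reproducible offline.  Column order is preserved.
* **One-site-per-protein collapse** (optional phospho experiment): keeps
  the highest-variance site per protein, ties broken toward the earlier
  column.  The choice of rule is open in principle; highest variance is the
  most informative single column under a linear-signal view and is
  configurable by swapping the transformer.
* **Feature subsampling** (optional): uniform without replacement, seeded;
  used to test whether a modality's advantage reflects raw feature count.

## Splitting protocol

Cell lines are shuffled by seed and partitioned into train/validation/test
by fractions (default 0.8/0.1/0.1; validation and test sizes are rounded,
the remainder goes to train).  All pairs inherit their cell line's
partition — the cancer-blind guarantee.  The process repeats (default 30
times) with derived seeds.

Within a repeat, training pairs are cut into K nested subsets (default
K = 8, minimum 32 pairs) at log-spaced sizes: prefixes of one seeded
shuffle, so consecutive curve points differ by *added* data, not
resampling.  When curves are averaged across repeats the driver uses one
size grid shared by all repeats, capped at the smallest repeat's training
pair count, so every grid point is averaged over every repeat.  Subsets are
taken over pairs (the default); small subsets may therefore contain few
distinct cell lines.  Fractions, K, the minimum size and the pair-level
convention are configuration, since reasonable alternatives exist (e.g.
subsetting whole cell lines).

## Models

* **Drug-average benchmark**: predicts each drug's training-mean ln(IC50);
  for a drug absent from training, the global training mean.  It ignores
  omics entirely, capturing the fact that some drugs kill most cell lines
  and others few — the dominant variance component of ln(IC50).  Per-drug
  means are computed with `np.mean` over each drug's training rows in the
  dataset's deterministic (cell line, drug) order, so results are bit-exact
  reproducible.
* **Gradient-boosted trees**: XGBoost with squared-error objective on the
  concatenated `(x_c ‖ x_d)` features, histogram tree method, single
  thread.  Boosting is capped (default 300 rounds) and halted when
  validation MSE stalls for 20 rounds.
* **Neural network**: a dense ReLU multilayer perceptron (scikit-learn MLP
  backend) on the same concatenated features, standardised on the training
  rows inside the estimator.  Training proceeds one epoch at a time with
  Adam; after each epoch the MSE on the explicit held-out validation set is
  evaluated, and training stops after `patience` (default 10) epochs
  without improvement, restoring the best epoch's weights.  Defaults:
  hidden layers (128, 64), learning rate 3e-3, batch 256, L2 penalty
  alpha = 10.  The strong default weight decay is deliberate: under
  cancer-blind evaluation the number of *distinct* omics profiles (hundreds
  of cell lines), not the number of pairs (tens of thousands), bounds the
  effective sample size for the omics→sensitivity mapping, and an
  under-regularised network memorises training profiles.  L2 is the
  regulariser because the MLP backend has no dropout; the two-branch
  concatenate-then-dense architecture is mathematically a dense network on
  the concatenated input, which is what is implemented.
* **Random search**: samples hyperparameter assignments (default 15 trials)
  from log/linear ranges and choice lists, fits each with the same data and
  seed, and keeps the assignment with the lowest validation MSE (earliest
  trial wins ties).  Default spaces: GBT — up to 2000 trees with early
  stopping, depth 3–10, learning rate 1e-3–0.3 (log), subsample 0.5–1;
  NN — layer widths {(256,128),(128,64),(64,32),(64,)}, alpha 1e-3–30
  (log), learning rate 1e-4–1e-2 (log), batch {64, 256, 1024}.

Determinism: with fixed seeds and a single thread, repeated fits agree in
validation MSE to well under 1e-6 (bit-level determinism is
backend-dependent); the benchmark and the driver's CSV outputs are
byte-identical across reruns.

## Learning curves

Per-size generalization errors `s_n^k` over repeats are averaged into a
mean curve with standard errors SD/√(repeats) (sample SD, ddof = 1).  The
power law ε(n) = α·n^β is fitted by least squares in (log n, log ε); the
default fit window excludes the smallest and largest observed sizes, since
those are the most likely to lie outside the power-law region.  Regions are
labelled per size from local log-log slopes (forward differences, so a
change point registers at its own grid index): slopes within 25% relative
tolerance of the fitted β are power-law; slopes below 50% of |β| are flat —
flat before the steepest descent is the small-data region, flat after it is
diminishing returns.  Both thresholds are configuration; the region
taxonomy is qualitative and any sharp thresholding of it is a convention.

Extrapolation evaluates α·n^β at a target size and flags predictions beyond
the fitted window; it is trustworthy only while the power-law regime lasts,
and nothing in an observed curve reveals when that regime will end.

Crossing detection between two curves on a shared grid reports the smallest
size where the error difference changes sign *and keeps the new sign
through the final grid size* (transient single-point flips are not
crossings), refined between grid points by linear interpolation in log n.

## Max-size comparison statistics

At the largest schedule size the driver emits a splits × conditions test-MSE
table with per-condition mean, standard error (SD/√splits, same convention
as the curves) and average ranking (rank 1 = lowest MSE per split, midranks
on ties — a condition winning 24 of 30 splits against one rival averages
0.8·1 + 0.2·2 = 1.2).  Percent MSE reduction is 100·(ref − cmp)/ref with
the reference explicit at every call site, positive when the comparison
condition is better.  Per-drug analysis groups squared errors by drug
alongside each drug's target SD (flagging drugs with <2 test pairs);
the association between per-drug MSE and per-drug IC50 SD is a Spearman
correlation with a one-sided permutation p-value (999 permutations,
seeded) for positive association.  Residual normality uses the
D'Agostino–Pearson test, reported but never used as a gate; no
multiple-testing correction is applied — the p-values are descriptive.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs at desk
scale; defaults are 200 cell lines, 50 drugs, 200 features per modality.

* Response surface: `y(c,d) = μ_d + e_c + ε`, with drug-level means
  μ_d ~ N(0, drug_mean_sd²) (default SD 1.0 — drug identity dominates,
  which is what makes the drug-average benchmark strong), a latent
  cell-line sensitivity e_c scaled to SD `cell_effect_sd` (default 0.6) and
  noise ε ~ N(0, noise_sd²) (default SD 0.4).  The defaults put the
  benchmark's cell-line term (0.36) comfortably above the noise floor
  (0.16), so omics-aware learners have real, but bounded, headroom.
* Omics matrices: Gaussian background on a log2-like scale (centre 5,
  SD 2).  The latent effect is embedded through a factor model on the first
  `n_informative_features` (default 20) columns of *every* modality:
  `x_j = 5 + a_j·(e_c + η_m) + noise`, loadings a_j ~ N(0, 2²).  Modalities
  are thus correlated read-outs of one cellular state — matching the
  empirical situation where transcriptome, proteome and phosphoproteome
  reach similar predictive performance — and each modality alone can
  recover most of e_c.  A per-modality distortion η_m (default SD 0)
  plants a modality advantage when raised.
* Missingness: proteomics entries are flagged missing uniformly at random
  at rate 0.38, mirroring the real proteomics matrix; masked entries are
  zero-imputed downstream, which mildly degrades the proteomics read-out —
  as in real data.  The true below-limit-of-quantitation mechanism (values
  missing because they are small) is *not* modelled, since the downstream
  handling is identical either way.
* Sparsity: 20% of (cell line, drug) pairs lack a response by default,
  approximating the incompleteness of large drug screens.

What passing tests on this generator do **not** show: robustness to batch
effects, to non-linear or pathway-structured signal, to informative
missingness, or to drug–cell-line interaction effects (the generator's cell
effect is additive across drugs; real sensitivity profiles interact).  A
model ranking obtained on synthetic data is a check of the *protocol*, not
evidence about real omics modalities.

## Problem sizes used by the shipped runs

The test suite and acceptance script run the full protocol at the default
generator scale (200 cell lines, 50 drugs) with compact model settings
chosen for quick iteration: fixed small GBT/NN hyperparameters instead of
the 15-trial search (the search itself is unit-tested separately), 3–10
repeats instead of 30, and 4-point size grids.  Error bars at these repeat
counts are wide; the protocol's statistical conventions are unchanged.

## Known limitations

* The NN backend (sklearn MLP) offers no dropout and no per-branch
  architecture; very large hidden layers are slow on CPU.
* With few repeats the comparison table's standard errors are themselves
  noisy; average rankings are more stable than mean MSEs at small repeat
  counts.
* Region classification on short (4-point) grids is underdetermined; the
  power-law fit window then covers all observed sizes.
* The driver's resume mode requires an exact config hash match; partial
  results from a different configuration are refused rather than merged.
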