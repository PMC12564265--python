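# Methods

## The problem

Screening deep eutectic solvents (DESs) for a poorly soluble active
ingredient means predicting log10 mole-fraction solubility, log x, for
many candidate solute–solvent–temperature systems from a modest table of
measured values.  Each system is described by 16 COSMO-RS-derived
descriptors: the COSMO-RS *computed* log-solubility (`logx_cosmo`, a
noisy but information-rich surrogate of the target), five solute
(API) quantities — total interaction energy, misfit (electrostatic),
hydrogen-bonding and van der Waals contributions, and the chemical
potential — the same five for the solvent (mole-fraction-weighted sums
over the DES components), and the five relative values (API minus
solvent).  The modelling question is not only "how accurate can a
nu-SVR be on this table" but "what is the simplest model whose accuracy
is statistically indistinguishable from the best", because parsimonious
models generalize better from small, expensive datasets.

## The procedure

One run of the procedure is an iterative loop over feature subsets,
starting from all 16 descriptors:

1. **Anchor the kernel width.** On the standardized training rows of the
   current subset, `gamma_base = 1 / median(pairwise squared Euclidean
   distance)` over a seeded subset of at most 512 rows (the classical
   median heuristic).  The searched quantity is a log-scale refinement
   `log10_gamma_scale ∈ [-1.5, 1.0]`, so the RBF coefficient is
   `gamma_base · 10^scale`.  The anchor is fixed once per iteration so
   all trials within an iteration share it.
2. **Dual-objective search.** Each trial samples `(C, nu, scale)`
   (C log-uniform in [1e-2, 1e3]; nu uniform in [0.05, 0.95]) and scores
   two objectives to be minimized jointly: the 5-fold cross-validated
   MAE, and the mean support-vector ratio across folds (#SV divided by
   that fold's training size — the intrinsic nu-SVR complexity measure).
   All trials in an iteration share one seeded fold partition so the
   objectives are comparable.  The default sampler is an in-package
   tree-structured Parzen estimator adapted to two objectives: the
   history is ranked by dominance count (then MAE), the top
   `min(ceil(0.1 n), 25)` trials form the "good" density, each dimension
   is modelled by a truncated-Gaussian Parzen mixture with a uniform
   exploration component, and the proposal maximizes the good/rest log
   density ratio over 24 candidate draws.  A plain random sampler is
   available with identical trial-record semantics.
3. **Pareto front and 1-SE selection.** The non-dominated set under
   (MAE, SV ratio) is extracted exactly (dominance: ≤ in both, < in at
   least one; exact duplicates keep the lowest trial id).  The iteration
   winner is the minimum-SV-ratio front member whose MAE lies within
   `best MAE + std/sqrt(k)` of the best front member (standard error of
   the fold mean; the raw fold-std band is available via `se_mode`).
4. **Pseudo-AICc scoring.** The winner is refit on all training rows.
   With RSS the residual sum of squares, `σ² = RSS/n` and
   `k = #SV + 2` (bias term + error variance), the Gaussian-residual
   likelihood approximation gives `AIC = n·ln σ² + 2k` (the likelihood
   bracket vanishes identically at σ² = RSS/n; additive constants are
   dropped because only differences matter) and
   `AICc = AIC + 2k(k+1)/(n−k−1)`, with a +∞ sentinel when
   `n ≤ k+1`.  By default RSS comes from the training-set refit; the
   out-of-fold alternative is always computed and reported alongside
   (`rss_source="cv"` swaps the default), and every manifest declares
   which one was used.
5. **Prune.** Features of the winner are ranked by permutation
   importance — mean increase in training-set MAE over 10 seeded
   permutations of one column — and the single least important feature
   is removed (ties break to the earliest feature in schema order).
   Permutation importance is computed on the standardized features;
   permuting a column commutes with standardizing it, so this choice is
   cosmetic.

The loop continues to a minimum feature count (default 6), yielding one
candidate model per complexity level.  A **stability study** repeats the
whole procedure with independent run seeds, records AICc per (run,
complexity), traces the best-per-complexity envelope, and selects the
global minimum-AICc candidate (ties: lower complexity, then lower run
id).  The reported "optimal region" is the contiguous complexity
interval around the minimizer where the envelope stays within 2 AICc
units — the conventional near-equivalence band; envelope convexity is an
empirical observation, not asserted.  Final validation is two-pronged:
5-fold CV with a fresh seed on the training rows (R², MAE, RMSE,
mean ± sd) plus a single fit evaluated on the held-out test set.  The
test split (20%, round-half-up on the train count) is made once, before
any run, and is shared by all runs; a fingerprint of the training-row
identities travels with every candidate and `final_validation` refuses a
table whose split differs (leakage guard).

## Seeding

Everything derives from one master seed: run seeds via
`SeedSequence([master_seed, run_index])`, iteration seeds via
`SeedSequence([run_seed, iteration_index])` (truncated to 31 bits).
Samplers, fold partitions, gamma-anchor subsets, and permutation
importance all consume these derived seeds, so a study is reproducible
end-to-end from `(table, config, master_seed)`.  Manifests are
byte-identical across reruns on the same platform; across BLAS/libsvm
builds, last-ulp float differences are possible.

## The synthetic emulation

The generator produces tables with the real dataset's shape so every
stage is testable without the measured compilation: by default n = 1148
rows and 16 features — 5 informative + 10 nuisance descriptors drawn
from a multivariate Gaussian with exchangeable correlation 0.3, plus one
anchor column playing the computed-solubility role.  The target is a
fixed, versioned smooth function of the informative features
(geometrically weighted tanh terms + one centered quadratic + one
pairwise interaction) plus Gaussian noise of sd 0.3, chosen so the noise
floor sits near the MAE scale reported for real descriptor tables of
this kind; the anchor is `target + 0.5 + N(0, 0.3²)` — biased and noisy,
but the single most informative column, which is exactly the role the
COSMO-RS predicted solubility plays.  What the emulation does *not*
reproduce: the block correlation structure of real API/solvent/relative
descriptor triples (the relative columns of a real table are exact
differences), heteroscedastic measurement error across labs, and any
physics.  Passing recovery tests therefore demonstrates that the
machinery identifies planted structure under realistic noise, not that
it reproduces chemistry.

## Numerical choices

- Standardization uses the population sd (ddof = 0); fold-spread
  statistics use the sample sd (ddof = 1).
- The libsvm solver is capped at 10 000 iterations: extreme (C, gamma)
  corners otherwise cost unbounded time; a capped trial simply scores
  poorly and is discarded by the search.  The cap is configurable on the
  estimator.
- The split rounds the train count half-up (1148 × 0.8 → 918 train /
  230 test).
- Rows with missing descriptor or target values are dropped with a
  per-row report, never imputed; non-numeric cells are a hard parse
  error with row/column coordinates.
- A zero median pairwise distance (duplicate-only subset) and an
  interpolating fit (RSS ≤ 0) are flagged as degenerate rather than
  scored.
- Temperature is metadata, not a 17th feature: the descriptor set is
  exactly the 16 columns above, and temperature enters upstream through
  the COSMO-RS computation that produced them.

## Problem sizes used in the shipped checks

The test suite runs the recovery experiment (10 master seeds, full
16-feature profile, 100 trials/iteration, pruning to 6) at quarter scale
(n = 287) and the determinism check on a 400-row/8-feature table; both
choices keep the default suite desk-sized while leaving the profile's
structure, noise, and budgets unchanged.  `scripts/acceptance.py` runs
the full-size profile (n = 1148) with a 2-run stability study at the
100-trial desk budget.  The full-budget study (12 runs × 2000 trials) is
available through the CLI (`dooit stability --runs 12 --n-trials 2000`)
and takes hours, not minutes, on one CPU.

## Known limitations

- The pseudo-AICc rests on a heuristic effective-parameter count
  (k = #SV + 2) and a Gaussian-residual likelihood; it is a relative
  ranking device within one dataset, not an absolute information
  criterion.
- The two-objective TPE is deliberately small; it has no multivariate
  dependence between dimensions and no prior weighting, and on hard
  landscapes it only modestly beats random search.
- Candidate models at different complexity levels share the training
  rows, so their AICc values are correlated; the stability envelope
  mitigates, but does not remove, selection noise.
- The applicability of a fitted model is bounded by the descriptor
  space it was trained on; nothing in the package estimates an
  applicability domain.
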