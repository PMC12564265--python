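# dooit-qspr

Dual-Objective Optimization with ITerative feature pruning (DOO-IT): a
model-selection framework that discovers maximally parsimonious
nu-support-vector-regression QSPR models.  It was built for predicting
log10 mole-fraction solubility of active pharmaceutical ingredients in
deep eutectic solvents from COSMO-RS-derived descriptor tables, but the
machinery is property-agnostic: any tabular regression task with a
modest, high-value dataset fits.

## Who this is for

Formulation and cheminformatics researchers who have a descriptor table
(here: 16 COSMO-RS descriptors per saturated solute–solvent system — the
computed log-solubility `logx_cosmo`, five solute energetic/chemical-
potential descriptors, five mole-fraction-weighted solvent descriptors,
and five relative values) and want a defensible answer to *which subset
of descriptors and which nuSVR hyperparameters give the simplest model
that is statistically indistinguishable from the most accurate one*.

## The method in brief

Per feature subset, every trial of a dual-objective search samples
(C, ν, log₁₀ γ-scale) — the RBF coefficient is anchored at
γ = γ_base·10^scale with γ_base = 1/median(pairwise d²) on standardized
training rows — and jointly minimizes

* **accuracy**: 5-fold cross-validated MAE, and
* **complexity**: the mean support-vector ratio across folds
  (#SV / fold-training size, the intrinsic nuSVR complexity measure).

From the Pareto front of the trial history, the 1-SE rule picks the
lowest-complexity member with MAE ≤ best MAE + SE.  That model is refit,
scored by a pseudo-corrected-AIC with k = #SV + 2 effective parameters,

    AIC  = n·ln(RSS/n) + 2k
    AICc = AIC + 2k(k+1)/(n−k−1),

its features are ranked by permutation importance (10 repeats), and the
least important one is pruned.  Iterating down to a minimum feature
count yields one candidate per complexity level; a multi-run stability
study traces the best-AICc-per-complexity envelope and selects the
global minimum.  See `docs/methods.md` for assumptions, seeding, and
numerical choices.

## Worked example

```python
from dooit import DooItRegressor, SyntheticSpec, generate, split_train_test

# a synthetic emulation of a descriptor table: 16 features =
# 5 informative + 10 nuisance + 1 computed-solubility anchor
table, truth = generate(SyntheticSpec(n_samples=287, seed=0))
table = split_train_test(table, train_frac=0.8, seed=0)

est = DooItRegressor(n_trials=100, p_min=6, random_state=0)
est.fit(table.df[list(table.feature_names)].iloc[table.mask("train")],
        table.train_y())
print(len(est.selected_features_), sorted(est.selected_features_))
print(round(est.best_candidate_.aicc, 1))
```

prints

```
7 ['anchor', 'x01', 'x02', 'x03', 'x04', 'x05', 'x10']
-524.1
```

i.e. the search kept all five informative features (`x01`–`x05`) plus
the anchor (the computed-solubility surrogate), pruned nine of the ten
nuisance descriptors, and the minimum-pseudo-AICc candidate sits at 7
features (negative AICc values are fine — only differences between
candidates matter).

The same workflow from the shell:

```bash
dooit generate --out table.csv --seed 0
dooit stability --data table.csv --schema table.schema.json \
      --fast --runs 3 --master-seed 0 --outdir study/
dooit report --manifest study/manifest.json
dooit validate --data table.csv --schema table.schema.json \
      --run-manifest study/manifest.json   # for single-run manifests
```

Real tables are plain CSV/TSV with a header; column names are mapped to
the canonical descriptor schema by a YAML/JSON schema file
(`TableSchema.cosmo_rs()` is the identity mapping for the standard 16
names).  Rows with missing values are dropped and reported, never
imputed.

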