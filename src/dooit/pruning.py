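"""Iterative backward feature pruning with pseudo-AICc scoring.

Each pruning iteration runs a full dual-objective search on the current
feature subset, picks the 1-SE winner from the Pareto front, refits it on
all training rows, scores it with a pseudo-corrected-AIC, ranks features
by permutation importance, and removes the single least important one.
The loop yields one candidate model per complexity level, from the full
feature count down to a configured minimum.

The pseudo-AICc treats the fitted nuSVR as a Gaussian-residual model with
k = (#support vectors) + 2 effective parameters (bias term and error
variance).  With sigma^2 = RSS/n the log-likelihood bracket collapses, so
AIC = n*ln(sigma^2) + 2k up to an additive constant that cancels in model
comparison, and AICc = AIC + 2k(k+1)/(n - k - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .dataset import ModelingTable
from .errors import DegenerateFitError, IterationError
from .search import (
    SearchSpace,
    SelectionOutcome,
    Trial,
    one_se_select,
    pareto_front,
    run_doo,
)
from .svr import FitReport, HyperParams, fit_full, gamma_base
from sklearn.model_selection import KFold
from sklearn.base import clone
from .dataset import standardize


@dataclass
class ImportanceReport:
    """Permutation importances: mean MAE increase per feature, with repeats."""

    features: tuple[str, ...]
    importances_mean: np.ndarray  # target units (MAE increase)
    importances: np.ndarray  # shape (n_features, n_repeats)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.features, map(float, self.importances_mean)))


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Mean increase in training-set MAE when one column is permuted.

    For each feature: importance = mean over seeded repeats of
    [MAE(permuted column) - MAE(baseline)].  Positive values mean the
    model relies on the feature.
    """
    res = _sk_permutation_importance(
        model, X, y,
        scoring="neg_mean_absolute_error",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return ImportanceReport(
        features=tuple(features),
        importances_mean=np.asarray(res.importances_mean, dtype=float),
        importances=np.asarray(res.importances, dtype=float),
    )


def prune_least_important(
    features: Sequence[str],
    report: ImportanceReport,
    canonical_order: Sequence[str] | None = None,
) -> tuple[list[str], str]:
    """Drop the argmin-importance feature; returns (reduced list, removed).

    Ties break toward the earliest feature in ``canonical_order`` (the
    full-schema order; defaults to the order of ``features``).
    """
    features = list(features)
    if len(features) < 2:
        raise IterationError("cannot prune below one feature")
    order = list(canonical_order) if canonical_order is not None else features
    scores = report.as_dict()
    min_score = min(scores[f] for f in features)
    ties = [f for f in features if scores[f] == min_score]
    removed = min(ties, key=order.index)
    return [f for f in features if f != removed], removed


def pseudo_aicc(rss: float, n: int, n_sv: int) -> tuple[float, float]:
    """Gaussian-residual pseudo information criteria for a fitted nuSVR.

    k = n_sv + 2 (support vectors + bias + error variance);
    sigma^2 = rss/n; aic = n*ln(sigma^2) + 2k;
    aicc = aic + 2k(k+1)/(n - k - 1) for n > k + 1, else +inf.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    if rss <= 0:
        raise DegenerateFitError(
            f"RSS must be positive to score a model, got {rss} "
            "(perfect interpolation is flagged, not scored)"
        )
    k = n_sv + 2
    sigma2 = rss / n
    aic = n * math.log(sigma2) + 2 * k
    if n > k + 1:
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = math.inf
    return aic, aicc


@dataclass
class CandidateModel:
    """The 1-SE-selected model at one feature-count level."""

    feature_subset: tuple[str, ...]
    hp: HyperParams
    fit: FitReport
    n: int  # training rows
    k_eff: int  # n_support_vectors + 2
    rss: float
    sigma2: float
    aic: float
    aicc: float
    iteration_index: int
    gamma_base: float
    rss_source: str = "train"
    cv_rss: float | None = None
    cv_aicc: float | None = None
    selection: SelectionOutcome | None = None
    train_fingerprint: str | None = None

    def to_dict(self) -> dict:
        return {
            "iteration_index": self.iteration_index,
            "n_features": len(self.feature_subset),
            "feature_subset": list(self.feature_subset),
            "hp": self.hp.to_dict(),
            "n": self.n,
            "n_support_vectors": self.fit.n_support_vectors,
            "sv_ratio": self.fit.sv_ratio,
            "k_eff": self.k_eff,
            "rss": self.rss,
            "sigma2": self.sigma2,
            "aic": self.aic,
            "aicc": self.aicc,
            "rss_source": self.rss_source,
            "cv_rss": self.cv_rss,
            "cv_aicc": self.cv_aicc,
            "gamma_base": self.gamma_base,
            "effective_gamma": self.fit.effective_gamma,
            "train_fingerprint": self.train_fingerprint,
        }


@dataclass(frozen=True)
class DooItConfig:
    """Every knob of one DOO-IT run."""

    n_trials: int = 2000
    p_min: int = 6
    sampler: str = "tpe"
    k_folds: int = 5
    n_importance_repeats: int = 10
    gamma_subset_size: int = 512
    space: SearchSpace = field(default_factory=SearchSpace)
    rss_source: str = "train"  # or "cv"
    se_mode: str = "sem"  # or "std"

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.p_min < 1:
            raise ValueError("n_trials and p_min must be positive")
        if self.rss_source not in {"train", "cv"}:
            raise ValueError("rss_source must be 'train' or 'cv'")

    def to_dict(self) -> dict:
        d = {
            "n_trials": self.n_trials,
            "p_min": self.p_min,
            "sampler": self.sampler,
            "k_folds": self.k_folds,
            "n_importance_repeats": self.n_importance_repeats,
            "gamma_subset_size": self.gamma_subset_size,
            "rss_source": self.rss_source,
            "se_mode": self.se_mode,
            "space": {
                "c_range": list(self.space.c_range),
                "nu_range": list(self.space.nu_range),
                "gamma_scale_range": list(self.space.gamma_scale_range),
            },
        }
        return d


@dataclass
class DooItResult:
    """One full pruning run: a candidate per complexity level plus the trace."""

    candidates: list[CandidateModel]
    trace: list[dict]  # one record per iteration: removed feature + importance
    config: DooItConfig
    run_seed: int
    trials_per_iteration: list[list[Trial]] = field(default_factory=list)

    def best_by_aicc(self) -> CandidateModel:
        return min(self.candidates, key=lambda c: (c.aicc, len(c.feature_subset),
                                                   c.iteration_index))

    def to_manifest(self) -> dict:
        return {
            "run_seed": self.run_seed,
            "config": self.config.to_dict(),
            "rss_source": self.config.rss_source,
            "candidates": [c.to_dict() for c in self.candidates],
            "trace": self.trace,
        }


def _iteration_seed(run_seed: int, iteration_index: int) -> int:
    """Seed for one pruning iteration: SeedSequence([run_seed, index])."""
    state = np.random.SeedSequence([int(run_seed), int(iteration_index)])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


def _cv_rss(X, y, hp, k_folds, seed, gb) -> float:
    """Out-of-fold residual sum of squares for the selected configuration."""
    from .svr import AnchoredNuSVR

    proto = AnchoredNuSVR(C=hp.C, nu=hp.nu,
                          log10_gamma_scale=hp.log10_gamma_scale, gamma_base=gb)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rss = 0.0
    for tr, va in kf.split(X):
        model = clone(proto).fit(X[tr], y[tr])
        rss += float(np.sum((y[va] - model.predict(X[va])) ** 2))
    return rss


def run_doo_it(
    table: ModelingTable,
    config: DooItConfig,
    run_seed: int = 0,
) -> DooItResult:
    """The full DOO-IT procedure on one split table.

    Per iteration: fix the gamma anchor on the standardized training rows
    of the current subset, run the dual-objective search, extract the
    Pareto front, apply the 1-SE rule, refit the winner on all training
    rows, score it with the pseudo-AICc, rank features by permutation
    importance, and prune the least important.  Fully reproducible from
    (table, config, run_seed); iteration seeds derive from
    ``SeedSequence([run_seed, iteration_index])``.
    """
    features = list(table.feature_names)
    if len(features) < config.p_min:
        raise IterationError(
            f"table has {len(features)} features, fewer than p_min={config.p_min}"
        )
    canonical = list(table.feature_names)
    y = table.train_y()
    n_train = len(y)
    fingerprint = table.train_fingerprint()

    candidates: list[CandidateModel] = []
    trace: list[dict] = []
    histories: list[list[Trial]] = []

    n_iterations = len(features) - config.p_min + 1
    for it in range(n_iterations):
        seed = _iteration_seed(run_seed, it)
        X = table.train_X(features)
        Xs, _, _, _ = standardize(X, feature_names=features)
        gb = gamma_base(Xs, config.gamma_subset_size, seed)

        trials = run_doo(
            X, y,
            n_trials=config.n_trials,
            sampler=config.sampler,
            seed=seed,
            space=config.space,
            k_folds=config.k_folds,
            cv_seed=seed,
            gamma_base_value=gb,
        )
        histories.append(trials)
        front = pareto_front(trials)
        selection = one_se_select(front, k_folds=config.k_folds,
                                  se_mode=config.se_mode)
        hp = selection.selected_trial.hp

        report = fit_full(X, y, hp, gamma_base_value=gb)
        train_rss = float(np.sum(report.residuals**2))
        cv_rss = _cv_rss(X, y, hp, config.k_folds, seed, gb)
        rss = train_rss if config.rss_source == "train" else cv_rss
        aic, aicc = pseudo_aicc(rss, n_train, report.n_support_vectors)
        _, cv_aicc = pseudo_aicc(cv_rss, n_train, report.n_support_vectors)

        imp = permutation_importance(
            report.model, X, y, features,
            n_repeats=config.n_importance_repeats, seed=seed,
        )

        candidates.append(
            CandidateModel(
                feature_subset=tuple(features),
                hp=hp,
                fit=report,
                n=n_train,
                k_eff=report.n_support_vectors + 2,
                rss=rss,
                sigma2=rss / n_train,
                aic=aic,
                aicc=aicc,
                iteration_index=it,
                gamma_base=gb,
                rss_source=config.rss_source,
                cv_rss=cv_rss,
                cv_aicc=cv_aicc,
                selection=selection,
                train_fingerprint=fingerprint,
            )
        )

        if len(features) <= config.p_min:
            break
        reduced, removed = prune_least_important(features, imp, canonical)
        trace.append(
            {
                "iteration_index": it,
                "removed_feature": removed,
                "importance": float(imp.as_dict()[removed]),
                "importances": imp.as_dict(),
            }
        )
        features = reduced

    return DooItResult(
        candidates=candidates,
        trace=trace,
        config=config,
        run_seed=run_seed,
        trials_per_iteration=histories,
    )
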