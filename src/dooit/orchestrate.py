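"""Multi-run stability analysis, final validation, and learning curves.

A stability study repeats the whole DOO-IT procedure with independent run
seeds (all derived from one master seed), records the pseudo-AICc of the
candidate at every complexity level, traces the best-per-complexity
envelope, and selects the global-minimum-AICc candidate.  The held-out
test set is created once, before any run, and shared by all of them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)
from sklearn.model_selection import KFold

from .dataset import ModelingTable
from .errors import LeakageError
from .pruning import CandidateModel, DooItConfig, DooItResult, run_doo_it
from .svr import AnchoredNuSVR


def run_seed_for(master_seed: int, run_index: int) -> int:
    """Seed of run ``run_index``: SeedSequence([master_seed, run_index])."""
    seq = np.random.SeedSequence([int(master_seed), int(run_index)])
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StabilityReport:
    """Per-run, per-complexity AICc records with envelope and global best."""

    runs: int
    records: list[dict]  # {"run_id", "n_features", "aicc", ...}
    envelope: dict[int, float]  # n_features -> best aicc over runs
    global_best: tuple[int, int, CandidateModel]  # (run_id, n_features, model)
    optimal_region: tuple[int, int]  # complexity interval around the minimum
    results: list[DooItResult] = field(default_factory=list)
    failed_runs: list[dict] = field(default_factory=list)

    def to_manifest(self) -> dict:
        run_id, n_features, cand = self.global_best
        return {
            "runs": self.runs,
            "records": self.records,
            "envelope": {str(k): v for k, v in sorted(self.envelope.items())},
            "global_best": {
                "run_id": run_id,
                "n_features": n_features,
                "candidate": cand.to_dict(),
            },
            "optimal_region": list(self.optimal_region),
            "failed_runs": self.failed_runs,
            "run_manifests": [r.to_manifest() for r in self.results],
        }


def stability_analysis(
    table: ModelingTable,
    config: DooItConfig,
    n_runs: int = 12,
    master_seed: int = 0,
) -> StabilityReport:
    """Repeat DOO-IT ``n_runs`` times; runs differ only in their run seed.

    The envelope is the minimum AICc per complexity level across runs; the
    global best is the envelope minimum, ties broken by lower complexity
    then lower run id.  The optimal region is the contiguous complexity
    interval around the minimizer where the envelope stays within 2 AICc
    units of the minimum (the conventional near-equivalence band).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    results: list[DooItResult] = []
    records: list[dict] = []
    failed: list[dict] = []
    for run_id in range(n_runs):
        seed = run_seed_for(master_seed, run_id)
        try:
            res = run_doo_it(table, config, run_seed=seed)
        except Exception as exc:
            warnings.warn(f"run {run_id} failed and is excluded: {exc}")
            failed.append({"run_id": run_id, "run_seed": seed, "error": str(exc)})
            continue
        results.append(res)
        for cand in res.candidates:
            records.append(
                {
                    "run_id": run_id,
                    "run_seed": seed,
                    "n_features": len(cand.feature_subset),
                    "aicc": cand.aicc,
                    "aic": cand.aic,
                    "sv_ratio": cand.fit.sv_ratio,
                    "cv_mae": cand.selection.selected_trial.cv_mae
                    if cand.selection
                    else None,
                }
            )
    if not results:
        raise LeakageError("every run failed; no stability report")  # pragma: no cover

    envelope: dict[int, float] = {}
    best_at: dict[int, tuple[float, int, CandidateModel]] = {}
    failed_ids = {f["run_id"] for f in failed}
    run_ids = [i for i in range(n_runs) if i not in failed_ids]
    for run_id, res in zip(run_ids, results):
        for cand in res.candidates:
            c = len(cand.feature_subset)
            key = (cand.aicc, run_id)
            if c not in best_at or key < (best_at[c][0], best_at[c][1]):
                best_at[c] = (cand.aicc, run_id, cand)
            envelope[c] = min(envelope.get(c, np.inf), cand.aicc)

    # global best: min envelope; ties -> lower complexity, lower run_id
    global_c = min(envelope, key=lambda c: (envelope[c], c, best_at[c][1]))
    _, g_run, g_cand = best_at[global_c]

    # optimal region: contiguous complexities with envelope <= min + 2
    comps = sorted(envelope)
    aicc_min = envelope[global_c]
    lo = hi = global_c
    ci = comps.index(global_c)
    j = ci
    while j - 1 >= 0 and envelope[comps[j - 1]] <= aicc_min + 2.0:
        j -= 1
        lo = comps[j]
    j = ci
    while j + 1 < len(comps) and envelope[comps[j + 1]] <= aicc_min + 2.0:
        j += 1
        hi = comps[j]

    return StabilityReport(
        runs=n_runs,
        records=records,
        envelope=envelope,
        global_best=(g_run, global_c, g_cand),
        optimal_region=(lo, hi),
        results=results,
        failed_runs=failed,
    )


@dataclass
class ValidationMetrics:
    """Two-pronged validation: k-fold CV on training rows + held-out test."""

    cv_r2_mean: float
    cv_r2_std: float
    cv_mae_mean: float
    cv_mae_std: float
    cv_rmse_mean: float
    cv_rmse_std: float
    test_r2: float
    test_mae: float
    test_rmse: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def final_validation(
    candidate: CandidateModel,
    table: ModelingTable,
    k_folds: int = 5,
    seed: int = 0,
    model=None,
) -> ValidationMetrics:
    """CV metrics from a fresh seeded fold split plus held-out-test metrics.

    Training rows are re-cross-validated with ``seed``; the test metrics
    come from a single model fit on all training rows.  Raises
    :class:`LeakageError` if the table's training rows differ from those
    the candidate was selected on.
    """
    if candidate.train_fingerprint is not None:
        if table.train_fingerprint() != candidate.train_fingerprint:
            raise LeakageError(
                "table training rows differ from the rows the candidate "
                "was selected on; test rows may have leaked into selection"
            )
    X_tr = table.train_X(candidate.feature_subset)
    y_tr = table.train_y()
    X_te = table.test_X(candidate.feature_subset)
    y_te = table.test_y()

    proto = model if model is not None else AnchoredNuSVR(
        C=candidate.hp.C,
        nu=candidate.hp.nu,
        log10_gamma_scale=candidate.hp.log10_gamma_scale,
        gamma_base=candidate.gamma_base,
    )
    r2s, maes, rmses = [], [], []
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, va in kf.split(X_tr):
        m = clone(proto).fit(X_tr[tr], y_tr[tr])
        pred = m.predict(X_tr[va])
        r2s.append(r2_score(y_tr[va], pred))
        maes.append(mean_absolute_error(y_tr[va], pred))
        rmses.append(np.sqrt(mean_squared_error(y_tr[va], pred)))

    final = clone(proto).fit(X_tr, y_tr)
    pred_te = final.predict(X_te)
    return ValidationMetrics(
        cv_r2_mean=float(np.mean(r2s)),
        cv_r2_std=float(np.std(r2s, ddof=1)),
        cv_mae_mean=float(np.mean(maes)),
        cv_mae_std=float(np.std(maes, ddof=1)),
        cv_rmse_mean=float(np.mean(rmses)),
        cv_rmse_std=float(np.std(rmses, ddof=1)),
        test_r2=float(r2_score(y_te, pred_te)),
        test_mae=float(mean_absolute_error(y_te, pred_te)),
        test_rmse=float(np.sqrt(mean_squared_error(y_te, pred_te))),
    )


@dataclass
class LearningCurveReport:
    """Train/CV MSE as a function of training-subset size."""

    sizes: list[int]
    train_mse: list[float]
    cv_mse: list[float]
    generalization_gap: list[float]
    skipped_sizes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "train_mse": self.train_mse,
            "cv_mse": self.cv_mse,
            "generalization_gap": self.generalization_gap,
            "skipped_sizes": self.skipped_sizes,
        }


def learning_curve(
    candidate: CandidateModel,
    table: ModelingTable,
    sizes,
    k_folds: int = 5,
    seed: int = 0,
    model=None,
) -> LearningCurveReport:
    """Seeded-subsample learning curve for the candidate's configuration.

    For each size: draw a seeded subsample of training rows, run k-fold CV
    inside the subsample (cv_mse) and fit on the whole subsample
    (train_mse); the generalization gap is |train_mse - cv_mse|.  Sizes
    smaller than ``2*k_folds`` are skipped with a warning.
    """
    sizes = sorted(int(s) for s in sizes)
    X_tr = table.train_X(candidate.feature_subset)
    y_tr = table.train_y()
    if sizes and sizes[-1] > len(y_tr):
        raise ValueError(
            f"largest size {sizes[-1]} exceeds training rows {len(y_tr)}"
        )
    proto = model if model is not None else AnchoredNuSVR(
        C=candidate.hp.C,
        nu=candidate.hp.nu,
        log10_gamma_scale=candidate.hp.log10_gamma_scale,
        gamma_base=candidate.gamma_base,
    )
    rng = np.random.default_rng(seed)
    out_sizes, train_mse, cv_mse, gaps, skipped = [], [], [], [], []
    for size in sizes:
        if size < 2 * k_folds:
            warnings.warn(f"size {size} < 2*k_folds, skipped")
            skipped.append(size)
            continue
        if size == len(y_tr):
            idx = np.arange(size)  # full set: keep row order, align with CV folds
        else:
            idx = rng.choice(len(y_tr), size=size, replace=False)
        Xs, ys = X_tr[idx], y_tr[idx]
        fold_mse = []
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        for tr, va in kf.split(Xs):
            m = clone(proto).fit(Xs[tr], ys[tr])
            fold_mse.append(mean_squared_error(ys[va], m.predict(Xs[va])))
        m_full = clone(proto).fit(Xs, ys)
        t_mse = float(mean_squared_error(ys, m_full.predict(Xs)))
        c_mse = float(np.mean(fold_mse))
        out_sizes.append(size)
        train_mse.append(t_mse)
        cv_mse.append(c_mse)
        gaps.append(abs(t_mse - c_mse))
    return LearningCurveReport(
        sizes=out_sizes,
        train_mse=train_mse,
        cv_mse=cv_mse,
        generalization_gap=gaps,
        skipped_sizes=skipped,
    )


def config_hash(config: DooItConfig) -> str:
    """Stable hash of a run configuration, for manifests."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
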