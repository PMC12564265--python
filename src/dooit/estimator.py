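"""scikit-learn meta-estimator wrapping the full DOO-IT procedure.

``DooItRegressor.fit(X, y)`` runs the iterative dual-objective search and
pruning loop on the supplied data, keeps one candidate model per
complexity level, selects the minimum-pseudo-AICc candidate, and refits it
for prediction.  The estimator composes with sklearn model selection; the
held-out split the command-line workflow maintains is the caller's
responsibility here, as usual for sklearn estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import ModelingTable
from .pruning import DooItConfig, run_doo_it
from .search import SearchSpace


class DooItRegressor(BaseEstimator, RegressorMixin):
    """Dual-objective nuSVR model selection with iterative feature pruning.

    Parameters
    ----------
    n_trials : int
        Dual-objective search budget per pruning iteration.
    p_min : int
        Minimum feature count the pruning descends to.
    sampler : {"tpe", "random"}
        Hyperparameter sampler.
    k_folds : int
        Folds of the cross-validated MAE objective.
    n_importance_repeats : int
        Permutation-importance repeats used for pruning.
    rss_source : {"train", "cv"}
        Residuals used in the pseudo-AICc (training-set refit or
        out-of-fold).
    c_range, nu_range, gamma_scale_range
        Search-space bounds (C log-uniform; others uniform).
    random_state : int
        Run seed; all iteration seeds derive from it.

    Attributes
    ----------
    candidates_ : list of CandidateModel
        One 1-SE-selected candidate per complexity level.
    best_candidate_ : CandidateModel
        The global minimum-pseudo-AICc candidate.
    selected_features_ : tuple of str
        Feature names of the selected model.
    best_model_ : AnchoredNuSVR
        The refitted selected model used by :meth:`predict`.
    pruning_trace_ : list of dict
        Removed feature and importances per iteration.
    aicc_by_complexity_ : dict
        n_features -> pseudo-AICc of that level's candidate.
    """

    def __init__(
        self,
        n_trials: int = 100,
        p_min: int = 6,
        sampler: str = "tpe",
        k_folds: int = 5,
        n_importance_repeats: int = 10,
        rss_source: str = "train",
        c_range: tuple[float, float] = (1e-2, 1e3),
        nu_range: tuple[float, float] = (0.05, 0.95),
        gamma_scale_range: tuple[float, float] = (-1.5, 1.0),
        gamma_subset_size: int = 512,
        random_state: int = 0,
    ) -> None:
        self.n_trials = n_trials
        self.p_min = p_min
        self.sampler = sampler
        self.k_folds = k_folds
        self.n_importance_repeats = n_importance_repeats
        self.rss_source = rss_source
        self.c_range = c_range
        self.nu_range = nu_range
        self.gamma_scale_range = gamma_scale_range
        self.gamma_subset_size = gamma_subset_size
        self.random_state = random_state

    def _config(self) -> DooItConfig:
        return DooItConfig(
            n_trials=self.n_trials,
            p_min=self.p_min,
            sampler=self.sampler,
            k_folds=self.k_folds,
            n_importance_repeats=self.n_importance_repeats,
            gamma_subset_size=self.gamma_subset_size,
            space=SearchSpace(
                c_range=tuple(self.c_range),
                nu_range=tuple(self.nu_range),
                gamma_scale_range=tuple(self.gamma_scale_range),
            ),
            rss_source=self.rss_source,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = tuple(str(c) for c in X.columns)
        else:
            names = None
        X_arr, y_arr = check_X_y(X, y, dtype=float)
        if names is None:
            names = tuple(f"x{i}" for i in range(X_arr.shape[1]))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X_arr.shape[1]

        df = pd.DataFrame(X_arr, columns=list(names))
        df["__target__"] = y_arr
        df["split"] = "train"
        table = ModelingTable(df=df, feature_names=names,
                              target_name="__target__")

        self.result_ = run_doo_it(table, self._config(),
                                  run_seed=self.random_state)
        self.candidates_ = self.result_.candidates
        self.best_candidate_ = self.result_.best_by_aicc()
        self.selected_features_ = self.best_candidate_.feature_subset
        self.best_model_ = self.best_candidate_.fit.model
        self.pruning_trace_ = self.result_.trace
        self.aicc_by_complexity_ = {
            len(c.feature_subset): c.aicc for c in self.candidates_
        }
        self._selected_idx_ = [list(names).index(f)
                               for f in self.selected_features_]
        return self

    def predict(self, X):
        check_is_fitted(self, "best_model_")
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.selected_features_)].to_numpy(dtype=float)
        else:
            X = check_array(X, dtype=float)[:, self._selected_idx_]
        return self.best_model_.predict(X)
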