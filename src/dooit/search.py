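"""Dual-objective hyperparameter search.

Each trial samples a nuSVR configuration and scores two objectives to be
minimized jointly: cross-validated MAE (accuracy) and the mean
support-vector ratio across folds (complexity).  The non-dominated subset
of the trial history is the Pareto front; the per-iteration winner is the
lowest-complexity front member whose MAE lies within one standard error of
the best front MAE (the 1-SE rule).

Two samplers are provided: an independent random sampler and a
tree-structured Parzen estimator (TPE).  The TPE splits the history into a
"good" set (lowest dominance rank, ties by MAE) and the rest, models each
hyperparameter dimension with a Parzen mixture of truncated Gaussians plus
a uniform exploration component, and proposes the candidate maximising the
good/rest density ratio.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .errors import IterationError
from .svr import CvResult, HyperParams, cv_evaluate


@dataclass(frozen=True)
class SearchSpace:
    """Bounds of the three searched hyperparameters.

    C is sampled log-uniformly, nu and the gamma scale uniformly.
    """

    c_range: tuple[float, float] = (1e-2, 1e3)
    nu_range: tuple[float, float] = (0.05, 0.95)
    gamma_scale_range: tuple[float, float] = (-1.5, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.c_range, self.nu_range, self.gamma_scale_range):
            if not lo < hi:
                raise ValueError("search ranges must satisfy lo < hi")
        if self.c_range[0] <= 0:
            raise ValueError("C range must be positive")

    # Internal coordinates: (log10 C, nu, log10_gamma_scale), all bounded.
    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [
            (math.log10(self.c_range[0]), math.log10(self.c_range[1])),
            self.nu_range,
            self.gamma_scale_range,
        ]

    def to_hp(self, u: np.ndarray) -> HyperParams:
        return HyperParams(C=10.0 ** u[0], nu=float(u[1]),
                           log10_gamma_scale=float(u[2]))

    def to_unit(self, hp: HyperParams) -> np.ndarray:
        return np.array([math.log10(hp.C), hp.nu, hp.log10_gamma_scale])


@dataclass(frozen=True)
class Trial:
    """One scored configuration."""

    trial_id: int
    hp: HyperParams
    cv_mae: float
    cv_mae_std: float
    sv_ratio: float
    timestamp: float = 0.0

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "hp": self.hp.to_dict(),
            "cv_mae": self.cv_mae,
            "cv_mae_std": self.cv_mae_std,
            "sv_ratio": self.sv_ratio,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trial":
        return cls(
            trial_id=int(d["trial_id"]),
            hp=HyperParams(**d["hp"]),
            cv_mae=float(d["cv_mae"]),
            cv_mae_std=float(d["cv_mae_std"]),
            sv_ratio=float(d["sv_ratio"]),
            timestamp=float(d.get("timestamp", 0.0)),
        )


class RandomSampler:
    """Independent uniform sampling over the (transformed) search space."""

    def __init__(self, space: SearchSpace, seed: int = 0) -> None:
        self.space = space
        self._rng = np.random.default_rng(seed)

    def suggest(self, history: list[Trial]) -> HyperParams:
        u = np.array([self._rng.uniform(lo, hi) for lo, hi in self.space.bounds])
        return self.space.to_hp(u)


def _dominance_counts(mae: np.ndarray, sv: np.ndarray) -> np.ndarray:
    """Number of trials strictly dominating each trial (vectorized)."""
    le = (mae[:, None] <= mae[None, :]) & (sv[:, None] <= sv[None, :])
    lt = (mae[:, None] < mae[None, :]) | (sv[:, None] < sv[None, :])
    return (le & lt).sum(axis=0)


class TpeSampler:
    """Tree-structured Parzen estimator adapted to two objectives.

    The first ``n_startup`` suggestions are random.  Afterwards the
    history is ordered by (dominance count, cv_mae) and the first
    ``min(ceil(0.1·n), 25)`` trials form the "good" split.  Each dimension
    gets two Parzen mixtures (good / rest) of truncated Gaussians with a
    Scott-style bandwidth and a uniform component for exploration;
    ``n_candidates`` draws from the good mixture are ranked by the log
    density ratio and the best is proposed.
    """

    def __init__(
        self,
        space: SearchSpace,
        seed: int = 0,
        n_startup: int = 10,
        n_candidates: int = 24,
    ) -> None:
        self.space = space
        self.n_startup = n_startup
        self.n_candidates = n_candidates
        self._rng = np.random.default_rng(seed)

    # -- Parzen helpers ----------------------------------------------------
    def _mixture(self, obs: np.ndarray, lo: float, hi: float):
        """(mus, sigma, uniform_weight) of a per-dimension Parzen mixture."""
        width = hi - lo
        sigma = max(width * 1.06 * len(obs) ** -0.2, width * 0.01)
        return obs, sigma, width

    def _logpdf(self, x: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
        mus, sigma, width = self._mixture(obs, lo, hi)
        k = len(mus)
        # truncated normal components, equal weights, plus one uniform
        z = (x[:, None] - mus[None, :]) / sigma
        norm = ndtr((hi - mus) / sigma) - ndtr((lo - mus) / sigma)
        comp = np.exp(-0.5 * z**2) / (sigma * math.sqrt(2 * math.pi))
        comp = comp / np.maximum(norm, 1e-12)[None, :]
        dens = (comp.sum(axis=1) + 1.0 / width) / (k + 1)
        return np.log(np.maximum(dens, 1e-300))

    def _sample_dim(self, obs: np.ndarray, lo: float, hi: float, size: int) -> np.ndarray:
        mus, sigma, width = self._mixture(obs, lo, hi)
        k = len(mus)
        pick = self._rng.integers(0, k + 1, size=size)
        out = np.empty(size)
        uniform = pick == k
        out[uniform] = self._rng.uniform(lo, hi, size=int(uniform.sum()))
        gauss = ~uniform
        if gauss.any():
            m = mus[pick[gauss]]
            a, b = ndtr((lo - m) / sigma), ndtr((hi - m) / sigma)
            u = self._rng.uniform(a, b)
            # inverse-CDF sampling of the truncated normal
            from scipy.special import ndtri

            out[gauss] = m + sigma * ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        return np.clip(out, lo, hi)

    def suggest(self, history: list[Trial]) -> HyperParams:
        n = len(history)
        if n < self.n_startup:
            u = np.array([self._rng.uniform(lo, hi) for lo, hi in self.space.bounds])
            return self.space.to_hp(u)

        mae = np.array([t.cv_mae for t in history])
        sv = np.array([t.sv_ratio for t in history])
        order = np.lexsort((mae, _dominance_counts(mae, sv)))
        n_good = max(2, min(math.ceil(0.1 * n), 25))
        good = order[:n_good]
        rest = order[n_good:]
        if rest.size == 0:
            rest = order

        U = np.stack([self.space.to_unit(t.hp) for t in history])
        cands = np.column_stack(
            [
                self._sample_dim(U[good, d], lo, hi, self.n_candidates)
                for d, (lo, hi) in enumerate(self.space.bounds)
            ]
        )
        score = np.zeros(self.n_candidates)
        for d, (lo, hi) in enumerate(self.space.bounds):
            score += self._logpdf(cands[:, d], U[good, d], lo, hi)
            score -= self._logpdf(cands[:, d], U[rest, d], lo, hi)
        return self.space.to_hp(cands[int(np.argmax(score))])


_SAMPLERS = {"random": RandomSampler, "tpe": TpeSampler}


def make_sampler(name: str, space: SearchSpace, seed: int):
    try:
        return _SAMPLERS[name](space, seed=seed)
    except KeyError:
        raise ValueError(f"unknown sampler {name!r}; choose from {sorted(_SAMPLERS)}")


def run_doo(
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int,
    sampler: str = "tpe",
    seed: int = 0,
    space: SearchSpace | None = None,
    k_folds: int = 5,
    cv_seed: int | None = None,
    gamma_base_value: float | None = None,
) -> list[Trial]:
    """Run the dual-objective search and return the full trial history.

    Every trial is scored with the same seeded fold partition so that the
    two objectives are comparable across trials.  ``gamma_base_value``
    fixes the kernel-width anchor for the whole search (one anchor per
    pruning iteration).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    space = space or SearchSpace()
    smp = make_sampler(sampler, space, seed)
    cv_seed = seed if cv_seed is None else cv_seed
    trials: list[Trial] = []
    failures: list[str] = []
    for tid in range(n_trials):
        hp = smp.suggest(trials)
        try:
            cv: CvResult = cv_evaluate(
                X, y, hp, k_folds=k_folds, seed=cv_seed,
                gamma_base_value=gamma_base_value,
            )
        except Exception as exc:
            failures.append(f"trial {tid}: {exc}")
            continue
        trials.append(
            Trial(
                trial_id=tid,
                hp=hp,
                cv_mae=cv.mae_mean,
                cv_mae_std=cv.mae_std,
                sv_ratio=cv.sv_ratio_mean,
                timestamp=time.time(),
            )
        )
    if not trials:
        raise IterationError("all trials failed: " + "; ".join(failures))
    return trials


@dataclass
class ParetoFront:
    """Non-dominated trials, sorted by ascending cv_mae."""

    members: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def pareto_front(trials: list[Trial]) -> ParetoFront:
    """Exact non-dominated set under (minimize cv_mae, minimize sv_ratio).

    Dominance is <= in both objectives and < in at least one; exact
    duplicates on both objectives keep only the lowest trial_id.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    ordered = sorted(trials, key=lambda t: (t.cv_mae, t.sv_ratio, t.trial_id))
    front: list[Trial] = []
    best_sv = math.inf
    for t in ordered:
        if t.sv_ratio < best_sv:
            front.append(t)
            best_sv = t.sv_ratio
    return ParetoFront(members=front)


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of applying the 1-SE rule to a Pareto front."""

    best_mae_trial: Trial
    se_threshold: float
    selected_trial: Trial


def one_se_select(
    front: ParetoFront, k_folds: int = 5, se_mode: str = "sem"
) -> SelectionOutcome:
    """Lowest-complexity front member within one standard error of best MAE.

    The band is best MAE + fold-std/sqrt(k) (``se_mode="sem"``, the
    default) or best MAE + fold-std (``se_mode="std"``).  Ties for the
    best trial break toward lower sv_ratio then lower trial_id; ties for
    the selected trial break toward lower cv_mae then lower trial_id.
    """
    if not front.members:
        raise ValueError("front must be non-empty")
    if se_mode not in {"sem", "std"}:
        raise ValueError(f"se_mode must be 'sem' or 'std', got {se_mode!r}")
    best = min(front.members, key=lambda t: (t.cv_mae, t.sv_ratio, t.trial_id))
    se = best.cv_mae_std / math.sqrt(k_folds) if se_mode == "sem" else best.cv_mae_std
    threshold = best.cv_mae + se
    within = [t for t in front.members if t.cv_mae <= threshold]
    selected = min(within, key=lambda t: (t.sv_ratio, t.cv_mae, t.trial_id))
    return SelectionOutcome(best_mae_trial=best, se_threshold=threshold,
                            selected_trial=selected)


def write_trials_jsonl(trials: list[Trial], path) -> None:
    """Persist a trial history as JSON lines (one trial per line)."""
    with open(path, "w") as fh:
        for t in trials:
            fh.write(json.dumps(t.to_dict()) + "\n")


def read_trials_jsonl(path) -> list[Trial]:
    with open(path) as fh:
        return [Trial.from_dict(json.loads(line)) for line in fh if line.strip()]
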