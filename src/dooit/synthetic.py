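"""Synthetic descriptor tables with known ground truth.

Emulates the statistical shape of a COSMO-RS solubility table: a block of
correlated continuous descriptors, a smooth non-linear target, and one
"computed solubility" anchor column that is a noisy, biased surrogate of
the target — the role the COSMO-RS predicted log-solubility plays in the
real data.  The generating function is fixed and versioned so recovery
benchmarks are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dataset import ModelingTable, TableSchema

#: Version tag of the fixed generating function.
GENERATOR_VERSION = "1"

#: Name of the anchor (computed-solubility surrogate) column.
ANCHOR_NAME = "anchor"

_TARGET_NAME = "log_x"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic emulation.

    Defaults mirror the real dataset's shape: n=1148 rows and 16 features
    (5 informative + 10 nuisance + 1 anchor).  ``noise_sd`` is the sd of
    the Gaussian noise on the target (target units, i.e. log10 x);
    ``anchor_bias``/``anchor_noise_sd`` control how biased and noisy the
    computed-solubility surrogate is.
    """

    n_samples: int = 1148
    n_informative: int = 5
    n_nuisance: int = 10
    feature_correlation: float = 0.3
    noise_sd: float = 0.3
    anchor_bias: float = 0.5
    anchor_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_informative < 1 or self.n_nuisance < 0:
            raise ValueError("counts must be positive (n_nuisance may be 0)")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must be in [0, 1)")
        if self.noise_sd < 0 or self.anchor_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")

    @property
    def n_features(self) -> int:
        """Total feature count including the anchor."""
        return self.n_informative + self.n_nuisance + 1


@dataclass(frozen=True)
class GroundTruth:
    """Which features generate the target, and with what parameters."""

    informative: tuple[str, ...]
    nuisance: tuple[str, ...]
    anchor: str
    weights: tuple[float, ...]
    quad_coef: float
    quad_feature: str
    interaction_coef: float
    interaction_features: tuple[str, ...]
    version: str = GENERATOR_VERSION

    def to_dict(self) -> dict:
        return asdict(self)


def _feature_names(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    p = spec.n_informative + spec.n_nuisance
    names = [f"x{i + 1:02d}" for i in range(p)]
    return names[: spec.n_informative], names[spec.n_informative:]


def ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """The generating parameters — a pure, stable function of ``spec``.

    The target is w·tanh(z_inf) + a·(z_q² − 1) + b·z_u·z_v + ε with fixed
    geometrically decaying weights; the quadratic acts on the first
    informative feature and the interaction on the second and third (both
    dropped when too few informative features exist).
    """
    informative, nuisance = _feature_names(spec)
    weights = tuple(1.2 * 0.85**j for j in range(spec.n_informative))
    has_interaction = spec.n_informative >= 3
    return GroundTruth(
        informative=tuple(informative),
        nuisance=tuple(nuisance),
        anchor=ANCHOR_NAME,
        weights=weights,
        quad_coef=0.4,
        quad_feature=informative[0],
        interaction_coef=0.5 if has_interaction else 0.0,
        interaction_features=tuple(informative[1:3]) if has_interaction else (),
    )


def generate(spec: SyntheticSpec) -> tuple[ModelingTable, GroundTruth]:
    """Draw a synthetic descriptor table.

    Raw features follow a multivariate Gaussian with exchangeable
    correlation ``feature_correlation``; the target is the fixed smooth
    non-linear function of the informative features plus Gaussian noise;
    the anchor column is target + anchor_bias + Gaussian(0, anchor_noise_sd).
    Fully deterministic given ``spec``.
    """
    gt = ground_truth(spec)
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_informative + spec.n_nuisance
    rho = spec.feature_correlation

    # Exchangeable correlation via a shared latent factor:
    # z_j = sqrt(rho)*g0 + sqrt(1-rho)*g_j has corr(z_i, z_j) = rho.
    g0 = rng.standard_normal((n, 1))
    g = rng.standard_normal((n, p))
    Z = np.sqrt(rho) * g0 + np.sqrt(1.0 - rho) * g

    informative, nuisance = _feature_names(spec)
    Zi = Z[:, : spec.n_informative]
    clean = (np.tanh(Zi) * np.asarray(gt.weights)).sum(axis=1)
    clean = clean + gt.quad_coef * (Zi[:, 0] ** 2 - 1.0)
    if gt.interaction_coef:
        clean = clean + gt.interaction_coef * Zi[:, 1] * Zi[:, 2]

    y = clean + rng.standard_normal(n) * spec.noise_sd
    anchor = y + spec.anchor_bias + rng.standard_normal(n) * spec.anchor_noise_sd

    df = pd.DataFrame(Z, columns=informative + nuisance)
    df[ANCHOR_NAME] = anchor
    df[_TARGET_NAME] = y

    table = ModelingTable(
        df=df,
        feature_names=(*informative, *nuisance, ANCHOR_NAME),
        target_name=_TARGET_NAME,
        provenance={
            "source": "synthetic",
            "generator_version": GENERATOR_VERSION,
            "spec": asdict(spec),
        },
    )
    return table, gt


def schema_for(spec: SyntheticSpec) -> TableSchema:
    """The I/O schema matching tables produced by :func:`generate`."""
    informative, nuisance = _feature_names(spec)
    names = (*informative, *nuisance, ANCHOR_NAME)
    return TableSchema(features={n: n for n in names}, target=_TARGET_NAME)
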