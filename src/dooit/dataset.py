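"""Descriptor tables: schema, loading, splitting, standardization, fusion helper.

The canonical descriptor set contains 16 COSMO-RS-derived features: the
computed log-solubility anchor, five solute (API) descriptors, five
mole-fraction-weighted solvent descriptors, and five relative (API minus
solvent) descriptors.  Tables are carried as a thin wrapper around a
pandas DataFrame with explicit train/test split labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CompositionError,
    DegenerateInputError,
    ParseError,
    SchemaError,
)

#: Canonical order of the 16 COSMO-RS descriptors.
CANONICAL_DESCRIPTORS: tuple[str, ...] = (
    "logx_cosmo",
    "E_int_API",
    "E_misfit_API",
    "E_HB_API",
    "E_vdW_API",
    "mu_API",
    "E_int_solv",
    "E_misfit_solv",
    "E_HB_solv",
    "E_vdW_solv",
    "mu_solv",
    "E_int_rel",
    "E_misfit_rel",
    "E_HB_rel",
    "E_vdW_rel",
    "mu_rel",
)

_MOLE_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class SolubilitySystem:
    """One saturated solute-solvent system.

    ``target_log_x`` is log10 mole-fraction solubility; solvent composition
    is solute-free and must sum to one.
    """

    solute_id: str
    solvent_components: tuple[tuple[str, float], ...]
    temperature: float  # kelvin
    target_log_x: float

    def __post_init__(self) -> None:
        total = sum(frac for _, frac in self.solvent_components)
        if abs(total - 1.0) > _MOLE_FRACTION_TOL:
            raise CompositionError(
                f"solvent mole fractions sum to {total!r}, expected 1"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not math.isfinite(self.target_log_x):
            raise ValueError("target_log_x must be finite")


@dataclass(frozen=True)
class FusionData:
    """Fusion thermodynamics of a solute under the constant-ΔCp approximation.

    The entropy of fusion is taken as ΔHfus/Tm and the heat capacity of
    fusion is approximated by the entropy of fusion, so the Gibbs energy
    of fusion reduces to ΔHfus·(1 − T/Tm).
    """

    dH_fus: float  # kJ/mol
    T_m: float  # kelvin

    def __post_init__(self) -> None:
        if self.T_m <= 0:
            raise ValueError("melting temperature must be positive")

    @property
    def dS_fus(self) -> float:
        """Entropy of fusion, kJ/mol/K."""
        return self.dH_fus / self.T_m

    @property
    def dCp_fus(self) -> float:
        """Heat capacity of fusion (≈ entropy of fusion), kJ/mol/K."""
        return self.dS_fus

    def dG_fus(self, T: float) -> float:
        """Gibbs energy of fusion at temperature ``T`` (kelvin), kJ/mol."""
        return gibbs_fusion(self.dH_fus, self.T_m, T)


def gibbs_fusion(dH_fus: float, T_m: float, T: float) -> float:
    """Gibbs free energy of fusion: ΔHfus·(1 − T/Tm), in kJ/mol.

    Uses ΔSfus ≈ ΔHfus/Tm, so ΔGfus = ΔHfus − T·ΔSfus = ΔHfus·(1 − T/Tm);
    zero at the melting point and linear in T.
    """
    if T_m <= 0:
        raise ValueError(f"melting temperature must be positive, got {T_m}")
    if T < 0:
        raise ValueError(f"temperature must be non-negative, got {T}")
    return dH_fus * (1.0 - T / T_m)


def solvent_weighted_descriptor(
    component_values: Sequence[float], mole_fractions: Sequence[float]
) -> float:
    """Mole-fraction-weighted sum of a per-component solvent descriptor."""
    if len(component_values) != len(mole_fractions):
        raise CompositionError("values and fractions must have equal length")
    total = float(sum(mole_fractions))
    if abs(total - 1.0) > _MOLE_FRACTION_TOL:
        raise CompositionError(
            f"mole fractions sum to {total!r}, expected 1 ± {_MOLE_FRACTION_TOL}"
        )
    return float(np.dot(component_values, mole_fractions))


#: The five energetic/chemical-potential quantities with API/solv/rel variants.
DESCRIPTOR_QUANTITIES: tuple[str, ...] = ("E_int", "E_misfit", "E_HB", "E_vdW", "mu")


def relative_descriptor_deviation(df: pd.DataFrame) -> float:
    """Max |rel - (API - solv)| over the five relative descriptors.

    The relative descriptors are defined as solute minus solvent values, so
    a well-formed table satisfies this identity to numerical precision.
    """
    dev = 0.0
    for q in DESCRIPTOR_QUANTITIES:
        api, solv, rel = f"{q}_API", f"{q}_solv", f"{q}_rel"
        if all(c in df.columns for c in (api, solv, rel)):
            d = np.abs(df[rel].to_numpy(float)
                       - (df[api].to_numpy(float) - df[solv].to_numpy(float)))
            if d.size:
                dev = max(dev, float(d.max()))
    return dev


@dataclass(frozen=True)
class TableSchema:
    """Maps file columns to model roles.

    ``features`` maps file column name -> canonical feature name (identity
    mapping is typical); ``target`` is the column holding log10 x;
    ``metadata`` columns are carried through untouched.
    """

    features: dict[str, str]
    target: str
    metadata: tuple[str, ...] = ()
    version: str = "1"

    @property
    def feature_names(self) -> tuple[str, ...]:
        """Canonical feature names, in schema order."""
        return tuple(self.features.values())

    @classmethod
    def cosmo_rs(cls, target: str = "log_x",
                 metadata: Sequence[str] = ()) -> "TableSchema":
        """The canonical 16-descriptor COSMO-RS schema (identity mapping)."""
        return cls(
            features={name: name for name in CANONICAL_DESCRIPTORS},
            target=target,
            metadata=tuple(metadata),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        """Load a schema from a YAML or JSON mapping file."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict) or "features" not in raw or "target" not in raw:
            raise SchemaError(f"{path}: schema file needs 'features' and 'target'")
        feats = raw["features"]
        if isinstance(feats, list):
            feats = {name: name for name in feats}
        return cls(
            features=dict(feats),
            target=str(raw["target"]),
            metadata=tuple(raw.get("metadata", ())),
            version=str(raw.get("version", "1")),
        )

    def to_dict(self) -> dict:
        return {
            "features": dict(self.features),
            "target": self.target,
            "metadata": list(self.metadata),
            "version": self.version,
        }


@dataclass
class ModelingTable:
    """Feature matrix + target + split labels; the universal tabular currency.

    ``df`` holds one column per canonical feature name, the target column,
    metadata columns, and (once assigned) a ``split`` column with values
    ``"train"``/``"test"``.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...]
    target_name: str
    standardized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        missing = [c for c in (*self.feature_names, self.target_name)
                   if c not in self.df.columns]
        if missing:
            raise SchemaError(f"table missing columns: {missing}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        names = tuple(features) if features is not None else self.feature_names
        unknown = set(names) - set(self.feature_names)
        if unknown:
            raise SchemaError(f"unknown features requested: {sorted(unknown)}")
        return self.df.loc[:, list(names)].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.df[self.target_name].to_numpy(dtype=float)

    @property
    def has_split(self) -> bool:
        return "split" in self.df.columns

    def mask(self, label: str) -> np.ndarray:
        if not self.has_split:
            raise DegenerateInputError("table has no split labels yet")
        return (self.df["split"] == label).to_numpy()

    def train_X(self, features: Sequence[str] | None = None) -> np.ndarray:
        return self.X(features)[self.mask("train")]

    def train_y(self) -> np.ndarray:
        return self.y()[self.mask("train")]

    def test_X(self, features: Sequence[str] | None = None) -> np.ndarray:
        return self.X(features)[self.mask("test")]

    def test_y(self) -> np.ndarray:
        return self.y()[self.mask("test")]

    def train_fingerprint(self) -> str:
        """Stable fingerprint of the training-row identities (leakage guard)."""
        idx = np.flatnonzero(self.mask("train"))
        return f"{len(idx)}:{int(np.bitwise_xor.reduce((idx + 1) * 2654435761 % (2**31)))}"

    # -- I/O ---------------------------------------------------------------
    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the normalized table as CSV plus a JSON sidecar."""
        csv_path = Path(csv_path)
        self.df.to_csv(csv_path, index=False)
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".json")
        sidecar = {
            "feature_names": list(self.feature_names),
            "target_name": self.target_name,
            "standardized": self.standardized,
            "provenance": self.provenance,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, default=str))


def load_table(path: str | Path, schema: TableSchema) -> ModelingTable:
    """Read a CSV/TSV descriptor table and validate it against ``schema``.

    Rows with any missing or non-numeric descriptor or target are dropped
    and listed in ``provenance["rejections"]`` as (row, column) records;
    row order of the surviving rows is preserved.  A missing required
    column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)

    required = [*schema.features.keys(), schema.target]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")

    numeric = {}
    rejections: list[dict] = []
    bad_rows = np.zeros(len(df), dtype=bool)
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        parse_fail = coerced.isna() & ~raw_na
        if parse_fail.any():
            i = int(np.flatnonzero(parse_fail.to_numpy())[0])
            raise ParseError(
                f"non-numeric cell at row {i}, column {col!r}: "
                f"{df[col].iloc[i]!r}"
            )
        for i in np.flatnonzero(raw_na.to_numpy()):
            rejections.append({"row": int(i), "column": col, "reason": "missing"})
        bad_rows |= coerced.isna().to_numpy()
        numeric[col] = coerced

    out = df.copy()
    for col in required:
        out[col] = numeric[col]
    out = out.loc[~bad_rows].reset_index(drop=True)
    # Rename file columns to canonical feature names.
    out = out.rename(columns=schema.features)

    if set(CANONICAL_DESCRIPTORS) <= set(out.columns):
        dev = relative_descriptor_deviation(out)
        if dev > 1e-9:
            import warnings

            warnings.warn(
                f"relative descriptors deviate from API minus solvent by up "
                f"to {dev:.3g}; check the source table"
            )

    return ModelingTable(
        df=out,
        feature_names=schema.feature_names,
        target_name=schema.target,
        provenance={
            "source": str(path),
            "schema_version": schema.version,
            "n_raw": int(len(df)),
            "rejections": rejections,
        },
    )


def split_train_test(table: ModelingTable, train_frac: float, seed: int) -> ModelingTable:
    """Assign train/test labels by a seeded random permutation.

    The train count is round-half-up of ``n·train_frac``; the split is a
    pure function of (n, train_frac, seed) and independent of column order.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if table.has_split:
        raise DegenerateInputError("table already has split labels")
    n = table.n
    if n < 2:
        raise DegenerateInputError(f"need at least 2 rows to split, got {n}")
    n_train = math.floor(n * train_frac + 0.5)
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:]] = "test"
    df = table.df.copy()
    df["split"] = labels
    prov = dict(table.provenance)
    prov.update({"split_seed": int(seed), "train_frac": float(train_frac)})
    return ModelingTable(
        df=df,
        feature_names=table.feature_names,
        target_name=table.target_name,
        standardized=table.standardized,
        provenance=prov,
    )


def standardize(
    train: np.ndarray,
    apply_to: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Zero-mean/unit-variance scaling fit on ``train`` only.

    Uses the population standard deviation (ddof=0).  Returns
    ``(train_std, apply_std, mean, sd)``; ``apply_to`` (e.g. the test set)
    is transformed with the train parameters only.  A zero-variance train
    column raises :class:`DegenerateInputError` naming the column.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = (
            [feature_names[i] for i in zero]
            if feature_names is not None
            else [f"column {i}" for i in zero]
        )
        raise DegenerateInputError(f"zero-variance train column(s): {names}")
    train_std = (train - mean) / sd
    apply_std = None
    if apply_to is not None:
        apply_std = (np.asarray(apply_to, dtype=float) - mean) / sd
    return train_std, apply_std, mean, sd
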