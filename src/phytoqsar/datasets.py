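"""Domain types and file IO for the QSAR / reactivity / binding-energy pipeline.

The central container is :class:`QsarDataset`: an ``n x m`` matrix of named
molecular descriptors (PaDEL-style column names) together with a pIC50
activity vector, where pIC50 is the negative base-10 logarithm of the molar
IC50. Models are plain multiple-linear-regression forms
``pIC50 = b0 + sum_j b_j * d_j`` stored with per-coefficient standard errors
and optional per-descriptor (center, scale) pairs so predictions on raw
descriptor values are reproducible.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DatasetValidationError",
    "Compound",
    "QsarDataset",
    "SplitResult",
    "GAConfig",
    "MlrModel",
    "ValidationReport",
    "AdReport",
    "ReactivityProfile",
    "EnergyComponents",
    "PostDynamicsRecord",
    "parse_spread",
    "read_qsar_csv",
    "write_model_json",
    "read_model_json",
]


class ConfigurationError(ValueError):
    """A caller supplied an inconsistent or missing configuration item."""


class DatasetValidationError(ValueError):
    """Input data violates a structural invariant (duplicate ids, NaNs, ...)."""


# U+2212 (minus sign) appears in typeset tables; normalize to ASCII hyphen-minus.
_MINUS = "−"
_SPREAD_RE = re.compile(r"^\s*([^\s±]+)\s*(?:±|\+/-)\s*([^\s]+)\s*$")


def parse_spread(cell: str | float) -> tuple[float, float | None]:
    """Parse a table cell of the form ``"a ± b"`` into ``(a, b)``.

    Plain numbers are returned with a ``None`` spread. Both the ASCII
    hyphen-minus and the typeset minus sign U+2212 are accepted.
    """
    if isinstance(cell, (int, float, np.floating, np.integer)):
        return float(cell), None
    text = str(cell).replace(_MINUS, "-").strip()
    m = _SPREAD_RE.match(text)
    if m:
        return float(m.group(1)), float(m.group(2))
    return float(text), None


@dataclass
class Compound:
    """A compound identity: unique label plus optional molar mass (g/mol)."""

    id: str
    mw: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise DatasetValidationError(f"compound {self.id!r}: mw must be > 0, got {self.mw}")


@dataclass
class QsarDataset:
    """Descriptor matrix + activity vector + compound ids.

    ``X`` has one row per compound (ordered as ``ids``) and one column per
    entry of ``descriptor_names``; ``y`` holds pIC50 values.
    """

    ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, m = self.X.shape
        if len(self.ids) != n:
            raise DatasetValidationError(f"{len(self.ids)} ids for {n} descriptor rows")
        if len(self.descriptor_names) != m:
            raise DatasetValidationError(
                f"{len(self.descriptor_names)} names for {m} descriptor columns"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate compound ids: {dupes}")
        if self.y.shape != (n,):
            raise DatasetValidationError("y must be one value per compound")
        if not np.all(np.isfinite(self.y)):
            raise DatasetValidationError("y contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=pd.Index(self.ids, name="id"), columns=self.descriptor_names)
        df["pIC50"] = self.y
        return df

    def select_rows(self, ids: Sequence[str]) -> "QsarDataset":
        index = {c: i for i, c in enumerate(self.ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise DatasetValidationError(f"unknown compound ids: {missing}")
        rows = [index[c] for c in ids]
        return QsarDataset(list(ids), list(self.descriptor_names), self.X[rows], self.y[rows])

    def select_columns(self, names: Sequence[str]) -> "QsarDataset":
        index = {d: j for j, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in index]
        if missing:
            raise DatasetValidationError(f"unknown descriptors: {missing}")
        cols = [index[d] for d in names]
        return QsarDataset(list(self.ids), list(names), self.X[:, cols], self.y.copy())

    def descriptor_matrix(self, names: Sequence[str]) -> np.ndarray:
        index = {d: j for j, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in index]
        if missing:
            raise DatasetValidationError(f"unknown descriptors: {missing}")
        return self.X[:, [index[d] for d in names]]


@dataclass
class SplitResult:
    """A disjoint train/test partition of compound ids."""

    train_ids: list[str]
    test_ids: list[str]
    method: str = "kennard_stone"

    def __post_init__(self) -> None:
        if not self.train_ids or not self.test_ids:
            raise DatasetValidationError("train and test sets must both be nonempty")
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise DatasetValidationError(f"train/test overlap: {sorted(overlap)}")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset selection.

    Defaults follow the study conditions: 1000 generations, equation length 8,
    crossover probability 1, mutation probability 0.5, 100 initial equations,
    3 survivors per generation.
    """

    generations: int = 1000
    equation_length: int = 8
    crossover_prob: float = 1.0
    mutation_prob: float = 0.5
    population_init: int = 100
    survivors_per_generation: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.equation_length < 1:
            raise ConfigurationError("equation_length must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.survivors_per_generation < 1 or self.survivors_per_generation > self.population_init:
            raise ConfigurationError("survivors_per_generation must lie in [1, population_init]")


@dataclass
class MlrModel:
    """A fitted (or literature) multiple-linear-regression activity model."""

    intercept: float
    intercept_se: float
    descriptor_names: list[str]
    coefficients: np.ndarray
    coefficient_se: np.ndarray
    scaling: dict[str, tuple[float, float]] | None = None
    training: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.coefficient_se = np.asarray(self.coefficient_se, dtype=float)
        k = len(self.descriptor_names)
        if k == 0:
            raise DatasetValidationError("model must have at least one descriptor")
        if self.coefficients.shape != (k,) or self.coefficient_se.shape != (k,):
            raise DatasetValidationError("coefficient arrays must match descriptor_names")
        if self.scaling is not None:
            missing = [d for d in self.descriptor_names if d not in self.scaling]
            if missing:
                raise DatasetValidationError(
                    f"scaling present but does not cover descriptors: {missing}"
                )

    @property
    def p(self) -> int:
        """Number of model terms including the intercept."""
        return len(self.descriptor_names) + 1

    def design(self, X: np.ndarray) -> np.ndarray:
        """Apply stored (center, scale) pairs to a raw descriptor matrix."""
        X = np.asarray(X, dtype=float)
        if self.scaling is None:
            return X
        centers = np.array([self.scaling[d][0] for d in self.descriptor_names])
        scales = np.array([self.scaling[d][1] for d in self.descriptor_names])
        return (X - centers) / scales

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + self.design(X) @ self.coefficients

    def predict_dataset(self, dataset: QsarDataset) -> np.ndarray:
        return self.predict_matrix(dataset.descriptor_matrix(self.descriptor_names))


@dataclass
class ValidationReport:
    """Internal + external validation metrics of an MLR activity model."""

    # internal
    r2: float | None = None
    r2_adj: float | None = None
    see: float | None = None
    press: float | None = None
    q2_loo: float | None = None
    avg_rm2_loo: float | None = None
    delta_rm2_loo: float | None = None
    # external
    r2_ext: float | None = None
    r0_2: float | None = None
    r0_prime_2: float | None = None
    k: float | None = None
    k_prime: float | None = None
    q2_f1: float | None = None
    q2_f2: float | None = None
    rmsep: float | None = None
    avg_rm2_test: float | None = None
    delta_rm2_test: float | None = None
    mae_95: float | None = None
    sd_95: float | None = None
    mae_verdict: str | None = None
    unreliable: bool = False
    gt_checks: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AdReport:
    """Applicability-domain summary: leverages, residuals, in-domain flags."""

    table: pd.DataFrame  # columns: id, leverage, std_residual, set, in_domain
    h_star: float
    residual_limit: float = 3.0

    def write_williams_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ReactivityProfile:
    """Global reactivity descriptors (eV) from frontier orbital energies."""

    homo: float
    lumo: float
    delta_e: float
    ip: float
    ea: float
    chi: float
    eta: float
    xi: float
    mu: float
    omega: float
    flags: list[str] = field(default_factory=list)


@dataclass
class EnergyComponents:
    """MM-GBSA energy terms (kcal/mol) for one protein-ligand complex."""

    complex_id: str
    e_vdw: float
    e_elec: float
    e_gb: float
    e_surf: float
    g_gas: float
    g_solv: float
    g_bind: float
    spreads: dict[str, float | None] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class PostDynamicsRecord:
    """Trajectory-averaged structural descriptors for one complex."""

    complex_id: str
    rmsd: float
    rog: float
    rmsf: float
    sasa: float
    n_hbond: float
    spreads: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rmsd", "rog", "rmsf", "sasa", "n_hbond"):
            if getattr(self, name) < 0:
                raise DatasetValidationError(f"{self.complex_id}: {name} must be >= 0")


def read_qsar_csv(
    path: str | Path,
    activity_column: str,
    id_column: str | None = None,
) -> QsarDataset:
    """Read a descriptor CSV (header row, one id column, numeric descriptors).

    ``id_column`` defaults to the first column. Column order is preserved.
    Rows with unparseable numerics are reported in the raised error.
    """
    df = pd.read_csv(path)
    if id_column is None:
        id_column = df.columns[0]
    if activity_column not in df.columns:
        raise ConfigurationError(
            f"activity column {activity_column!r} not found; columns: {list(df.columns)}"
        )
    if id_column not in df.columns:
        raise ConfigurationError(f"id column {id_column!r} not found")
    ids = df[id_column].astype(str).tolist()
    descriptor_names = [c for c in df.columns if c not in (id_column, activity_column)]
    numeric = df[descriptor_names + [activity_column]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[descriptor_names + [activity_column]].notna()
    if bad.any().any():
        rows = [ids[i] for i in np.where(bad.any(axis=1))[0]]
        raise DatasetValidationError(f"unparseable numeric values in rows: {rows}")
    if numeric.isna().any().any():
        rows = [ids[i] for i in np.where(numeric.isna().any(axis=1))[0]]
        raise DatasetValidationError(f"missing values in rows: {rows}")
    return QsarDataset(
        ids=ids,
        descriptor_names=descriptor_names,
        X=numeric[descriptor_names].to_numpy(float),
        y=numeric[activity_column].to_numpy(float),
    )


def write_model_json(model: MlrModel, path: str | Path) -> None:
    """Serialize a model to JSON (keys: intercept, intercept_se, coefficients,
    scaling, training)."""
    payload = {
        "intercept": model.intercept,
        "intercept_se": model.intercept_se,
        "coefficients": [
            {"name": d, "value": float(v), "se": float(s)}
            for d, v, s in zip(model.descriptor_names, model.coefficients, model.coefficient_se)
        ],
        "scaling": (
            None
            if model.scaling is None
            else {d: list(cs) for d, cs in model.scaling.items()}
        ),
        "training": model.training,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model_json(path: str | Path) -> MlrModel:
    """Read a model written by :func:`write_model_json` (round-trip identity)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ConfigurationError(f"malformed model file {path}: {err}") from err
    for key in ("intercept", "intercept_se", "coefficients"):
        if key not in payload:
            raise ConfigurationError(f"model file {path} missing key {key!r}")
    coeffs = payload["coefficients"]
    if not coeffs:
        raise DatasetValidationError("model must have at least one descriptor")
    scaling = payload.get("scaling")
    return MlrModel(
        intercept=float(payload["intercept"]),
        intercept_se=float(payload["intercept_se"]),
        descriptor_names=[c["name"] for c in coeffs],
        coefficients=np.array([c["value"] for c in coeffs], dtype=float),
        coefficient_se=np.array([c["se"] for c in coeffs], dtype=float),
        scaling=None if scaling is None else {d: (float(c), float(s)) for d, (c, s) in scaling.items()},
        training={k: v for k, v in payload.get("training", {}).items()},
    )
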