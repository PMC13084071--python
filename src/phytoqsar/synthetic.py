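"""Synthetic inputs with the statistical structure the pipeline assumes.

The study's ChEMBL-derived training matrices are not deposited, so every
modeling stage is exercised on generated data instead: a descriptor matrix
with a sparse planted linear pIC50 signal plus collinear and pure-noise
columns, log-logistic percentage-inhibition curves with known IC50, and
MM-GBSA component tables that satisfy the thermodynamic cycle by
construction. All generators are pure functions of (spec, seed).

Descriptor columns are drawn standard normal: the real PaDEL descriptor
families have wildly heterogeneous scales, but keeping the generator on a
common scale keeps the oracle checks (exact coefficient recovery at zero
noise) simple. An optional per-column scale multiplier restores scale
heterogeneity when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, EnergyComponents, QsarDataset

__all__ = ["SyntheticQsarSpec", "gen_qsar_dataset", "gen_dose_response", "gen_energy_table"]

# keeps generated pIC50 in a realistic 4-9 range for coefficient magnitudes ~1
DEFAULT_INTERCEPT = 6.0


@dataclass
class SyntheticQsarSpec:
    """Recipe for a descriptor matrix with a planted sparse linear signal."""

    n_compounds: int = 330
    m_descriptors: int = 564
    k_informative: int = 8
    true_coefficients: tuple[float, ...] = (1.5, -2.0, 1.0, 0.8, -1.2, 2.5, -0.7, 1.1)
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = 0.2
    collinearity_rho: float = 0.0
    n_redundant: int = 0
    column_scales: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.m_descriptors:
            raise ConfigurationError("k_informative cannot exceed m_descriptors")
        if len(self.true_coefficients) != self.k_informative:
            raise ConfigurationError(
                f"need {self.k_informative} true coefficients, got {len(self.true_coefficients)}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not abs(self.collinearity_rho) < 1:
            raise ConfigurationError("|collinearity_rho| must be < 1")
        if self.n_redundant > self.m_descriptors - self.k_informative:
            raise ConfigurationError("n_redundant exceeds available non-informative columns")


def gen_qsar_dataset(spec: SyntheticQsarSpec) -> tuple[QsarDataset, dict]:
    """Generate a dataset and its ground-truth record.

    The matrix has ``m_descriptors`` standard-normal columns; ``k_informative``
    of them (chosen by the seeded RNG) carry the linear signal
    ``y = intercept + X_inf @ beta + N(0, noise_sd)``. ``n_redundant``
    non-informative columns are overwritten with rho-correlated noisy copies
    of informative columns. Fixed seed implies bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, k = spec.n_compounds, spec.m_descriptors, spec.k_informative
    X = rng.standard_normal((n, m))
    informative = np.sort(rng.choice(m, size=k, replace=False))
    others = np.setdiff1d(np.arange(m), informative)
    redundant = np.sort(rng.choice(others, size=spec.n_redundant, replace=False))
    redundant_of = {}
    rho = spec.collinearity_rho
    for j in redundant:
        src = int(rng.choice(informative))
        X[:, j] = rho * X[:, src] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        redundant_of[f"D{j + 1:04d}"] = f"D{src + 1:04d}"
    beta = np.asarray(spec.true_coefficients, dtype=float)
    y = spec.intercept + X[:, informative] @ beta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.column_scales is not None:
        scales = np.asarray(spec.column_scales, dtype=float)
        if scales.shape != (m,):
            raise ConfigurationError("column_scales must have one entry per descriptor")
        X = X * scales
    names = [f"D{j + 1:04d}" for j in range(m)]
    dataset = QsarDataset(
        ids=[f"C{i + 1:04d}" for i in range(n)],
        descriptor_names=names,
        X=X,
        y=y,
    )
    truth = {
        "informative": [names[j] for j in informative],
        "coefficients": dict(zip((names[j] for j in informative), beta)),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "redundant_of": redundant_of,
    }
    return dataset, truth


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: tuple[float, ...] = (10, 25, 50, 75, 100, 125, 150, 200),
    noise_sd: float = 2.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate percentage-inhibition measurements.

    Mean response follows the log-logistic form
    ``bottom + (top - bottom) / (1 + (ic50 / c) ** hill)`` with independent
    Gaussian replicate noise (percentage points). Returns a long-format frame
    with columns concentration, replicate, inhibition.
    """
    if ic50 <= 0:
        raise ConfigurationError("ic50 must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    mean = bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)
    records = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
        values = mean + noise
        for c, v in zip(conc, values):
            records.append({"concentration": c, "replicate": rep + 1, "inhibition": v})
    return pd.DataFrame.from_records(records)


def gen_energy_table(
    n_complexes: int,
    component_sd: float = 20.0,
    seed: int = 0,
) -> list[EnergyComponents]:
    """Random MM-GBSA component tables obeying the thermodynamic cycle exactly.

    The four elementary terms (van der Waals, electrostatic, polar solvation,
    nonpolar surface) are drawn around magnitudes typical of the study's
    complexes; the aggregate columns are computed as exact sums, so every row
    passes cycle validation at zero tolerance by construction.
    """
    if n_complexes < 1:
        raise ConfigurationError("n_complexes must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_complexes):
        e_vdw = rng.normal(-30.0, component_sd / 2.0)
        e_elec = rng.normal(-60.0, component_sd)
        e_gb = rng.normal(60.0, component_sd)
        e_surf = -abs(rng.normal(4.0, component_sd / 10.0))
        g_gas = e_vdw + e_elec
        g_solv = e_gb + e_surf
        rows.append(
            EnergyComponents(
                complex_id=f"complex-{i + 1}",
                e_vdw=e_vdw,
                e_elec=e_elec,
                e_gb=e_gb,
                e_surf=e_surf,
                g_gas=g_gas,
                g_solv=g_solv,
                g_bind=g_gas + g_solv,
            )
        )
    return rows
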