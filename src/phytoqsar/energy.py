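"""MM-GBSA bookkeeping: thermodynamic-cycle validation, component
aggregation, per-residue contribution ranking, and correlation of binding
energies with post-dynamics structural descriptors.

The end-state binding free energy decomposes as
``dG_bind = dG_gas + dG_solv`` with ``dG_gas = dE_vdw + dE_elec`` and
``dG_solv = dE_GB + dE_surf`` (polar continuum + nonpolar surface terms).
This module never computes energies from trajectories; it audits and
aggregates tables produced by an MM-GBSA engine. Configurational-entropy
terms are out of scope, matching the upstream tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, DatasetValidationError, EnergyComponents
from .reactivity import correlation_matrix

__all__ = [
    "CycleCheck",
    "validate_thermo_cycle",
    "aggregate_components",
    "rank_residue_contributions",
    "correlate_post_dynamics",
]

# half a unit in the last digit on each of three 2-decimal operands
DEFAULT_TOLERANCE = 0.02


@dataclass
class CycleCheck:
    """Result of auditing one complex against the thermodynamic cycle."""

    complex_id: str
    residual_gas: float
    residual_solv: float
    residual_bind: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return all(
            abs(r) <= self.tolerance
            for r in (self.residual_gas, self.residual_solv, self.residual_bind)
        )


def validate_thermo_cycle(
    row: EnergyComponents,
    tolerance: float = DEFAULT_TOLERANCE,
) -> CycleCheck:
    """Check the three cycle identities for one complex.

    ``g_gas = e_vdw + e_elec``, ``g_solv = e_gb + e_surf`` and
    ``g_bind = g_gas + g_solv``, each within ``tolerance`` (kcal/mol). The
    default suits tables printed to two decimals; machine-precision inputs
    warrant something like 1e-9.
    """
    for f in ("e_vdw", "e_elec", "e_gb", "e_surf", "g_gas", "g_solv", "g_bind"):
        value = getattr(row, f, None)
        if value is None or not np.isfinite(value):
            raise DatasetValidationError(f"{row.complex_id}: component {f} missing or non-finite")
    return CycleCheck(
        complex_id=row.complex_id,
        residual_gas=row.g_gas - (row.e_vdw + row.e_elec),
        residual_solv=row.g_solv - (row.e_gb + row.e_surf),
        residual_bind=row.g_bind - (row.g_gas + row.g_solv),
        tolerance=tolerance,
    )


def aggregate_components(
    e_vdw: float, e_elec: float, e_gb: float, e_surf: float
) -> tuple[float, float, float]:
    """Exact aggregate terms ``(g_gas, g_solv, g_bind)`` from the four
    elementary components."""
    g_gas = e_vdw + e_elec
    g_solv = e_gb + e_surf
    return g_gas, g_solv, g_gas + g_solv


_RESNUM = re.compile(r"(\d+)")


def _residue_number(residue_id: str) -> int:
    m = _RESNUM.search(str(residue_id))
    return int(m.group(1)) if m else 0


def rank_residue_contributions(
    decomposition: Sequence[tuple[str, float]],
    top_k: int,
) -> list[tuple[str, float]]:
    """Rank per-residue energy contributions, most favorable first.

    Sorted ascending by energy (most negative = most stabilizing), ties
    broken by residue number. Returns at most ``top_k`` entries.
    """
    if top_k <= 0:
        raise ConfigurationError("top_k must be positive")
    if not decomposition:
        raise ConfigurationError("decomposition list is empty")
    ranked = sorted(decomposition, key=lambda item: (item[1], _residue_number(item[0])))
    return list(ranked[:top_k])


def correlate_post_dynamics(
    energies: Mapping[str, float],
    records: pd.DataFrame | Sequence,
) -> pd.Series:
    """Pearson correlation of binding free energy with each post-dynamics
    descriptor (RMSD, ROG, RMSF, SASA, H-bond count).

    ``energies`` maps complex id -> dG_bind; ``records`` is a DataFrame with
    a ``complex_id`` column (or a sequence of records with those attributes).
    Requires at least 3 matching complexes; unmatched ids raise, listing them.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [
                {
                    "complex_id": r.complex_id,
                    "rmsd": r.rmsd,
                    "rog": r.rog,
                    "rmsf": r.rmsf,
                    "sasa": r.sasa,
                    "n_hbond": r.n_hbond,
                }
                for r in records
            ]
        )
    records = records.set_index("complex_id") if "complex_id" in records.columns else records
    unmatched = sorted(set(energies) ^ set(records.index))
    if unmatched:
        raise DatasetValidationError(f"unmatched complex ids: {unmatched}")
    if len(energies) < 3:
        raise ConfigurationError(f"need at least 3 complexes, got {len(energies)}")
    df = records.loc[list(energies)].astype(float).copy()
    df.insert(0, "g_bind", [energies[c] for c in df.index])
    corr = correlation_matrix(df)
    return corr.loc["g_bind"].drop("g_bind")
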