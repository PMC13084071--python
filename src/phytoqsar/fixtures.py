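"""Packaged reference tables from the dual PTP1B/DPP4 inhibitor study.

Five tables travel with the package as plain CSV, exactly as printed
(ASCII-normalized minus signs, no thousands separators):

* ``table2`` -- MM-GBSA energy components per complex (kcal/mol)
* ``table3`` -- post-dynamics trajectory summaries (RMSD, ROG, RMSF, SASA,
  H-bond counts) plus the printed correlation blocks
* ``table4`` -- frontier-orbital reactivity descriptors (eV) with binding
  free energies, plus the printed merged correlation matrix
* ``table7`` -- the full validation-metric table for both QSAR models
* ``table8`` -- model descriptors and predicted IC50 values for the leads

Rows whose printed values are internally inconsistent (arithmetic that does
not close at printed precision) are loaded verbatim and flagged, never
silently corrected: the tables are the record of what was printed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    EnergyComponents,
    MlrModel,
    PostDynamicsRecord,
    parse_spread,
)

__all__ = [
    "load_fixture",
    "model_ptp1b",
    "model_dpp4",
    "FIXTURE_NAMES",
]

_FILES = {
    "table2": "table2_mmgbsa.csv",
    "table3": "table3_postdynamics.csv",
    "table3_correlations": "table3_correlations.csv",
    "table4": "table4_reactivity.csv",
    "table4_correlations": "table4_correlations.csv",
    "table7": "table7_validation.csv",
    "table8": "table8_predictions.csv",
}
FIXTURE_NAMES = tuple(_FILES)

# tolerance for flagging printed-arithmetic inconsistencies: one unit in the
# last printed digit on either operand side, doubled for summed roundings
_PRINT_TOL = 0.02


def _fixture_path(filename: str) -> Path:
    return Path(resources.files("phytoqsar") / "data" / filename)


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(_fixture_path(_FILES[name]))


def _load_table2() -> list[EnergyComponents]:
    rows = []
    fields = ("e_vdw", "e_elec", "e_gb", "e_surf", "g_gas", "g_solv", "g_bind")
    for _, row in _read("table2").iterrows():
        values, spreads = {}, {}
        for f in fields:
            values[f], spreads[f] = parse_spread(row[f])
        rec = EnergyComponents(complex_id=row["complex_id"], spreads=spreads, **values)
        residuals = (
            rec.g_gas - (rec.e_vdw + rec.e_elec),
            rec.g_solv - (rec.e_gb + rec.e_surf),
            rec.g_bind - (rec.g_gas + rec.g_solv),
        )
        for label, res in zip(("g_gas", "g_solv", "g_bind"), residuals):
            if abs(res) > _PRINT_TOL:
                rec.flags.append(f"printed_inconsistency:{label}:{res:+.2f}")
        rows.append(rec)
    return rows


def _load_table3() -> list[PostDynamicsRecord]:
    rows = []
    fields = ("rmsd", "rog", "rmsf", "sasa", "n_hbond")
    for _, row in _read("table3").iterrows():
        values, spreads = {}, {}
        for f in fields:
            values[f], spreads[f] = parse_spread(row[f])
        rows.append(PostDynamicsRecord(complex_id=row["complex_id"], spreads=spreads, **values))
    return rows


def _load_table4() -> pd.DataFrame:
    df = _read("table4")
    flags = []
    for _, row in df.iterrows():
        bad = []
        ip, ea = -row["homo"], -row["lumo"]
        eta, chi = (ip - ea) / 2.0, (ip + ea) / 2.0
        expected = {
            "delta_e": row["lumo"] - row["homo"],
            "ip": ip,
            "ea": ea,
            "eta": eta,
            "chi": chi,
            "mu": -chi,
            "xi": 1.0 / eta,
            "omega": chi**2 / (2.0 * eta),
        }
        for name, value in expected.items():
            if abs(row[name] - value) > _PRINT_TOL:
                bad.append(name)
        flags.append(",".join(bad))
    df["inconsistent_fields"] = flags
    return df


def load_fixture(name: str):
    """Return a packaged study table by short name.

    ``table2`` -> list of :class:`EnergyComponents`; ``table3`` -> list of
    :class:`PostDynamicsRecord`; everything else -> a :class:`pandas.DataFrame`
    holding exactly the printed values. Unknown names raise ``KeyError``
    listing the available fixtures.
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}")
    if name == "table2":
        return _load_table2()
    if name == "table3":
        return _load_table3()
    if name == "table4":
        return _load_table4()
    return _read(name)


def model_ptp1b() -> MlrModel:
    """The published 8-descriptor PTP1B activity model (coefficients ± SE).

    The printed coefficients apply to descriptor values on an undisclosed
    scale; applied to raw descriptor values they do not reproduce the
    published predictions (see the package methods note). The model is
    packaged for bookkeeping, serialization and unit-conversion work.
    """
    names = ["R_TpiPCTPC", "nRing", "ATSC4m", "GATS3p", "fragC", "MATS7e", "MAXDP", "AATS3e"]
    coef = [0.927, -2.007, 0.743, -0.767, 3.407, -0.267, -1.308, -0.756]
    se = [0.070, 0.177, 0.146, 0.086, 0.188, 0.105, 0.118, 0.089]
    return MlrModel(
        intercept=6.697,
        intercept_se=0.111,
        descriptor_names=names,
        coefficients=np.array(coef),
        coefficient_se=np.array(se),
        training={"n": 330, "y_min": 4.0, "y_max": 9.0},
    )


def model_dpp4() -> MlrModel:
    """The published 8-descriptor DPP4 activity model (coefficients ± SE)."""
    names = ["SIC0", "GATS7m", "SpMax1_Bhv", "JGT", "apol", "SpMin2_Bhv", "ATSC6p", "AATSC8p"]
    coef = [-2.521, 2.015, 6.098, 3.804, 0.044, -9.424, 0.119, 10.345]
    se = [0.952, 0.174, 0.256, 0.428, 0.003, 0.382, 0.010, 0.592]
    return MlrModel(
        intercept=-5.494,
        intercept_se=0.816,
        descriptor_names=names,
        coefficients=np.array(coef),
        coefficient_se=np.array(se),
        training={"n": 91, "y_min": 4.0, "y_max": 9.0},
    )
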