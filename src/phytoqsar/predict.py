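"""Model application and activity unit conversions.

pIC50 is the negative base-10 logarithm of the molar IC50, so
``IC50 [mol/dm^3] = 10**(-pIC50)`` and the mass concentration follows as
``IC50 [ug/ml] = IC50 [mol/L] * MW [g/mol] * 1000``.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, MlrModel

__all__ = [
    "apply_model",
    "pic50_to_molar",
    "molar_to_pic50",
    "molar_to_mass_conc",
    "prediction_table",
    "round_sig",
]


def apply_model(model: MlrModel, descriptors: Mapping[str, float]) -> float:
    """Predict pIC50 for one compound from a name -> value descriptor map.

    Stored scaling is applied before the linear form. Missing model
    descriptors raise; extra descriptors are ignored with a warning.
    """
    missing = [d for d in model.descriptor_names if d not in descriptors]
    if missing:
        raise ConfigurationError(f"missing model descriptors: {missing}")
    extra = sorted(set(descriptors) - set(model.descriptor_names))
    if extra:
        warnings.warn(f"ignoring descriptors not in the model: {extra}", stacklevel=2)
    x = np.array([[float(descriptors[d]) for d in model.descriptor_names]])
    return float(model.predict_matrix(x)[0])


def pic50_to_molar(pic50: float) -> float:
    """IC50 in mol/dm^3 from pIC50: ``10**(-pIC50)``."""
    if not math.isfinite(pic50):
        raise ConfigurationError("pIC50 must be finite")
    return 10.0 ** (-pic50)


def molar_to_pic50(ic50_molar: float) -> float:
    """Inverse of :func:`pic50_to_molar`."""
    if ic50_molar <= 0:
        raise ConfigurationError("molar IC50 must be positive")
    return -math.log10(ic50_molar)


def molar_to_mass_conc(ic50_molar: float, mw: float) -> float:
    """Convert a molar IC50 to ug/ml given the molar mass (g/mol).

    mol/L x g/mol = g/L, and 1 g/L = 1000 ug/ml; linear in both arguments.
    """
    if mw <= 0:
        raise ConfigurationError(f"molar mass must be positive, got {mw}")
    return ic50_molar * mw * 1000.0


def round_sig(x: float, digits: int = 3) -> float:
    """Round to a number of significant figures (half away from zero is not
    forced; IEEE round-half-even as printed tables typically use)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


def prediction_table(
    model: MlrModel,
    compounds: pd.DataFrame,
    mw_column: str = "mw",
    rounding: str | None = None,
) -> pd.DataFrame:
    """Predict pIC50 for a table of compounds and attach unit conversions.

    ``compounds`` must carry one column per model descriptor plus an optional
    molar-mass column; the index labels the compounds. Output columns:
    pic50_pred, ic50_molar, ic50_ug_ml (NaN when MW is absent), and an
    ``extrapolated`` flag for predictions outside the model's training
    activity range. ``rounding="printed"`` mimics the reporting style of the
    source tables: molar to 3 significant figures, mass to 2 decimals.
    """
    rows = []
    y_min = model.training.get("y_min") if model.training else None
    y_max = model.training.get("y_max") if model.training else None
    for label, row in compounds.iterrows():
        pic50 = apply_model(model, {d: row[d] for d in model.descriptor_names})
        molar = pic50_to_molar(pic50)
        mw = row.get(mw_column) if mw_column in compounds.columns else None
        mass = molar_to_mass_conc(molar, float(mw)) if mw is not None and pd.notna(mw) else np.nan
        extrapolated = (
            y_min is not None and y_max is not None and not (y_min <= pic50 <= y_max)
        )
        if rounding == "printed":
            molar = round_sig(molar, 3)
            mass = round(mass, 2) if not np.isnan(mass) else mass
        rows.append(
            {
                "compound": label,
                "pic50_pred": pic50,
                "ic50_molar": molar,
                "ic50_ug_ml": mass,
                "extrapolated": bool(extrapolated),
            }
        )
    return pd.DataFrame(rows).set_index("compound") if rows else pd.DataFrame(
        columns=["pic50_pred", "ic50_molar", "ic50_ug_ml", "extrapolated"]
    )
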