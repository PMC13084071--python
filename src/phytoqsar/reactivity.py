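"""Conceptual-DFT global reactivity descriptors and correlation analysis.

From frontier orbital energies (eV) the standard global indices follow:
energy gap dE = E_LUMO - E_HOMO, ionization potential IP = -E_HOMO, electron
affinity EA = -E_LUMO, electronegativity chi = (IP + EA)/2, chemical
hardness eta = (IP - EA)/2, chemical potential mu = -chi, softness xi, and
the electrophilicity index omega = mu^2 / (2 eta).

Two softness conventions circulate in the literature: xi = 1/eta and
xi = 1/(2 eta). The default here is ``inverse_eta`` because that is the
convention the source study's printed values follow (eta = 2.07 eV pairs
with xi = 0.48 eV^-1 = 1/2.07); the literal 1/(2 eta) form is selectable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, ReactivityProfile

__all__ = ["reactivity_profile", "profile_table", "correlation_matrix", "merge_triangles"]

_CONVENTIONS = ("inverse_eta", "inverse_2eta")


def reactivity_profile(
    homo: float,
    lumo: float,
    softness_convention: str = "inverse_eta",
) -> ReactivityProfile:
    """Compute the eight global reactivity descriptors from HOMO/LUMO (eV).

    ``homo >= lumo`` (non-positive hardness) is physically irregular; the
    profile is still computed but flagged. Zero hardness leaves softness and
    electrophilicity undefined (NaN, flagged).
    """
    if softness_convention not in _CONVENTIONS:
        raise ConfigurationError(
            f"unknown softness convention {softness_convention!r}; choose from {_CONVENTIONS}"
        )
    flags: list[str] = []
    delta_e = lumo - homo
    ip = -homo
    ea = -lumo
    eta = (ip - ea) / 2.0
    chi = (ip + ea) / 2.0
    mu = -chi
    if homo >= lumo:
        flags.append("non_positive_gap")
    if eta == 0.0:
        flags.append("undefined_softness_and_electrophilicity")
        xi = math.nan
        omega = math.nan
    else:
        xi = 1.0 / eta if softness_convention == "inverse_eta" else 1.0 / (2.0 * eta)
        omega = mu**2 / (2.0 * eta)
    return ReactivityProfile(
        homo=homo, lumo=lumo, delta_e=delta_e, ip=ip, ea=ea,
        chi=chi, eta=eta, xi=xi, mu=mu, omega=omega, flags=flags,
    )


def profile_table(
    orbitals: pd.DataFrame,
    homo_column: str = "homo",
    lumo_column: str = "lumo",
    softness_convention: str = "inverse_eta",
) -> pd.DataFrame:
    """Vectorized :func:`reactivity_profile` over a table of orbital energies."""
    for col in (homo_column, lumo_column):
        if col not in orbitals.columns:
            raise ConfigurationError(f"column {col!r} not found")
    records = []
    for label, row in orbitals.iterrows():
        prof = reactivity_profile(
            float(row[homo_column]), float(row[lumo_column]), softness_convention
        )
        rec = {k: getattr(prof, k) for k in
               ("homo", "lumo", "delta_e", "ip", "ea", "chi", "eta", "xi", "mu", "omega")}
        rec["flags"] = ";".join(prof.flags)
        records.append(rec)
    return pd.DataFrame(records, index=orbitals.index)


def correlation_matrix(
    columns: pd.DataFrame,
    min_rows: int = 3,
    report_precision: int | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of named numeric columns.

    Symmetric with unit diagonal; correlations involving a zero-variance
    column are NaN (degenerate, not an error). ``report_precision`` rounds a
    COPY for display; full precision is what callers should compute with.
    """
    df = columns.astype(float)
    if len(df) < min_rows:
        raise ConfigurationError(f"need at least {min_rows} complete rows, got {len(df)}")
    corr = df.corr(method="pearson", min_periods=min_rows)
    np.fill_diagonal(corr.values, 1.0)
    if report_precision is not None:
        corr = corr.round(report_precision)
    return corr


def merge_triangles(lower: pd.DataFrame, upper: pd.DataFrame) -> pd.DataFrame:
    """Merge two full correlation matrices into one report-style matrix with
    one dataset below the diagonal and the other above it."""
    if list(lower.columns) != list(upper.columns):
        raise ConfigurationError("matrices must share the same variables")
    merged = lower.copy()
    iu = np.triu_indices(len(merged), k=1)
    merged.values[iu] = upper.values[iu]
    np.fill_diagonal(merged.values, 1.0)
    return merged
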