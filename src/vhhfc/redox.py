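"""Disulfide reduction potentials and reduction-propensity classification.

The calculated reduction potential of a disulfide comes from the Nernst
relation E = -dG / (n F) with the free-energy difference dG between reduced
and oxidized states (kJ/mol), n electrons transferred (2 for a disulfide),
and the Faraday constant; the empirical correction

    E_corr = 1.5 * E_cal - 43   (mV)

maps the calculated value onto the experimental scale.  Classification
follows the reduction-propensity bands: a corrected potential below -330 mV
stabilizes the fold, while potentials in the -330 to -89 mV band mark a
disulfide prone to enzymatic reduction (values above -89 mV are flagged as
highly labile on top of that).

Because the upstream free-energy protocol is not exactly recoverable from
dG alone, E_cal may be supplied directly and the Nernst step bypassed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import pandas as pd

__all__ = [
    "FARADAY_KJ_PER_MOL_V",
    "RedoxRecord",
    "nernst_potential",
    "corrected_potential",
    "classify_redox",
    "redox_table",
    "STABILIZING",
    "REDUCTION_PRONE",
]

FARADAY_KJ_PER_MOL_V = 96.485

STABILIZING = "stabilizing"
REDUCTION_PRONE = "reduction-prone"

STABLE_BELOW_MV = -330.0
LABILE_ABOVE_MV = -89.0


def nernst_potential(dG_kJ_mol: float, n: int = 2) -> float:
    """Reduction potential in mV from dG (kJ/mol): E = -dG / (n F)."""
    if n <= 0:
        raise ValueError("n (electrons transferred) must be >= 1")
    volts = -dG_kJ_mol / (n * FARADAY_KJ_PER_MOL_V)
    return volts * 1000.0


def corrected_potential(E_cal_mV: float) -> float:
    """Empirically corrected potential: E_corr = 1.5 * E_cal - 43 (mV)."""
    return 1.5 * E_cal_mV - 43.0


def classify_redox(E_corr_mV: float, stable_below: float = STABLE_BELOW_MV,
                   labile_above: float = LABILE_ABOVE_MV) -> str:
    """Reduction-propensity class from the corrected potential.

    The boundary value (exactly ``stable_below``) goes to the risk class.
    """
    return STABILIZING if E_corr_mV < stable_below else REDUCTION_PRONE


def is_highly_labile(E_corr_mV: float, labile_above: float = LABILE_ABOVE_MV) -> bool:
    return E_corr_mV > labile_above


@dataclasses.dataclass
class RedoxRecord:
    """One disulfide bond's energetics and classification."""

    bond: str                       # e.g. "C130-C130"
    dG_kJ_mol: float | None
    E_cal_mV: float
    E_corr_mV: float
    classification: str
    highly_labile: bool
    n_electrons: int = 2

    @property
    def reduction_prone(self) -> bool:
        return self.classification == REDUCTION_PRONE


def evaluate_bond(bond: str, dG_kJ_mol: float | None = None,
                  E_cal_mV: float | None = None, n: int = 2) -> RedoxRecord:
    """Full pipeline for one bond; E_cal (if given) overrides the Nernst step."""
    if E_cal_mV is None:
        if dG_kJ_mol is None:
            raise ValueError(f"bond {bond!r}: need dG_kJ_mol or E_cal_mV")
        E_cal_mV = nernst_potential(dG_kJ_mol, n)
    e_corr = corrected_potential(E_cal_mV)
    return RedoxRecord(
        bond=bond, dG_kJ_mol=dG_kJ_mol, E_cal_mV=float(E_cal_mV),
        E_corr_mV=e_corr, classification=classify_redox(e_corr),
        highly_labile=is_highly_labile(e_corr), n_electrons=n,
    )


def redox_table(table: pd.DataFrame, n: int = 2) -> pd.DataFrame:
    """Evaluate a bond table with columns ``bond_label`` and ``dG_kJ_mol``
    and/or ``E_cal_mV``; returns the table with E_corr and classification
    columns appended."""
    required = {"bond_label"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    records: list[RedoxRecord] = []
    for _, row in table.iterrows():
        records.append(evaluate_bond(
            str(row["bond_label"]),
            dG_kJ_mol=float(row["dG_kJ_mol"]) if "dG_kJ_mol" in table.columns
            and pd.notna(row.get("dG_kJ_mol")) else None,
            E_cal_mV=float(row["E_cal_mV"]) if "E_cal_mV" in table.columns
            and pd.notna(row.get("E_cal_mV")) else None,
            n=n,
        ))
    out = table.copy()
    out["E_cal_mV"] = [r.E_cal_mV for r in records]
    out["E_corr_mV"] = [r.E_corr_mV for r in records]
    out["classification"] = [r.classification for r in records]
    out["highly_labile"] = [r.highly_labile for r in records]
    return out


def reduction_prone_bonds(records: Iterable[RedoxRecord]) -> list[RedoxRecord]:
    return [r for r in records if r.reduction_prone]
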