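"""Unbound exposure, Emax target occupancy and toxicity separation analysis.

In vivo target inhibition is approximated by receptor occupancy under an
Emax model with competitive binding between a parent drug and one optional
active metabolite.  With r_p = C_u,parent / IC50,parent and
r_m = C_u,metabolite / IC50,metabolite,

    occupancy% = 100 * (r_p + r_m) / (1 + r_p + r_m)

so occupancy is 0% with no drug, 50% when the unbound parent concentration
equals its IC50 (no metabolite), and approaches the assumed 100% ceiling at
high exposure.  Setting the metabolite concentration to zero recovers the
single-species hyperbola 100 * r_p / (1 + r_p) exactly.

The separation analysis asks whether a single occupancy threshold divides
toxicity-positive from toxicity-negative studies: it does iff the largest
occupancy among negatives lies below the smallest among positives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "fraction_unbound",
    "unbound_concentration",
    "occupancy",
    "SeparationReport",
    "separation_analysis",
    "study_occupancies",
    "read_exposure_table",
]


def fraction_unbound(buffer_conc: float, plasma_conc: float) -> float:
    """Fraction unbound from an equilibrium-dialysis pair of concentrations.

    fu = C_buffer / C_plasma after matrix matching; values outside [0, 1]
    (possible with assay noise) are clipped with a warning.
    """
    if plasma_conc <= 0:
        raise ValueError("plasma concentration must be positive")
    if buffer_conc < 0:
        raise ValueError("buffer concentration must be non-negative")
    fu = buffer_conc / plasma_conc
    if fu > 1.0:
        warnings.warn(
            f"fraction unbound {fu:.3g} > 1 clipped to 1.0", stacklevel=2
        )
        fu = 1.0
    return fu


def unbound_concentration(c_total: float, fu: float) -> float:
    """Average unbound plasma concentration C_u = fu * C_total."""
    if c_total < 0:
        raise ValueError("total concentration must be non-negative")
    if not 0 <= fu <= 1:
        raise ValueError("fraction unbound must lie in [0, 1]")
    return fu * c_total


def occupancy(
    c_u_parent: float,
    ic50_parent: float,
    c_u_metabolite: float = 0.0,
    ic50_metabolite: float = math.inf,
) -> float:
    """Competitive Emax target occupancy in percent.

    Concentrations and IC50s must share a unit (occupancy is invariant to
    rescaling both by the same factor).  The metabolite term defaults to
    zero contribution (C = 0, IC50 = inf).
    """
    if c_u_parent < 0 or c_u_metabolite < 0:
        raise ValueError("concentrations must be non-negative")
    if not ic50_parent > 0:
        raise ValueError("parent IC50 must be positive")
    if not ic50_metabolite > 0:
        raise ValueError("metabolite IC50 must be positive")
    r_p = c_u_parent / ic50_parent
    r_m = c_u_metabolite / ic50_metabolite if math.isfinite(ic50_metabolite) else 0.0
    return 100.0 * (r_p + r_m) / (1.0 + r_p + r_m)


@dataclass(frozen=True)
class SeparationReport:
    """Whether one occupancy threshold separates positive from negative studies."""

    target_id: str
    separable: Optional[bool]
    max_negative_occupancy: Optional[float]
    min_positive_occupancy: Optional[float]
    threshold_interval: Optional[Tuple[float, float]]
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "separable": self.separable,
            "max_negative_occupancy": self.max_negative_occupancy,
            "min_positive_occupancy": self.min_positive_occupancy,
            "threshold_interval": list(self.threshold_interval)
            if self.threshold_interval
            else None,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def separation_analysis(
    occupancies: Sequence[float],
    outcomes: Sequence[str],
    target_id: str = "",
) -> SeparationReport:
    """Test for a clean occupancy threshold between outcome classes.

    ``outcomes`` entries are 'positive' or 'negative'.  With both classes
    present, separable is True iff max(negative) < min(positive), and the
    open interval between the two is every threshold that would separate.
    Single-class input yields separable=None with a warning.
    """
    occ = np.asarray(occupancies, dtype=float)
    out = np.asarray(outcomes, dtype=object)
    if occ.shape != out.shape:
        raise ValueError("occupancies and outcomes must have equal length")
    bad = set(out) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    pos = occ[out == "positive"]
    neg = occ[out == "negative"]
    if len(pos) == 0 or len(neg) == 0:
        warnings.warn(
            "separation undefined: need at least one positive and one "
            "negative study",
            stacklevel=2,
        )
        return SeparationReport(
            target_id=target_id,
            separable=None,
            max_negative_occupancy=float(neg.max()) if len(neg) else None,
            min_positive_occupancy=float(pos.min()) if len(pos) else None,
            threshold_interval=None,
            n_positive=len(pos),
            n_negative=len(neg),
        )
    max_neg = float(neg.max())
    min_pos = float(pos.min())
    separable = max_neg < min_pos
    return SeparationReport(
        target_id=target_id,
        separable=separable,
        max_negative_occupancy=max_neg,
        min_positive_occupancy=min_pos,
        threshold_interval=(max_neg, min_pos) if separable else None,
        n_positive=len(pos),
        n_negative=len(neg),
    )


def study_occupancies(
    records: pd.DataFrame,
    ic50_column: str = "ic50_parent_molar",
    metabolite_ic50_column: str = "ic50_metabolite_molar",
) -> pd.DataFrame:
    """Per-study occupancy from an exposure table.

    Expects columns ``study_id, c_total, fu, outcome`` plus the chosen IC50
    column; optional metabolite columns ``c_total_metabolite, fu_metabolite``
    and ``ic50_metabolite_molar`` add a competitive metabolite term.
    Returns the input with ``c_u`` and ``occupancy_percent`` appended.
    """
    df = records.copy()
    df["c_u"] = df["fu"].astype(float) * df["c_total"].astype(float)
    has_met = (
        "c_total_metabolite" in df.columns
        and metabolite_ic50_column in df.columns
    )
    occ = []
    for _, row in df.iterrows():
        c_u_m, ic50_m = 0.0, math.inf
        if has_met and pd.notna(row.get("c_total_metabolite")) and pd.notna(
            row.get(metabolite_ic50_column)
        ):
            fu_m = row.get("fu_metabolite", row["fu"])
            c_u_m = float(fu_m) * float(row["c_total_metabolite"])
            ic50_m = float(row[metabolite_ic50_column])
        occ.append(
            occupancy(float(row["c_u"]), float(row[ic50_column]), c_u_m, ic50_m)
        )
    df["occupancy_percent"] = occ
    return df


def read_exposure_table(path) -> pd.DataFrame:
    """Read the CSV exposure-record table written by the simulator or a user."""
    df = pd.read_csv(path)
    required = {"study_id", "compound_id", "c_total", "fu", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exposure table missing columns: {sorted(missing)}")
    return df
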