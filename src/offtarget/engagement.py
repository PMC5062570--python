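"""Probe-competition densitometry to IC50s, potency shifts and selectivity.

In-gel fluorescence competition assays read out target engagement as the
loss of probe-labelled band intensity with increasing competitor
concentration.  Band intensities are normalized between a no-inhibition
anchor (DMSO) and a full-block anchor (saturating control inhibitor) to
percent inhibition, then fitted with a four-parameter logistic (4PL) on
log10 concentration:

    inhibition% = bottom + (top - bottom) / (1 + 10^((log10 IC50 - log10 C) * hill))

Cell-free (purified enzyme) and live-cell IC50s for the same compound are
compared as a potency shift (enzyme/cell), and selectivity windows between
targets as ratios of cellular IC50s.  Censored potencies (">100 uM") are
carried through these ratios as :class:`~offtarget.bounds.Bound` objects.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bounds import Bound, PotencyValue, divide

logger = logging.getLogger(__name__)

__all__ = [
    "DensitometrySeries",
    "FourPLFit",
    "four_pl",
    "normalize_intensities",
    "fit_ic50",
    "potency_shift",
    "selectivity_window",
    "accumulation_report",
    "read_densitometry_table",
]


@dataclass
class DensitometrySeries:
    """One compound's band-intensity series in one assay context.

    ``concentrations`` are molar, ``intensities`` arbitrary optical-density
    units.  ``no_inhibition_intensity`` is the DMSO anchor and
    ``full_block_intensity`` the saturating-competitor anchor.  After
    :func:`normalize_intensities`, ``inhibition`` holds percent inhibition.
    """

    compound_id: str
    assay_context: str  # 'live_cell' or 'purified_enzyme'
    target_id: str
    concentrations: np.ndarray
    intensities: np.ndarray
    no_inhibition_intensity: float
    full_block_intensity: float
    replicate_id: str = "rep1"
    inhibition: Optional[np.ndarray] = None
    warnings_: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.shape != self.intensities.shape:
            raise ValueError("concentration/intensity arrays differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        order = np.argsort(self.concentrations, kind="stable")
        self.concentrations = self.concentrations[order]
        self.intensities = self.intensities[order]
        if self.inhibition is not None:
            self.inhibition = np.asarray(self.inhibition, dtype=float)[order]


def four_pl(
    conc: np.ndarray, log10_ic50: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    """Four-parameter logistic in percent-inhibition form."""
    logc = np.log10(np.asarray(conc, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ic50 - logc) * hill))


def normalize_intensities(series: DensitometrySeries) -> DensitometrySeries:
    """Anchor-normalize band intensities to percent inhibition.

    0% at the no-inhibition (DMSO) anchor, 100% at the full-block anchor;
    noisy values slightly outside [0, 100] are retained.  The result is
    invariant to any affine rescaling of all intensities (scanner gain).
    """
    span = series.no_inhibition_intensity - series.full_block_intensity
    if span == 0:
        raise ValueError(
            "degenerate anchors: no-inhibition and full-block intensities equal"
        )
    inhibition = (
        100.0 * (series.no_inhibition_intensity - series.intensities) / span
    )
    return replace(series, inhibition=inhibition)


@dataclass(frozen=True)
class FourPLFit:
    ic50: Optional[float]
    hill: Optional[float]
    top: Optional[float]
    bottom: Optional[float]
    rss: Optional[float]
    converged: bool
    ci95_ic50: Optional[Tuple[float, float]] = None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "ic50": self.ic50,
            "hill": self.hill,
            "top": self.top,
            "bottom": self.bottom,
            "rss": self.rss,
            "converged": self.converged,
            "ci95_ic50": list(self.ci95_ic50) if self.ci95_ic50 else None,
            "message": self.message,
        }


_FAILED = FourPLFit(None, None, None, None, None, False)


def fit_ic50(series: DensitometrySeries) -> FourPLFit:
    """Least-squares 4PL fit of a normalized series.

    Top and bottom are free within [-20, 120]%; the IC50 is fitted on the
    log10 scale with an asymptotic 95% confidence interval from the Jacobian.
    Degenerate inputs (flat response, optimizer failure) return
    ``converged=False`` instead of raising; fewer than four distinct
    concentrations is a usage error and raises.
    """
    if series.inhibition is None:
        series = normalize_intensities(series)
    conc = series.concentrations
    y = series.inhibition
    if np.unique(conc).size < 4:
        raise ValueError("IC50 fitting requires at least 4 distinct concentrations")
    if np.ptp(y) < 5.0:  # < 5 percentage points of dynamic range: no curve
        return replace(_FAILED, message="flat response; no dose dependence")

    logc = np.log10(conc)
    # midpoint guess: concentration where response crosses half its range
    half = (y.min() + y.max()) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    p0 = [logc[idx], 1.0, max(y.max(), 90.0), min(y.min(), 10.0)]
    lb = [logc.min() - 3.0, 0.05, -20.0, -20.0]
    ub = [logc.max() + 3.0, 10.0, 120.0, 120.0]
    p0 = np.clip(p0, lb, ub)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                four_pl, conc, y, p0=p0, bounds=(lb, ub), maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        return replace(_FAILED, message=f"optimizer failed: {exc}")
    log_ic50, hill, top, bottom = popt
    resid = y - four_pl(conc, *popt)
    rss = float(resid @ resid)
    ci: Optional[Tuple[float, float]] = None
    dof = len(y) - 4
    if dof > 0 and np.isfinite(pcov[0, 0]) and pcov[0, 0] >= 0:
        se = math.sqrt(pcov[0, 0])
        tcrit = stats.t.ppf(0.975, dof)
        ci = (10.0 ** (log_ic50 - tcrit * se), 10.0 ** (log_ic50 + tcrit * se))
    return FourPLFit(
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        converged=True,
        ci95_ic50=ci,
    )


def pool_replicates(replicates: Sequence[DensitometrySeries]) -> DensitometrySeries:
    """Pool normalized points from replicate series into one joint-fit series.

    Each replicate is anchor-normalized against its own anchors first, so
    scanner gain differences between gels cancel before pooling.
    """
    if not replicates:
        raise ValueError("no replicate series to pool")
    normed = [
        s if s.inhibition is not None else normalize_intensities(s)
        for s in replicates
    ]
    first = normed[0]
    return DensitometrySeries(
        compound_id=first.compound_id,
        assay_context=first.assay_context,
        target_id=first.target_id,
        replicate_id="pooled",
        concentrations=np.concatenate([s.concentrations for s in normed]),
        intensities=np.concatenate([s.intensities for s in normed]),
        no_inhibition_intensity=first.no_inhibition_intensity,
        full_block_intensity=first.full_block_intensity,
        inhibition=np.concatenate([s.inhibition for s in normed]),
    )


def potency_shift(
    enzyme_ic50: PotencyValue, cell_ic50: PotencyValue
) -> PotencyValue:
    """Fold disconnect between cell-free and cellular potency (enzyme/cell).

    A value > 1 means the compound is that many fold more potent in live
    cells than against the purified enzyme.  Censored inputs propagate as
    bounds (an enzyme potency of ">100 uM" gives a ">x-fold" shift).
    """
    return divide(enzyme_ic50, cell_ic50)


def selectivity_window(
    bace1_cell_ic50: PotencyValue, catd_cell_ic50: PotencyValue
) -> PotencyValue:
    """Cellular selectivity window for the on-target vs off-target.

    window = off-target IC50 / on-target IC50, so larger is safer.
    """
    return divide(catd_cell_ic50, bace1_cell_ic50)


def accumulation_report(
    levels: pd.DataFrame,
    control_id: str = "DMSO",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold-vs-control protein accumulation with per-concentration t-tests.

    ``levels`` has columns ``compound_id, concentration_molar, level`` with
    control wells under ``compound_id == control_id``.  For every compound x
    concentration group the fold over the control mean and a two-tailed
    two-sample t-test p-value are reported, plus the lowest concentration at
    which accumulation (fold > 1) first becomes significant.
    """
    required = {"compound_id", "concentration_molar", "level"}
    if missing := required - set(levels.columns):
        raise ValueError(f"levels table missing columns: {sorted(missing)}")
    control = levels.loc[levels["compound_id"] == control_id, "level"].to_numpy(
        dtype=float
    )
    if control.size == 0:
        raise ValueError(f"no control wells with compound_id == {control_id!r}")
    rows = []
    treated = levels[levels["compound_id"] != control_id]
    for (cmpd, conc), grp in treated.groupby(
        ["compound_id", "concentration_molar"], sort=True
    ):
        vals = grp["level"].to_numpy(dtype=float)
        fold = float(vals.mean() / control.mean())
        if vals.size > 1 and control.size > 1:
            _, p = stats.ttest_ind(vals, control, equal_var=True)
            p = float(p) if np.isfinite(p) else 1.0
        else:
            p = float("nan")
        rows.append(
            {
                "compound_id": cmpd,
                "concentration_molar": float(conc),
                "n": int(vals.size),
                "fold_vs_control": fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["first_significant"] = pd.Series(dtype=bool)
        return out
    out["significant"] = (out["p_value"] < alpha) & (out["fold_vs_control"] > 1)
    out["first_significant"] = False
    for cmpd, grp in out.groupby("compound_id"):
        sig = grp[grp["significant"]]
        if not sig.empty:
            out.loc[sig["concentration_molar"].idxmin(), "first_significant"] = True
    return out


def read_densitometry_table(path) -> List[DensitometrySeries]:
    """Read the CSV layout: one row per well, anchors tagged in ``anchor_role``.

    Columns: ``compound_id, assay_context, target_id, replicate_id,
    concentration_molar, intensity, anchor_role`` where anchor_role is blank
    for titration wells, 'no_inhibition' or 'full_block' for anchors.
    """
    df = pd.read_csv(path)
    series = []
    for (cmpd, ctx, tgt, rep), grp in df.groupby(
        ["compound_id", "assay_context", "target_id", "replicate_id"], sort=True
    ):
        roles = grp["anchor_role"].fillna("")
        anchors = grp[roles != ""]
        points = grp[roles == ""]
        try:
            no_inh = float(
                anchors.loc[roles == "no_inhibition", "intensity"].mean()
            )
            block = float(anchors.loc[roles == "full_block", "intensity"].mean())
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"missing anchor wells for {cmpd}: {exc}")
        if math.isnan(no_inh) or math.isnan(block):
            raise ValueError(f"missing anchor wells for series {cmpd}/{ctx}/{rep}")
        series.append(
            DensitometrySeries(
                compound_id=str(cmpd),
                assay_context=str(ctx),
                target_id=str(tgt),
                replicate_id=str(rep),
                concentrations=points["concentration_molar"].to_numpy(),
                intensities=points["intensity"].to_numpy(),
                no_inhibition_intensity=no_inh,
                full_block_intensity=block,
            )
        )
    return series
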