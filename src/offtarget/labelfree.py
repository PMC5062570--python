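"""Label-free differential protein abundance from spectral counts (PSM).

Peptide spectral matches per protein serve as a relative abundance proxy
between vehicle- and compound-treated tissue samples.  The stage applies
three QC steps before testing: low-confidence peptide removal (search-engine
ion score), contaminant protein removal (keratins, hemoglobins, histones and
a configurable pattern list), and rejection of samples whose spectral-count
profile has lost pairwise linearity with the rest of the run set.  Abundance
changes are then called with a per-protein two-sample t-test plus a
fold-change rule on proteins meeting detection/eligibility minimums.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PSMMatrix",
    "DEFAULT_CONTAMINANT_PATTERNS",
    "preprocess",
    "linearity_qc",
    "differential_abundance",
    "read_psm_table",
]

DEFAULT_CONTAMINANT_PATTERNS = ("keratin", "hemoglobin", "histone")

LONG_COLUMNS = [
    "protein_accession",
    "description",
    "sample_id",
    "condition",
    "subject_id",
    "tech_rep",
    "psm",
]


@dataclass
class PSMMatrix:
    """Protein x sample spectral-count matrix with sample metadata.

    ``counts`` is indexed by protein accession with one column per sample;
    ``samples`` is indexed by sample id and must carry a ``condition`` column
    with values 'vehicle' / 'treated'.  ``descriptions`` maps accession to
    the protein description line used for contaminant matching.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    descriptions: pd.Series

    def __post_init__(self) -> None:
        if "condition" not in self.samples.columns:
            raise ValueError("sample metadata must contain a 'condition' column")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("PSM counts must be non-negative")
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PSMMatrix":
        """Build from the long TSV layout (one row per protein per sample)."""
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"PSM table missing columns: {sorted(missing)}")
        counts = (
            df.pivot_table(
                index="protein_accession",
                columns="sample_id",
                values="psm",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )
        counts = counts[sorted(counts.columns)]
        meta = (
            df[["sample_id", "condition", "subject_id", "tech_rep"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
            .loc[counts.columns]
        )
        desc = (
            df[["protein_accession", "description"]]
            .drop_duplicates("protein_accession")
            .set_index("protein_accession")["description"]
            .reindex(counts.index)
            .fillna("")
        )
        return cls(counts=counts, samples=meta, descriptions=desc)


def read_psm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def preprocess(
    df: pd.DataFrame,
    min_ion_score: float = 20.0,
    contaminant_patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS,
) -> PSMMatrix:
    """Score-filter peptides, drop contaminant proteins, sum to protein level.

    Rows may be peptide-level (with ``ion_score``); peptides scoring strictly
    below ``min_ion_score`` are removed (a score of exactly 20 is kept).
    Proteins whose accession or description matches any contaminant pattern
    (case-insensitive substring/regex) are dropped entirely.
    """
    work = df.copy()
    n0 = len(work)
    if "ion_score" in work.columns:
        keep = work["ion_score"].isna() | (work["ion_score"] >= min_ion_score)
        removed = int((~keep).sum())
        work = work[keep]
        logger.info("ion-score filter removed %d of %d rows", removed, n0)
    if contaminant_patterns:
        pat = re.compile("|".join(contaminant_patterns), re.IGNORECASE)
        text = (
            work["protein_accession"].astype(str)
            + " "
            + work.get("description", pd.Series("", index=work.index)).astype(str)
        )
        is_contam = text.str.contains(pat)
        for p in contaminant_patterns:
            n = int(
                text[is_contam].str.contains(p, case=False, regex=True).sum()
            )
            logger.info("contaminant rule %r matched %d rows", p, n)
        work = work[~is_contam]
    return PSMMatrix.from_long(work)


def _pairwise_r2(counts: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation between every pair of sample columns."""
    r = np.corrcoef(counts.to_numpy(dtype=float), rowvar=False)
    r2 = r**2
    np.fill_diagonal(r2, np.nan)
    return pd.DataFrame(r2, index=counts.columns, columns=counts.columns)


def linearity_qc(
    matrix: PSMMatrix, r2_min: float = 0.8
) -> Tuple[PSMMatrix, Dict]:
    """Iteratively drop samples whose spectral counts break pairwise linearity.

    For each pair of retained samples the squared Pearson correlation of
    their protein PSM vectors is computed; a sample whose *median* pairwise
    r-squared falls strictly below ``r2_min`` is removed (worst first), and
    the matrix is re-evaluated until stable.  A median of exactly ``r2_min``
    is retained.
    """
    if matrix.counts.shape[1] < 3:
        raise ValueError("linearity QC needs at least 3 samples")
    counts = matrix.counts.copy()
    removal_order: List[str] = []
    initial_r2 = _pairwise_r2(counts)
    while True:
        if counts.shape[1] == 0:
            raise ValueError("linearity QC removed every sample; dataset unusable")
        r2 = _pairwise_r2(counts)
        medians = r2.median(axis=0, skipna=True)
        failing = medians[medians < r2_min]
        if failing.empty:
            break
        worst = failing.idxmin()
        removal_order.append(str(worst))
        counts = counts.drop(columns=[worst])
        if counts.shape[1] < 2:
            raise ValueError("linearity QC removed every sample; dataset unusable")
    kept = list(counts.columns)
    report = {
        "r2_matrix": initial_r2.round(6).to_dict(),
        "median_r2": {
            s: float(m) for s, m in initial_r2.median(axis=0).items()
        },
        "removed_samples": removal_order,
        "retained_samples": kept,
        "r2_min": r2_min,
    }
    logger.info(
        "linearity QC removed %d sample(s): %s", len(removal_order), removal_order
    )
    return (
        PSMMatrix(
            counts=counts,
            samples=matrix.samples.loc[kept],
            descriptions=matrix.descriptions,
        ),
        report,
    )


def differential_abundance(
    matrix: PSMMatrix,
    min_detected: int = 4,
    min_avg_psm: float = 5.0,
    fold_threshold: float = 1.5,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein treated-vs-vehicle fold change and two-tailed t-test.

    A protein is *eligible* when detected (PSM > 0) in at least
    ``min_detected`` samples of each condition and its average PSM is at
    least ``min_avg_psm`` in both.  It is called *significant* when eligible,
    |log fold| exceeds the two-sided ``fold_threshold`` (max(fold, 1/fold)
    strictly greater) and the raw t-test p-value is below ``alpha``.
    A Benjamini-Hochberg adjusted p-value is reported alongside but does not
    enter the call.  Student's equal-variance t-test by default; set
    ``equal_var=False`` for Welch.
    """
    cond = matrix.samples["condition"]
    veh_cols = list(cond[cond == "vehicle"].index)
    trt_cols = list(cond[cond == "treated"].index)
    if not veh_cols or not trt_cols:
        raise ValueError("both 'vehicle' and 'treated' samples are required")

    veh = matrix.counts[veh_cols].to_numpy(dtype=float)
    trt = matrix.counts[trt_cols].to_numpy(dtype=float)

    avg_veh = veh.mean(axis=1)
    avg_trt = trt.mean(axis=1)
    det_veh = (veh > 0).sum(axis=1)
    det_trt = (trt > 0).sum(axis=1)
    eligible = (
        (det_veh >= min_detected)
        & (det_trt >= min_detected)
        & (avg_veh >= min_avg_psm)
        & (avg_trt >= min_avg_psm)
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(avg_veh > 0, avg_trt / avg_veh, np.inf)
        fold = np.where((avg_veh == 0) & (avg_trt == 0), np.nan, fold)
        tstat, pval = stats.ttest_ind(trt, veh, axis=1, equal_var=equal_var)
    pval = np.where(np.isnan(pval), 1.0, pval)

    with np.errstate(divide="ignore", invalid="ignore"):
        two_sided_fold = np.fmax(fold, 1.0 / fold)
    significant = (
        eligible & (two_sided_fold > fold_threshold) & (pval < alpha)
    )

    bh = np.full(len(pval), np.nan)
    if eligible.any():
        bh[eligible] = multipletests(pval[eligible], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "protein_accession": matrix.counts.index,
            "description": matrix.descriptions.reindex(matrix.counts.index).values,
            "avg_psm_vehicle": avg_veh,
            "avg_psm_treated": avg_trt,
            "fold_change": fold,
            "t_statistic": tstat,
            "p_value": pval,
            "bh_adjusted_p": bh,
            "eligible": eligible,
            "significant": significant,
        }
    ).reset_index(drop=True)
    logger.info(
        "differential: %d proteins, %d eligible, %d significant",
        len(out),
        int(eligible.sum()),
        int(significant.sum()),
    )
    return out
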