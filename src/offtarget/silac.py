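"""Protein-level SILAC competition analysis for photoprobe target calling.

Cells pretreated with an unlabelled competitor lose photoprobe labelling at
shared binding sites, so after mixing heavy/light proteomes the competition
ratio (control channel over competed channel) rises above 1 for genuine
targets and sits near 1 for background.  This module aggregates peptide-level
ratios to protein level, applies replicate/peptide-count/variability filters,
and calls proteins whose median competition ratio clears a fold threshold.

Orientation matters: when the competitor was applied to the *light* culture,
the raw heavy/light ratio already reads control/competed; in label-swap
replicates (competitor in the heavy culture) the raw ratio must be inverted
before pooling.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ORIENTATIONS",
    "PEPTIDE_COLUMNS",
    "orient_ratios",
    "aggregate_proteins",
    "apply_quality_filters",
    "call_specific_targets",
    "read_peptide_table",
    "run_silac",
]

ORIENTATIONS = ("competitor_in_light", "competitor_in_heavy")

PEPTIDE_COLUMNS = [
    "protein_accession",
    "protein_description",
    "peptide_sequence",
    "replicate_id",
    "orientation",
    "ratio_hl",
]


def read_peptide_table(path) -> pd.DataFrame:
    """Read the peptide-level SILAC TSV (see :data:`PEPTIDE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def orient_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Convert raw H/L ratios to competition orientation (control/competed).

    Raw ratios from label-swap replicates (``competitor_in_heavy``) are
    inverted; others pass through.  The returned table carries the oriented
    value in ``competition_ratio``.
    """
    df = records.copy()
    orient = df["orientation"]
    bad = df.loc[~orient.isin(ORIENTATIONS) | orient.isna(), "replicate_id"]
    if len(bad):
        raise ValueError(
            "missing or invalid orientation for replicates: "
            f"{sorted(set(bad.astype(str)))}"
        )
    ratios = df["ratio_hl"].astype(float)
    if not (ratios > 0).all():
        raise ValueError("all H/L ratios must be positive")
    flip = orient == "competitor_in_heavy"
    df["competition_ratio"] = np.where(flip, 1.0 / ratios, ratios)
    return df


def aggregate_proteins(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise oriented peptide ratios per protein.

    The headline ``median_competition_ratio`` is the median over all pooled
    peptide observations; per-replicate medians are retained and their sample
    standard deviation (ddof=1) feeds the variability filter.  Proteins seen
    in a single replicate get a missing (NaN) standard deviation.
    """
    if records.empty:
        logger.warning("empty peptide table: no proteins to aggregate")
        return pd.DataFrame(
            columns=[
                "protein_accession",
                "protein_description",
                "n_peptides_total",
                "n_replicates_detected",
                "replicate_medians",
                "median_competition_ratio",
                "sd_between_replicates",
            ]
        )
    if "competition_ratio" not in records.columns:
        raise ValueError("records must be oriented first (orient_ratios)")

    rows = []
    for acc, grp in records.groupby("protein_accession", sort=True):
        rep_medians = (
            grp.groupby("replicate_id")["competition_ratio"].median().sort_index()
        )
        sd = float(rep_medians.std(ddof=1)) if len(rep_medians) > 1 else math.nan
        rows.append(
            {
                "protein_accession": acc,
                "protein_description": grp["protein_description"].iloc[0],
                "n_peptides_total": int(len(grp)),
                "n_replicates_detected": int(len(rep_medians)),
                "replicate_medians": list(rep_medians),
                "median_competition_ratio": float(
                    grp["competition_ratio"].median()
                ),
                "sd_between_replicates": sd,
            }
        )
    return pd.DataFrame(rows)


def apply_quality_filters(
    summaries: pd.DataFrame,
    min_total_peptides: int = 5,
    max_sd: float = 3.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Flag proteins passing the quantification quality filters.

    A protein passes iff it has at least ``min_total_peptides`` pooled
    quantified peptides, a between-replicate standard deviation no greater
    than ``max_sd`` (a missing sd fails), and detection in at least
    ``min_replicates`` replicates.  Boundary semantics follow the filter
    wording: exactly 5 peptides pass, sd exactly 3.0 passes.
    """
    df = summaries.copy()
    if df.empty:
        df["passes_filters"] = pd.Series(dtype=bool)
        return df
    sd = df["sd_between_replicates"]
    df["passes_filters"] = (
        (df["n_peptides_total"] >= min_total_peptides)
        & sd.notna()
        & (sd <= max_sd)
        & (df["n_replicates_detected"] >= min_replicates)
    )
    return df


def call_specific_targets(
    summaries: pd.DataFrame, ratio_threshold: float = 2.0
) -> List[str]:
    """Proteins passing filters with median ratio strictly above threshold.

    Returned sorted by descending median competition ratio.
    """
    if summaries.empty:
        return []
    if "passes_filters" not in summaries.columns:
        raise ValueError("run apply_quality_filters first")
    hits = summaries[
        summaries["passes_filters"]
        & (summaries["median_competition_ratio"] > ratio_threshold)
    ]
    hits = hits.sort_values(
        "median_competition_ratio", ascending=False, kind="stable"
    )
    return list(hits["protein_accession"])


def run_silac(
    records: pd.DataFrame,
    min_total_peptides: int = 5,
    max_sd: float = 3.0,
    min_replicates: int = 2,
    ratio_threshold: float = 2.0,
) -> tuple[pd.DataFrame, List[str]]:
    """Full stage: orient, aggregate, filter, call. Returns (summary, calls)."""
    oriented = orient_ratios(records)
    summary = aggregate_proteins(oriented)
    summary = apply_quality_filters(
        summary,
        min_total_peptides=min_total_peptides,
        max_sd=max_sd,
        min_replicates=min_replicates,
    )
    calls = call_specific_targets(summary, ratio_threshold=ratio_threshold)
    summary["is_specific_target"] = summary["protein_accession"].isin(calls)
    logger.info(
        "silac: %d proteins, %d pass filters, %d specific targets",
        len(summary),
        int(summary["passes_filters"].sum()) if len(summary) else 0,
        len(calls),
    )
    return summary, calls
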