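"""Synthetic datasets with planted ground truth for every pipeline stage.

Each generator emulates one of the four input table types the pipeline
consumes — peptide-level SILAC competition ratios, protein x sample PSM
count matrices, probe-competition densitometry series, and dosing-cohort
exposure records — plus MS2 peak lists for adduct site localization.  All
planted effects (competed targets, fold changes, true IC50s, occupancy-rule
outcomes, modification sites) are returned in a :class:`GroundTruth` object
so downstream stages can be scored for recovery without any external data.

Randomness: every table type draws from its own child stream of a single
seeded generator (``numpy`` ``SeedSequence`` spawning), so regenerating one
table never perturbs the others and a fixed seed reproduces every byte.

Default condition choices mirror the study design the pipeline targets:
four SILAC replicates with one label-swap, background ratios log-normal
around 1 with sigma 0.15 (keeping ~95% of protein medians inside the
0.5-2.0 background band), six samples per condition for the PSM matrix
(two technical replicates of three subjects), and rat cohorts of 4-6
animals (2 for dogs) whose ocular-toxicity outcome follows an 80%
cell-occupancy rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fragments as frag
from .engagement import DensitometrySeries, four_pl
from .fragments import PeakList, PeptideSpec, theoretical_fragments
from .occupancy import occupancy

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortCompound",
    "DEFAULT_COHORT",
    "generate_silac_dataset",
    "generate_psm_matrix",
    "generate_dose_response",
    "generate_cohort",
    "generate_peaklist",
    "write_fixture_directory",
]

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# child-stream keys: one fixed spawn position per table type
_STREAM = {"silac": 0, "psm": 1, "dose_response": 2, "cohort": 3, "peaks": 4}


@dataclass(frozen=True)
class CohortCompound:
    """One compound arm of the toxicology cohort simulation.

    ``cell_ic50`` / ``enzyme_ic50`` are molar; ``shift`` = enzyme/cell is
    implied.  ``unbound_exposures`` are the average unbound plasma
    concentrations (molar) achieved at each tested dose level.
    """

    compound_id: str
    cell_ic50: float
    enzyme_ic50: float
    unbound_exposures: Tuple[float, ...]
    species: str = "rat"
    fu: float = 0.3
    cohort_size: int = 5


# A heterogeneous-shift compound set: two high-shift compounds dosed into the
# occupancy-positive regime, one low-shift and one intermediate-shift compound
# kept below it.  Scoring occupancy with the enzyme potencies scrambles the
# ordering, which is exactly the non-separability the negative control needs.
DEFAULT_COHORT: Tuple[CohortCompound, ...] = (
    CohortCompound("thioamidine-1", 140e-9, 12e-6, (2e-6, 50e-9), "rat", 0.3, 5),
    CohortCompound("firstgen-1", 59e-9, 5.6e-6, (1e-6, 20e-9), "rat", 0.25, 6),
    CohortCompound("secondgen-1", 6.8e-6, 13.6e-6, (10e-6, 1e-6), "rat", 0.35, 4),
    CohortCompound("sulfonylguanidine-1", 2.9e-6, 98.6e-6, (5e-6,), "dog", 0.4, 2),
)


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators (see module docstring)."""

    seed: int = 0
    # SILAC
    n_proteins: int = 200
    peptides_per_protein: Tuple[int, int] = (5, 12)
    background_ratio_sigma: float = 0.15
    planted_targets: Sequence[Tuple[str, float]] = ()
    n_replicates: int = 4
    orientation_swaps: Sequence[str] = ("rep4",)
    # PSM
    psm_mean_range: Tuple[float, float] = (5.0, 80.0)
    psm_planted_mean: float = 50.0  # base abundance of planted-fold proteins
    psm_fold_changes: Sequence[Tuple[str, float]] = ()
    n_subjects_per_condition: int = 3
    n_tech_reps: int = 2
    n_contaminants: int = 6
    degraded_sample: Optional[str] = None
    psm_overdispersion: float = 0.0
    # dose-response
    dr_true_ic50: float = 140e-9
    dr_hill: float = 1.0
    dr_top: float = 100.0
    dr_bottom: float = 0.0
    dr_noise_sd: float = 5.0  # percent-inhibition units
    dr_n_points: int = 10
    # cohort
    cohort: Tuple[CohortCompound, ...] = DEFAULT_COHORT
    outcome_threshold: float = 80.0
    stochastic_outcomes: bool = False

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.peptides_per_protein[0] < 1:
            raise ValueError("peptides_per_protein minimum must be >= 1")
        if self.background_ratio_sigma < 0:
            raise ValueError("background_ratio_sigma must be non-negative")
        for acc, ratio in self.planted_targets:
            if not ratio > 0:
                raise ValueError(f"planted ratio for {acc} must be positive")
        for acc, fold in self.psm_fold_changes:
            if not fold > 0:
                raise ValueError(f"planted fold for {acc} must be positive")
        if not self.dr_true_ic50 > 0:
            raise ValueError("true IC50 must be positive")
        for c in self.cohort:
            if not (c.cell_ic50 > 0 and c.enzyme_ic50 > 0):
                raise ValueError(f"IC50s for {c.compound_id} must be positive")
            if not c.unbound_exposures:
                raise ValueError(f"{c.compound_id} needs at least one exposure")

    def rng(self, table: str) -> np.random.Generator:
        """Independent child generator for one table type."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAM))
        return np.random.default_rng(children[_STREAM[table]])


@dataclass
class GroundTruth:
    """Planted truth for scoring recovery of every synthetic effect."""

    silac_targets: Dict[str, float] = field(default_factory=dict)
    psm_folds: Dict[str, float] = field(default_factory=dict)
    degraded_sample: Optional[str] = None
    contaminants: List[str] = field(default_factory=list)
    true_ic50: Optional[float] = None
    occupancies: Dict[str, float] = field(default_factory=dict)
    outcomes: Dict[str, str] = field(default_factory=dict)
    mod_position: Optional[int] = None
    mod_mass: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _random_peptides(rng: np.random.Generator, n: int) -> List[str]:
    lengths = rng.integers(8, 16, size=n)
    return ["".join(rng.choice(_AMINO, size=l)) for l in lengths]


def generate_silac_dataset(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Peptide-level SILAC competition table with planted competed targets.

    Background proteins have true competition ratio 1; peptide observations
    scatter log-normally (sigma ``background_ratio_sigma``) around each
    protein's true ratio.  Replicates listed in ``orientation_swaps`` are
    label-swapped: their raw H/L is the *inverse* of the competition ratio
    and they carry orientation 'competitor_in_heavy'.
    """
    rng = config.rng("silac")
    planted = dict(config.planted_targets)
    accessions = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    for acc in planted:
        if acc not in accessions:
            accessions.append(acc)
    truth = GroundTruth(silac_targets=dict(planted))

    lo, hi = config.peptides_per_protein
    replicates = [f"rep{i}" for i in range(1, config.n_replicates + 1)]
    swaps = set(config.orientation_swaps)
    rows = []
    for acc in accessions:
        true_ratio = planted.get(acc, 1.0)
        desc = (
            f"planted target {acc}" if acc in planted else f"background protein {acc}"
        )
        for rep in replicates:
            n_pep = int(rng.integers(lo, hi + 1))
            peptides = _random_peptides(rng, n_pep)
            noise = rng.normal(0.0, config.background_ratio_sigma, size=n_pep)
            comp_ratio = true_ratio * np.exp(noise)
            if rep in swaps:
                ratio_hl = 1.0 / comp_ratio
                orientation = "competitor_in_heavy"
            else:
                ratio_hl = comp_ratio
                orientation = "competitor_in_light"
            for pep, r in zip(peptides, ratio_hl):
                rows.append((acc, desc, pep, rep, orientation, float(r)))
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "protein_description",
            "peptide_sequence",
            "replicate_id",
            "orientation",
            "ratio_hl",
        ],
    )
    return df, truth


_CONTAMINANT_NAMES = (
    ("CONT_KRT1", "Keratin, type II cytoskeletal 1"),
    ("CONT_KRT10", "Keratin, type I cytoskeletal 10"),
    ("CONT_HBA", "Hemoglobin subunit alpha"),
    ("CONT_HBB", "Hemoglobin subunit beta"),
    ("CONT_H2B", "Histone H2B"),
    ("CONT_H4", "Histone H4"),
)


def generate_psm_matrix(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Long-format protein x sample PSM count table with planted folds.

    Counts are Poisson around protein base means (uniform over
    ``psm_mean_range``), with treated-condition means multiplied by any
    planted fold.  An optional gamma multiplier (``psm_overdispersion`` > 0)
    makes counts negative-binomial-like.  Contaminant proteins (keratins,
    hemoglobins, histones) are appended, and ``degraded_sample``, if set,
    has its counts permuted across proteins to destroy pairwise linearity
    while preserving the total.
    """
    rng = config.rng("psm")
    folds = dict(config.psm_fold_changes)
    accessions = [f"R{i:05d}" for i in range(1, config.n_proteins + 1)]
    for acc in folds:
        if acc not in accessions:
            accessions.append(acc)
    base_means = rng.uniform(*config.psm_mean_range, size=len(accessions))
    for i, acc in enumerate(accessions):
        if acc in folds:
            base_means[i] = config.psm_planted_mean

    samples = []
    for cond in ("vehicle", "treated"):
        for subj in range(1, config.n_subjects_per_condition + 1):
            for tech in range(1, config.n_tech_reps + 1):
                samples.append(
                    {
                        "sample_id": f"{cond}_s{subj}_t{tech}",
                        "condition": cond,
                        "subject_id": f"{cond}_s{subj}",
                        "tech_rep": tech,
                    }
                )

    counts = np.empty((len(accessions), len(samples)), dtype=int)
    for j, s in enumerate(samples):
        means = base_means.copy()
        if s["condition"] == "treated":
            for i, acc in enumerate(accessions):
                if acc in folds:
                    means[i] *= folds[acc]
        if config.psm_overdispersion > 0:
            k = 1.0 / config.psm_overdispersion
            means = means * rng.gamma(k, 1.0 / k, size=means.size)
        counts[:, j] = rng.poisson(means)

    # contaminants: moderately abundant, condition-independent
    contam = list(_CONTAMINANT_NAMES[: config.n_contaminants])
    contam_counts = rng.poisson(30.0, size=(len(contam), len(samples)))

    degraded = config.degraded_sample
    truth = GroundTruth(
        psm_folds=dict(folds),
        degraded_sample=degraded,
        contaminants=[acc for acc, _ in contam],
    )
    if degraded is not None:
        ids = [s["sample_id"] for s in samples]
        if degraded not in ids:
            raise ValueError(f"degraded_sample {degraded!r} not in sample layout")
        j = ids.index(degraded)
        counts[:, j] = rng.permutation(counts[:, j])

    rows = []
    all_accs = accessions + [a for a, _ in contam]
    all_desc = [f"tissue protein {a}" for a in accessions] + [d for _, d in contam]
    all_counts = np.vstack([counts, contam_counts])
    for i, (acc, desc) in enumerate(zip(all_accs, all_desc)):
        for j, s in enumerate(samples):
            rows.append(
                (
                    acc,
                    desc,
                    s["sample_id"],
                    s["condition"],
                    s["subject_id"],
                    s["tech_rep"],
                    int(all_counts[i, j]),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "description",
            "sample_id",
            "condition",
            "subject_id",
            "tech_rep",
            "psm",
        ],
    )
    return df, truth


def generate_dose_response(
    config: SimulationConfig,
    compound_id: str = "compound-1",
    assay_context: str = "live_cell",
) -> Tuple[DensitometrySeries, GroundTruth]:
    """Densitometry titration following a 4PL plus Gaussian intensity noise.

    Concentrations are log-spaced two decades either side of the true IC50.
    Anchor wells (DMSO / saturating blocker) are emitted with the same noise.
    A warning flag is recorded on the series if the requested IC50 falls
    outside the concentration range.
    """
    rng = config.rng("dose_response")
    n = config.dr_n_points
    if n < 4:
        raise ValueError("need at least 4 concentration points")
    conc = np.logspace(
        np.log10(config.dr_true_ic50) - 2.0,
        np.log10(config.dr_true_ic50) + 2.0,
        n,
    )
    inhibition = four_pl(
        conc,
        np.log10(config.dr_true_ic50),
        config.dr_hill,
        config.dr_top,
        config.dr_bottom,
    )
    no_inh_anchor = 10000.0  # arbitrary optical-density scale
    full_block_anchor = 500.0
    span = no_inh_anchor - full_block_anchor
    intensities = no_inh_anchor - span * inhibition / 100.0
    if config.dr_noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, span * config.dr_noise_sd / 100.0, size=n
        )
    series = DensitometrySeries(
        compound_id=compound_id,
        assay_context=assay_context,
        target_id="CatD",
        concentrations=conc,
        intensities=intensities,
        no_inhibition_intensity=no_inh_anchor,
        full_block_intensity=full_block_anchor,
    )
    if not conc.min() <= config.dr_true_ic50 <= conc.max():
        series.warnings_.append("true IC50 outside concentration range")
    return series, GroundTruth(true_ic50=config.dr_true_ic50)


def generate_cohort(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Exposure-record table whose outcomes follow an occupancy rule.

    Each compound/exposure level becomes one study.  True occupancy is
    computed from the *cellular* IC50; the ocular-toxicity outcome is
    positive iff that occupancy exceeds ``outcome_threshold`` percent
    (deterministic default).  With ``stochastic_outcomes`` the cohort
    incidence is Bernoulli per animal with probability ramping with
    occupancy, and the study is positive if at least one animal is affected.
    Both cellular and enzyme IC50s are emitted so the separation analysis
    can be run against either potency scale.
    """
    rng = config.rng("cohort")
    rows = []
    truth = GroundTruth()
    for cmpd in config.cohort:
        for k, c_u in enumerate(cmpd.unbound_exposures, start=1):
            study = f"{cmpd.compound_id}_dose{k}"
            occ_cell = occupancy(c_u, cmpd.cell_ic50)
            if config.stochastic_outcomes:
                p_affected = occ_cell / 100.0 if occ_cell > config.outcome_threshold else 0.02
                affected = int(rng.binomial(cmpd.cohort_size, p_affected))
                outcome = "positive" if affected > 0 else "negative"
            else:
                positive = occ_cell > config.outcome_threshold
                outcome = "positive" if positive else "negative"
                affected = cmpd.cohort_size if positive else 0
            rows.append(
                {
                    "study_id": study,
                    "species": cmpd.species,
                    "compound_id": cmpd.compound_id,
                    "dose_mgkg": round(10.0 * (k + 1), 1),
                    "duration_days": 14,
                    "c_total": c_u / cmpd.fu,
                    "c_total_units": "M",
                    "fu": cmpd.fu,
                    "ic50_parent_molar": cmpd.cell_ic50,
                    "ic50_parent_enzyme_molar": cmpd.enzyme_ic50,
                    "outcome": outcome,
                    "affected": affected,
                    "cohort": cmpd.cohort_size,
                }
            )
            truth.occupancies[study] = occ_cell
            truth.outcomes[study] = outcome
    return pd.DataFrame(rows), truth


def generate_peaklist(
    peptide: str,
    mod_position: Optional[int] = None,
    mod_mass: float = frag.PROBE_ADDUCT,
    noise_peaks: int = 0,
    intensity_cv: float = 0.0,
    seed: int = 0,
    max_charge: int = 1,
) -> Tuple[PeakList, GroundTruth]:
    """MS2 peak list of a peptide with an optional planted adduct.

    Every theoretical b/y ion of the (modified) peptide is emitted as a
    peak; fragments containing ``mod_position`` are therefore shifted by
    ``mod_mass``.  Optional decoy peaks at random m/z and log-normal
    intensity jitter can be layered on top.
    """
    mods = {mod_position: mod_mass} if mod_position is not None else {}
    spec = PeptideSpec(peptide, mods)
    ions = theoretical_fragments(spec, max_charge=max_charge)
    rng = np.random.default_rng(seed)
    mz = np.array([ion.mz for ion in ions])
    intensity = np.full(mz.size, 1000.0)
    if intensity_cv > 0:
        intensity = intensity * rng.lognormal(0.0, intensity_cv, size=mz.size)
    if noise_peaks > 0:
        noise_mz = rng.uniform(mz.min() * 0.5, mz.max() * 1.1, size=noise_peaks)
        noise_int = rng.uniform(10.0, 100.0, size=noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    peaklist = PeakList(
        mz=mz,
        intensity=intensity,
        precursor_mz=spec.precursor_mh(),
        precursor_charge=1,
        title=f"synthetic {peptide}",
    )
    truth = GroundTruth(
        mod_position=mod_position, mod_mass=mod_mass if mod_position else None
    )
    return peaklist, truth


def write_fixture_directory(config: SimulationConfig, outdir) -> Dict[str, str]:
    """Write every synthetic table plus a combined ground-truth JSON.

    Returns a manifest mapping logical names to the files written.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}

    silac_df, silac_truth = generate_silac_dataset(config)
    silac_path = out / "silac_peptides.tsv"
    silac_df.to_csv(silac_path, sep="\t", index=False)
    manifest["silac"] = str(silac_path)

    psm_df, psm_truth = generate_psm_matrix(config)
    psm_path = out / "psm_counts.tsv"
    psm_df.to_csv(psm_path, sep="\t", index=False)
    manifest["psm"] = str(psm_path)

    dr_series, dr_truth = generate_dose_response(config)
    dr_path = out / "densitometry.csv"
    rows = [
        {
            "compound_id": dr_series.compound_id,
            "assay_context": dr_series.assay_context,
            "target_id": dr_series.target_id,
            "replicate_id": dr_series.replicate_id,
            "concentration_molar": c,
            "intensity": i,
            "anchor_role": "",
        }
        for c, i in zip(dr_series.concentrations, dr_series.intensities)
    ]
    rows.append(
        {
            "compound_id": dr_series.compound_id,
            "assay_context": dr_series.assay_context,
            "target_id": dr_series.target_id,
            "replicate_id": dr_series.replicate_id,
            "concentration_molar": 0.0,
            "intensity": dr_series.no_inhibition_intensity,
            "anchor_role": "no_inhibition",
        }
    )
    rows.append(
        {
            "compound_id": dr_series.compound_id,
            "assay_context": dr_series.assay_context,
            "target_id": dr_series.target_id,
            "replicate_id": dr_series.replicate_id,
            "concentration_molar": 100e-6,
            "intensity": dr_series.full_block_intensity,
            "anchor_role": "full_block",
        }
    )
    pd.DataFrame(rows).to_csv(dr_path, index=False)
    manifest["densitometry"] = str(dr_path)

    cohort_df, cohort_truth = generate_cohort(config)
    cohort_path = out / "exposure_records.csv"
    cohort_df.to_csv(cohort_path, index=False)
    manifest["cohort"] = str(cohort_path)

    peaklist, peak_truth = generate_peaklist(
        "MGMDIPPPSGPL", mod_position=1, seed=config.seed
    )
    mgf_path = out / "site_localization.mgf"
    frag.write_mgf([peaklist], mgf_path)
    manifest["peaklist"] = str(mgf_path)

    truth = GroundTruth(
        silac_targets=silac_truth.silac_targets,
        psm_folds=psm_truth.psm_folds,
        degraded_sample=psm_truth.degraded_sample,
        contaminants=psm_truth.contaminants,
        true_ic50=dr_truth.true_ic50,
        occupancies=cohort_truth.occupancies,
        outcomes=cohort_truth.outcomes,
        mod_position=peak_truth.mod_position,
        mod_mass=peak_truth.mod_mass,
    )
    truth_path = out / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    manifest["ground_truth"] = str(truth_path)
    return manifest
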