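"""End-to-end orchestration: config validation, stage execution, manifest.

A run config (YAML or dict) toggles stages and carries all thresholds.
Stages execute in fixed order — simulate, silac, labelfree, engage,
occupancy, localize — each reading either the simulator's fixture files or
user-supplied inputs, and writing TSV/JSON outputs plus a manifest with
per-stage record counts in and out of every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import engagement, fragments, labelfree, occupancy, silac, simulate

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

STAGES = ("simulate", "silac", "labelfree", "engage", "occupancy", "localize")

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "outdir": "offtarget_run",
    "stages": {name: True for name in STAGES},
    "inputs": {},  # per-stage input paths; empty -> use simulator outputs
    "silac": {
        "min_peptides": 5,
        "max_sd": 3.0,
        "min_replicates": 2,
        "ratio_threshold": 2.0,
        "planted_targets": [["CTSD_SYNTH", 2.7]],
    },
    "labelfree": {
        "min_ion_score": 20.0,
        "r2_min": 0.8,
        "min_detected": 4,
        "min_avg_psm": 5.0,
        "fold_threshold": 1.5,
        "alpha": 0.01,
        "degraded_sample": "vehicle_s3_t2",
        "fold_changes": [["CTSD_SYNTH", 1.7]],
    },
    "engage": {"enzyme_ic50": 12e-6},
    "occupancy": {},
    "localize": {
        "peptide": "MGMDIPPPSGPL",
        "mod_mass": 562.1738,
        "fragment_tol": 0.8,
    },
}


def _merge(base: Dict, extra: Dict) -> Dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: Optional[Dict] = None) -> Dict:
    """Load a YAML run config over the defaults; overrides win last."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def validate_config(config: Dict) -> List[str]:
    """Human-readable diagnostics; empty list means the config is valid."""
    diags: List[str] = []
    stages = config.get("stages", {})
    for name in stages:
        if name not in STAGES:
            diags.append(f"stages.{name}: unknown stage")
    if not isinstance(config.get("seed", 0), int):
        diags.append("seed: must be an integer")
    sil = config.get("silac", {})
    for key in ("min_peptides", "min_replicates"):
        if sil.get(key, 1) < 0:
            diags.append(f"silac.{key}: must be non-negative")
    if sil.get("max_sd", 1) < 0:
        diags.append("silac.max_sd: must be non-negative")
    if sil.get("ratio_threshold", 1) <= 0:
        diags.append("silac.ratio_threshold: must be positive")
    lf = config.get("labelfree", {})
    if not 0 < lf.get("alpha", 0.01) < 1:
        diags.append("labelfree.alpha: must lie in (0, 1)")
    if not 0 < lf.get("r2_min", 0.8) <= 1:
        diags.append("labelfree.r2_min: must lie in (0, 1]")
    if lf.get("fold_threshold", 1.5) <= 0:
        diags.append("labelfree.fold_threshold: must be positive")
    loc = config.get("localize", {})
    pep = loc.get("peptide", "")
    for aa in pep:
        if aa not in fragments.RESIDUE_MASSES:
            diags.append(f"localize.peptide: unknown residue {aa!r}")
            break
    # input paths only matter for enabled stages without simulate
    inputs = config.get("inputs", {})
    simulating = stages.get("simulate", False)
    for stage, key in (
        ("silac", "silac"),
        ("labelfree", "psm"),
        ("engage", "densitometry"),
        ("occupancy", "cohort"),
    ):
        if stages.get(stage) and not simulating:
            path = inputs.get(key)
            if not path:
                diags.append(f"inputs.{key}: required when stage '{stage}' is "
                             "enabled without the simulator")
            elif not Path(path).exists():
                diags.append(f"inputs.{key}: path {path!r} does not exist")
    return diags


def _sim_config(config: Dict) -> simulate.SimulationConfig:
    sil = config.get("silac", {})
    lf = config.get("labelfree", {})
    return simulate.SimulationConfig(
        seed=int(config.get("seed", 0)),
        planted_targets=[tuple(t) for t in sil.get("planted_targets", [])],
        psm_fold_changes=[tuple(t) for t in lf.get("fold_changes", [])],
        degraded_sample=lf.get("degraded_sample"),
    )


def run_pipeline(config: Dict) -> Dict:
    """Execute enabled stages in order and write a report bundle.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  Any stage exception is recorded in the manifest
    before re-raising, so partial outputs stay on disk for inspection.
    """
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    inputs = dict(config.get("inputs", {}))
    manifest: Dict = {
        "seed": config.get("seed", 0),
        "thresholds": {
            k: config[k] for k in ("silac", "labelfree", "engage", "localize")
        },
        "stages": {},
    }

    def _fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        if stages.get("simulate"):
            sim_manifest = simulate.write_fixture_directory(
                _sim_config(config), outdir / "fixtures"
            )
            inputs = {**sim_manifest, **inputs}
            manifest["stages"]["simulate"] = {
                "status": "ok",
                "files": sim_manifest,
            }
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)
        raise

    try:
        if stages.get("silac"):
            sil = config["silac"]
            records = silac.read_peptide_table(inputs["silac"])
            summary, calls = silac.run_silac(
                records,
                min_total_peptides=sil["min_peptides"],
                max_sd=sil["max_sd"],
                min_replicates=sil["min_replicates"],
                ratio_threshold=sil["ratio_threshold"],
            )
            out = summary.copy()
            out["replicate_medians"] = out["replicate_medians"].map(
                lambda xs: ";".join(f"{x:.6g}" for x in xs)
            )
            out.to_csv(outdir / "silac_summary.tsv", sep="\t", index=False)
            manifest["stages"]["silac"] = {
                "status": "ok",
                "n_proteins": int(len(summary)),
                "n_pass_filters": int(summary["passes_filters"].sum()),
                "specific_targets": calls,
            }
    except Exception as exc:  # noqa: BLE001
        _fail("silac", exc)
        raise

    try:
        if stages.get("labelfree"):
            lf = config["labelfree"]
            long_df = labelfree.read_psm_table(inputs["psm"])
            matrix = labelfree.preprocess(long_df, min_ion_score=lf["min_ion_score"])
            n_before = matrix.counts.shape[1]
            matrix, qc = labelfree.linearity_qc(matrix, r2_min=lf["r2_min"])
            results = labelfree.differential_abundance(
                matrix,
                min_detected=lf["min_detected"],
                min_avg_psm=lf["min_avg_psm"],
                fold_threshold=lf["fold_threshold"],
                alpha=lf["alpha"],
            )
            results.to_csv(outdir / "labelfree_results.tsv", sep="\t", index=False)
            (outdir / "labelfree_qc.json").write_text(json.dumps(qc, indent=2))
            manifest["stages"]["labelfree"] = {
                "status": "ok",
                "n_samples_in": n_before,
                "samples_removed": qc["removed_samples"],
                "n_proteins": int(len(results)),
                "n_eligible": int(results["eligible"].sum()),
                "n_significant": int(results["significant"].sum()),
                "significant": list(
                    results.loc[results["significant"], "protein_accession"]
                ),
            }
    except Exception as exc:  # noqa: BLE001
        _fail("labelfree", exc)
        raise

    try:
        if stages.get("engage"):
            series_list = engagement.read_densitometry_table(inputs["densitometry"])
            fits = {}
            for s in series_list:
                fit = engagement.fit_ic50(engagement.normalize_intensities(s))
                key = f"{s.compound_id}/{s.assay_context}/{s.replicate_id}"
                entry = fit.to_dict()
                enzyme_ic50 = config["engage"].get("enzyme_ic50")
                if fit.converged and enzyme_ic50:
                    shift = engagement.potency_shift(float(enzyme_ic50), fit.ic50)
                    entry["potency_shift_vs_enzyme"] = (
                        shift if isinstance(shift, float) else str(shift)
                    )
                fits[key] = entry
            (outdir / "engagement_fits.json").write_text(
                json.dumps(fits, indent=2)
            )
            manifest["stages"]["engage"] = {
                "status": "ok",
                "n_series": len(series_list),
                "fits": {k: v["ic50"] for k, v in fits.items()},
            }
    except Exception as exc:  # noqa: BLE001
        _fail("engage", exc)
        raise

    try:
        if stages.get("occupancy"):
            records = occupancy.read_exposure_table(inputs["cohort"])
            reports = {}
            table = None
            for label, col in (
                ("cellular", "ic50_parent_molar"),
                ("enzyme", "ic50_parent_enzyme_molar"),
            ):
                if col not in records.columns:
                    continue
                occ_df = occupancy.study_occupancies(records, ic50_column=col)
                rep = occupancy.separation_analysis(
                    occ_df["occupancy_percent"],
                    occ_df["outcome"],
                    target_id=f"CatD ({label} IC50)",
                )
                reports[label] = rep.to_dict()
                occ_df = occ_df.assign(ic50_scale=label)
                table = occ_df if table is None else pd.concat([table, occ_df])
            if table is not None:
                table.to_csv(outdir / "occupancy_table.tsv", sep="\t", index=False)
            (outdir / "separation_report.json").write_text(
                json.dumps(reports, indent=2)
            )
            manifest["stages"]["occupancy"] = {
                "status": "ok",
                "separation": {
                    k: v["separable"] for k, v in reports.items()
                },
            }
    except Exception as exc:  # noqa: BLE001
        _fail("occupancy", exc)
        raise

    try:
        if stages.get("localize"):
            loc = config["localize"]
            peptide = loc["peptide"]
            peaklists = fragments.read_mgf(inputs["peaklist"])
            results = []
            for pl in peaklists:
                res = localize_spectrum(
                    peptide,
                    pl,
                    mod_mass=loc["mod_mass"],
                    fragment_tol=loc["fragment_tol"],
                )
                results.append(res)
            (outdir / "localization.json").write_text(
                json.dumps(results, indent=2)
            )
            manifest["stages"]["localize"] = {
                "status": "ok",
                "intervals": [r["interval"] for r in results],
            }
    except Exception as exc:  # noqa: BLE001
        _fail("localize", exc)
        raise

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def localize_spectrum(
    peptide: str,
    peaklist: fragments.PeakList,
    mod_mass: float = fragments.PROBE_ADDUCT,
    fragment_tol: float = 0.8,
    max_charge: int = 1,
) -> Dict:
    """Match unshifted and adduct-shifted ion series and localize the site.

    The shifted series used for constraint intersection is the one computed
    with the adduct on the N-terminal residue for b ions and the C-terminal
    residue for y ions: any fragment that contains the true site matches one
    of these m/z values regardless of where within the fragment the site
    lies, because the shift is a constant mass offset.  Plain and shifted
    candidates compete for peaks in a single matching pass, so a peak can
    never be double-counted as evidence for both series.
    """
    spec_plain = fragments.PeptideSpec(peptide)
    n = len(peptide)
    ions_plain = fragments.theoretical_fragments(spec_plain, max_charge=max_charge)
    spec_nterm = fragments.PeptideSpec(peptide, {1: mod_mass})
    spec_cterm = fragments.PeptideSpec(peptide, {n: mod_mass})
    shifted = [
        i
        for i in fragments.theoretical_fragments(spec_nterm, max_charge=max_charge)
        if i.series == "b"
    ] + [
        i
        for i in fragments.theoretical_fragments(spec_cterm, max_charge=max_charge)
        if i.series == "y"
    ]
    pooled = list(ions_plain) + shifted
    shifted_set = set(id(i) for i in shifted)
    matches = fragments.match_peaks(pooled, peaklist, fragment_tol)
    matched_plain = [m.ion for m in matches if id(m.ion) not in shifted_set]
    matched_shifted = [m.ion for m in matches if id(m.ion) in shifted_set]
    result = fragments.localize(matched_plain, matched_shifted, n)
    return {
        "peptide": peptide,
        "interval": list(result.interval),
        "sequence_window": peptide[result.interval[0] - 1 : result.interval[1]],
        "shifted_ions": list(result.shifted_ions),
        "unshifted_ions": list(result.unshifted_ions),
    }
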