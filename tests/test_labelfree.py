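"""PSM preprocessing, linearity QC and differential abundance."""

import math

import numpy as np
import pandas as pd
import pytest

from offtarget import labelfree, simulate
from offtarget.labelfree import PSMMatrix


def long_row(acc, desc, sample, cond, psm, score=None):
    row = {
        "protein_accession": acc,
        "description": desc,
        "sample_id": sample,
        "condition": cond,
        "subject_id": sample.rsplit("_", 1)[0],
        "tech_rep": 1,
        "psm": psm,
    }
    if score is not None:
        row["ion_score"] = score
    return row


def toy_matrix(vehicle, treated):
    """Build a PSMMatrix from dict protein -> (vehicle counts, treated counts)."""
    rows = []
    nv = len(next(iter(vehicle.values())))
    nt = len(next(iter(treated.values())))
    for acc in vehicle:
        for j, c in enumerate(vehicle[acc]):
            rows.append(long_row(acc, acc, f"veh_s{j}", "vehicle", c))
        for j, c in enumerate(treated[acc]):
            rows.append(long_row(acc, acc, f"trt_s{j}", "treated", c))
    return PSMMatrix.from_long(pd.DataFrame(rows))


class TestPreprocess:
    def test_ion_score_boundary(self):
        rows = [
            long_row("A", "protein A", "veh_s1", "vehicle", 5, score=19.9),
            long_row("A", "protein A", "veh_s1", "vehicle", 7, score=20.0),
            long_row("A", "protein A", "trt_s1", "treated", 4, score=25.0),
        ]
        m = labelfree.preprocess(pd.DataFrame(rows), contaminant_patterns=())
        # 19.9 dropped, 20.0 kept: vehicle sum is 7, not 12
        assert m.counts.loc["A", "veh_s1"] == 7

    def test_contaminant_rules_drop_matching_proteins(self):
        descs = (
            ["Keratin, type II"] * 3
            + ["Hemoglobin subunit"] * 2
            + ["Histone H4"]
            + [f"tissue protein {i}" for i in range(4)]
        )
        rows = [
            long_row(f"P{i}", d, s, c, 5)
            for i, d in enumerate(descs)
            for s, c in (("veh_s1", "vehicle"), ("trt_s1", "treated"))
        ]
        m = labelfree.preprocess(pd.DataFrame(rows))
        assert m.counts.shape[0] == 4

    def test_no_scores_no_patterns_is_identity(self):
        rows = [
            long_row("A", "a", "veh_s1", "vehicle", 3),
            long_row("A", "a", "trt_s1", "treated", 9),
        ]
        m = labelfree.preprocess(pd.DataFrame(rows), contaminant_patterns=())
        assert m.counts.loc["A"].tolist() == [9, 3] or m.counts.loc["A"].sum() == 12


def hand_r2(x, y):
    """Hand-rolled squared Pearson correlation oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))


class TestLinearityQC:
    def test_identical_samples_all_retained(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(40, size=(50, 1))
        mat = np.repeat(counts, 4, axis=1)
        # tiny jitter so correlation is defined but ~1
        mat = mat + rng.integers(0, 2, size=mat.shape)
        df = pd.DataFrame(
            mat, index=[f"P{i}" for i in range(50)],
            columns=["veh_s1", "veh_s2", "trt_s1", "trt_s2"],
        )
        m = PSMMatrix(
            counts=df,
            samples=pd.DataFrame(
                {"condition": ["vehicle", "vehicle", "treated", "treated"]},
                index=df.columns,
            ),
            descriptions=pd.Series("", index=df.index),
        )
        kept, report = labelfree.linearity_qc(m)
        assert report["removed_samples"] == []

    def test_permuted_sample_removed_matches_hand_r2(self):
        """Simulator's degraded sample breaks linearity and is the one removed."""
        cfg = simulate.SimulationConfig(
            seed=11, n_proteins=150, degraded_sample="vehicle_s2_t1"
        )
        long_df, truth = simulate.generate_psm_matrix(cfg)
        m = labelfree.preprocess(long_df)
        kept, report = labelfree.linearity_qc(m)
        assert report["removed_samples"] == [truth.degraded_sample]
        # cross-check the reported r2 entries against a hand oracle
        cols = list(m.counts.columns)
        a, b = cols[0], cols[1]
        assert report["r2_matrix"][a][b] == pytest.approx(
            hand_r2(m.counts[a], m.counts[b]), abs=1e-5
        )

    def test_median_exactly_at_threshold_is_retained(self):
        # construct three samples where one has median r2 exactly equal to
        # the threshold passed in; strict "<" must retain it
        rng = np.random.default_rng(4)
        base = rng.poisson(50, size=200).astype(float)
        s1 = base
        s2 = np.clip(base + rng.normal(0, 1, 200), 0, None)
        s3 = np.clip(base + rng.normal(0, 40, 200), 0, None)
        df = pd.DataFrame({"a": s1, "b": s2, "c": s3})
        m = PSMMatrix(
            counts=df,
            samples=pd.DataFrame(
                {"condition": ["vehicle", "vehicle", "treated"]}, index=df.columns
            ),
            descriptions=pd.Series("", index=df.index),
        )
        r2 = labelfree._pairwise_r2(df)
        threshold = float(r2.median(axis=0).min())  # worst sample's median
        _, report = labelfree.linearity_qc(m, r2_min=threshold)
        assert report["removed_samples"] == []
        _, report2 = labelfree.linearity_qc(m, r2_min=threshold + 1e-9)
        assert report2["removed_samples"] == ["c"]

    def test_all_samples_removed_raises(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            rng.permuted(
                np.tile(rng.poisson(30, size=(60, 1)), (1, 4)), axis=0
            ),
            columns=["a", "b", "c", "d"],
        )
        m = PSMMatrix(
            counts=df,
            samples=pd.DataFrame({"condition": ["vehicle"] * 4}, index=df.columns),
            descriptions=pd.Series("", index=df.index),
        )
        with pytest.raises(ValueError, match="unusable"):
            labelfree.linearity_qc(m, r2_min=0.999999)


def hand_t_two_tailed(x, y):
    """Textbook equal-variance two-sample t statistic and two-tailed p."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    tstat = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(tstat), nx + ny - 2)
    return tstat, p


class TestDifferentialAbundance:
    VEH = [30, 32, 28, 31, 29, 30]
    TRT = [51, 49, 52, 50, 48, 50]

    def test_identical_conditions_not_significant(self):
        m = toy_matrix({"A": self.VEH}, {"A": self.VEH})
        res = labelfree.differential_abundance(m)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert not res["significant"].iloc[0]

    def test_toy_6v6_matches_textbook_t_oracle(self):
        m = toy_matrix({"A": self.VEH}, {"A": self.TRT})
        res = labelfree.differential_abundance(m)
        row = res.iloc[0]
        t_oracle, p_oracle = hand_t_two_tailed(self.TRT, self.VEH)
        assert row["fold_change"] == pytest.approx(
            np.mean(self.TRT) / np.mean(self.VEH)
        )
        assert row["fold_change"] == pytest.approx(1.67, abs=0.01)
        assert row["t_statistic"] == pytest.approx(t_oracle, abs=1e-12)
        assert row["p_value"] == pytest.approx(p_oracle, abs=1e-12)
        assert row["significant"]

    def test_eligibility_rules(self):
        # detected in only 3 of 6 vehicle samples -> ineligible
        m = toy_matrix({"A": [0, 0, 0, 9, 9, 9]}, {"A": [9] * 6})
        res = labelfree.differential_abundance(m)
        assert not res["eligible"].iloc[0]
        # average below 5 in one condition -> ineligible
        m2 = toy_matrix({"A": [4] * 6}, {"A": [9] * 6})
        res2 = labelfree.differential_abundance(m2)
        assert not res2["eligible"].iloc[0]
        assert not res2["significant"].iloc[0]

    def test_zero_vehicle_mean_gives_infinite_fold(self):
        m = toy_matrix(
            {"A": [0, 0, 0, 0, 0, 0], "B": [10] * 6},
            {"A": [8, 9, 7, 8, 9, 8], "B": [10] * 6},
        )
        res = labelfree.differential_abundance(m, min_detected=0, min_avg_psm=0)
        a = res.set_index("protein_accession").loc["A"]
        assert math.isinf(a["fold_change"])

    def test_sample_permutation_invariance(self):
        cfg = simulate.SimulationConfig(seed=2, n_proteins=40)
        long_df, _ = simulate.generate_psm_matrix(cfg)
        m = labelfree.preprocess(long_df)
        res1 = labelfree.differential_abundance(m)
        perm_cols = list(m.counts.columns)[::-1]
        m2 = PSMMatrix(
            counts=m.counts[perm_cols],
            samples=m.samples.loc[perm_cols],
            descriptions=m.descriptions,
        )
        res2 = labelfree.differential_abundance(m2)
        pd.testing.assert_frame_equal(
            res1.sort_values("protein_accession").reset_index(drop=True),
            res2.sort_values("protein_accession").reset_index(drop=True),
        )

    def test_condition_swap_reciprocates_fold_keeps_p(self):
        cfg = simulate.SimulationConfig(
            seed=8, n_proteins=30, psm_fold_changes=[("R00001", 2.0)]
        )
        long_df, _ = simulate.generate_psm_matrix(cfg)
        m = labelfree.preprocess(long_df)
        res1 = labelfree.differential_abundance(m)
        swapped = m.samples.copy()
        swapped["condition"] = swapped["condition"].map(
            {"vehicle": "treated", "treated": "vehicle"}
        )
        m2 = PSMMatrix(counts=m.counts, samples=swapped,
                       descriptions=m.descriptions)
        res2 = labelfree.differential_abundance(m2)
        np.testing.assert_allclose(
            res2["fold_change"], 1.0 / res1["fold_change"], rtol=1e-12
        )
        np.testing.assert_allclose(res2["p_value"], res1["p_value"], atol=1e-12)

    def test_planted_twofold_protein_recovered(self):
        """2-fold planted protein at mean ~50 PSM in a 6v6 layout is called."""
        cfg = simulate.SimulationConfig(
            seed=13,
            n_proteins=100,
            psm_mean_range=(40.0, 60.0),
            psm_fold_changes=[("PLANTED", 2.0)],
        )
        long_df, _ = simulate.generate_psm_matrix(cfg)
        m = labelfree.preprocess(long_df)
        res = labelfree.differential_abundance(m)
        row = res.set_index("protein_accession").loc["PLANTED"]
        assert row["significant"]
        assert row["fold_change"] == pytest.approx(2.0, rel=0.2)
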