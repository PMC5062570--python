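"""SILAC competition aggregation, filters and target calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from offtarget import silac, simulate


def make_records(rows):
    return pd.DataFrame(
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


class TestOrientRatios:
    @pytest.mark.parametrize(
        "orientation,raw,expected",
        [
            ("competitor_in_light", 2.7, 2.7),
            ("competitor_in_heavy", 0.5, 2.0),
            ("competitor_in_light", 1.0, 1.0),
        ],
    )
    def test_orientation_semantics(self, orientation, raw, expected):
        df = make_records([("A", "d", "PEP", "rep1", orientation, raw)])
        out = silac.orient_ratios(df)
        assert out["competition_ratio"].iloc[0] == pytest.approx(expected)

    def test_missing_orientation_lists_replicates(self):
        df = make_records(
            [
                ("A", "d", "PEP", "repX", None, 1.0),
                ("A", "d", "PEP", "repY", "sideways", 1.0),
            ]
        )
        with pytest.raises(ValueError, match="repX"):
            silac.orient_ratios(df)

    def test_nonpositive_ratio_rejected(self):
        df = make_records([("A", "d", "PEP", "rep1", "competitor_in_light", 0.0)])
        with pytest.raises(ValueError, match="positive"):
            silac.orient_ratios(df)


class TestAggregateProteins:
    def test_odd_count_median(self, peptide_records):
        summary = silac.aggregate_proteins(silac.orient_ratios(peptide_records))
        a = summary.set_index("protein_accession").loc["A"]
        assert a["median_competition_ratio"] == pytest.approx(2.7)
        assert a["n_peptides_total"] == 3
        assert a["n_replicates_detected"] == 2

    def test_median_matches_sort_based_oracle(self):
        rng = np.random.default_rng(42)
        ratios = rng.lognormal(0.3, 0.4, size=7)
        rows = [
            ("A", "d", f"PEP{i}", f"rep{1 + i % 3}", "competitor_in_light", r)
            for i, r in enumerate(ratios)
        ]
        summary = silac.aggregate_proteins(silac.orient_ratios(make_records(rows)))
        srt = np.sort(ratios)
        oracle = srt[3]  # middle of 7
        got = summary["median_competition_ratio"].iloc[0]
        assert got == pytest.approx(oracle)

    def test_single_replicate_sd_missing_and_fails_filter(self):
        rows = [("A", "d", "PEP", "rep1", "competitor_in_light", 2.0)]
        summary = silac.aggregate_proteins(silac.orient_ratios(make_records(rows)))
        assert summary["n_replicates_detected"].iloc[0] == 1
        assert math.isnan(summary["sd_between_replicates"].iloc[0])
        filtered = silac.apply_quality_filters(summary, min_total_peptides=1)
        assert not filtered["passes_filters"].iloc[0]

    def test_empty_table_gives_empty_output(self):
        out = silac.aggregate_proteins(
            silac.orient_ratios(make_records([])).assign(competition_ratio=[])
        )
        assert out.empty

    def test_sd_is_sample_sd_over_replicate_medians(self):
        rows = [
            ("A", "d", "P1", "rep1", "competitor_in_light", 2.0),
            ("A", "d", "P2", "rep2", "competitor_in_light", 3.0),
            ("A", "d", "P3", "rep3", "competitor_in_light", 4.0),
        ]
        summary = silac.aggregate_proteins(silac.orient_ratios(make_records(rows)))
        assert summary["sd_between_replicates"].iloc[0] == pytest.approx(
            np.std([2.0, 3.0, 4.0], ddof=1)
        )


class TestQualityFilters:
    def base_summary(self, **overrides):
        row = {
            "protein_accession": "A",
            "protein_description": "d",
            "n_peptides_total": 6,
            "n_replicates_detected": 3,
            "replicate_medians": [2.0, 2.1, 2.2],
            "median_competition_ratio": 2.1,
            "sd_between_replicates": 0.1,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    @pytest.mark.parametrize(
        "field,value,passes",
        [
            ("n_peptides_total", 4, False),  # "less than five" excluded
            ("n_peptides_total", 5, True),
            ("sd_between_replicates", 3.0, True),  # ">3" excluded, 3.0 kept
            ("sd_between_replicates", 3.01, False),
            ("n_replicates_detected", 1, False),
            ("n_replicates_detected", 2, True),
        ],
    )
    def test_boundary_semantics(self, field, value, passes):
        out = silac.apply_quality_filters(self.base_summary(**{field: value}))
        assert bool(out["passes_filters"].iloc[0]) is passes

    def test_pass_count_matches_row_predicate_oracle(self):
        rng = np.random.default_rng(7)
        n = 300
        df = pd.DataFrame(
            {
                "protein_accession": [f"P{i}" for i in range(n)],
                "protein_description": "d",
                "n_peptides_total": rng.integers(1, 12, n),
                "n_replicates_detected": rng.integers(1, 5, n),
                "replicate_medians": [[1.0]] * n,
                "median_competition_ratio": rng.lognormal(0, 0.3, n),
                "sd_between_replicates": np.where(
                    rng.random(n) < 0.1, np.nan, rng.exponential(2.0, n)
                ),
            }
        )
        out = silac.apply_quality_filters(df)
        oracle = sum(
            (r.n_peptides_total >= 5)
            and (not math.isnan(r.sd_between_replicates))
            and (r.sd_between_replicates <= 3.0)
            and (r.n_replicates_detected >= 2)
            for r in df.itertuples()
        )
        assert int(out["passes_filters"].sum()) == oracle


class TestCallSpecificTargets:
    def test_strictly_greater_than_threshold(self):
        df = pd.DataFrame(
            {
                "protein_accession": ["A", "B"],
                "median_competition_ratio": [2.0, 2.001],
                "passes_filters": [True, True],
            }
        )
        assert silac.call_specific_targets(df) == ["B"]

    def test_two_planted_targets_sorted_descending(self):
        cfg = simulate.SimulationConfig(
            seed=3,
            n_proteins=50,
            planted_targets=[("T_LOW", 2.4), ("T_HIGH", 3.0)],
        )
        records, _ = simulate.generate_silac_dataset(cfg)
        _, calls = silac.run_silac(records)
        assert calls == ["T_HIGH", "T_LOW"]

    def test_only_planted_target_called_in_study_layout(
        self, planted_silac_config
    ):
        """Planted 2.7x target among 200 background proteins is the sole call."""
        records, truth = simulate.generate_silac_dataset(planted_silac_config)
        summary, calls = silac.run_silac(records)
        assert calls == list(truth.silac_targets)
        assert summary.loc[
            summary["protein_accession"] == "CTSD_SYNTH",
            "median_competition_ratio",
        ].iloc[0] == pytest.approx(2.7, rel=0.15)


class TestInvariances:
    def test_orientation_inversion_leaves_summaries_unchanged(
        self, planted_silac_config
    ):
        records, _ = simulate.generate_silac_dataset(planted_silac_config)
        flipped = records.copy()
        flipped["ratio_hl"] = 1.0 / flipped["ratio_hl"]
        flipped["orientation"] = np.where(
            flipped["orientation"] == "competitor_in_light",
            "competitor_in_heavy",
            "competitor_in_light",
        )
        s1, _ = silac.run_silac(records)
        s2, _ = silac.run_silac(flipped)
        pd.testing.assert_series_equal(
            s1["median_competition_ratio"], s2["median_competition_ratio"]
        )
        pd.testing.assert_series_equal(
            s1["sd_between_replicates"], s2["sd_between_replicates"]
        )

    @settings(deadline=None, max_examples=20)
    @given(st.randoms(use_true_random=False))
    def test_median_invariant_to_row_order_and_duplication(self, rnd):
        cfg = simulate.SimulationConfig(seed=5, n_proteins=10)
        records, _ = simulate.generate_silac_dataset(cfg)
        shuffled = records.sample(frac=1, random_state=rnd.randint(0, 2**31))
        doubled = pd.concat([records, records])
        base = silac.aggregate_proteins(silac.orient_ratios(records))
        for other in (shuffled, doubled):
            summary = silac.aggregate_proteins(silac.orient_ratios(other))
            pd.testing.assert_series_equal(
                base["median_competition_ratio"],
                summary["median_competition_ratio"],
            )

    def test_background_only_rarely_yields_calls(self):
        """No planted targets and default noise: specific calls in <5% of seeds."""
        n_with_calls = 0
        for seed in range(20):
            cfg = simulate.SimulationConfig(seed=seed, n_proteins=60)
            records, _ = simulate.generate_silac_dataset(cfg)
            _, calls = silac.run_silac(records)
            n_with_calls += bool(calls)
        assert n_with_calls == 0
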