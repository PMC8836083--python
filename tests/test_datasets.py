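"""Packaged tables, IQR trimming and the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import caoscsim as cs
from caoscsim.datasets import group_summary
from caoscsim.parameters import DrugDose


class TestFixtures:
    def test_control_row(self):
        table1 = cs.load_fixture("table1")
        row = table1[(table1.S1_uM == 0) & (table1.S2_uM == 0)].iloc[0]
        assert (row.period_s, row.sem_s) == (32.8, 1.2)

    def test_high_dose_rp4010_row(self):
        table1 = cs.load_fixture("table1")
        row = table1[(table1.S2_uM == 10)].iloc[0]
        assert (row.period_s, row.sem_s) == (122.0, 6.6)

    def test_combination_table_first_row(self):
        table4 = cs.load_fixture("table4")
        row = table4.iloc[0]
        assert (row.S2_uM, row.S1_uM, row.period_s, row.sem_s) == (5.0, 2.5, 92.3, 4.6)

    def test_sensitivity_summary_row(self):
        table3 = cs.load_fixture("table3")
        row = table3[table3.parameter == "c2"].iloc[0]
        assert (row.baseline, row.prcc) == (1.0, 0.812)

    def test_parameter_fixtures(self):
        kyse = cs.load_fixture("params_kyse150")
        het = cs.load_fixture("params_het1a")
        assert kyse.k_f / het.k_f == pytest.approx(5.0)
        assert kyse.alpha1 / het.alpha1 == pytest.approx(3.0)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            cs.load_fixture("table9")

    def test_round_trip_identity(self, tmp_path):
        table1 = cs.load_fixture("table1")
        path = tmp_path / "t1.csv"
        table1.to_csv(path, index=False)
        pd.testing.assert_frame_equal(pd.read_csv(path), table1)


class TestIqrTrim:
    def test_zero_iqr_keeps_equal_values(self):
        kept, removed = cs.iqr_trim([30.0, 30.0, 30.0, 30.0])
        assert len(kept) == 4 and len(removed) == 0

    def test_hand_computed_fence(self):
        # linear-interpolation quartiles: Q1 = 31, Q3 = 33, fence at 36
        kept, removed = cs.iqr_trim([30.0, 31.0, 32.0, 33.0, 200.0])
        assert list(removed) == [200.0]
        assert list(kept) == [30.0, 31.0, 32.0, 33.0]

    def test_inliers_pass_through(self):
        values = [30.0, 31.0, 32.0, 33.0, 34.0]
        kept, removed = cs.iqr_trim(values)
        assert list(kept) == values and len(removed) == 0

    @given(st.lists(st.floats(1.0, 1e3), min_size=4, max_size=60))
    def test_partition_respects_the_fences(self, values):
        # kept and removed partition the input exactly at the fences
        kept, removed = cs.iqr_trim(values)
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert len(kept) + len(removed) == len(values)
        assert all(lo <= v <= hi for v in kept)
        assert all(v < lo or v > hi for v in removed)

    def test_second_pass_removes_nothing_on_cohort_data(self):
        # the published procedure applies the rule once; on a cell-period
        # cohort (unimodal noise around a group mean) a second pass is a
        # no-op (this is not a universal property of the rule: removing
        # points shrinks the quartiles, so pathological samples can lose
        # further points on re-application)
        rng = np.random.default_rng(17)
        cohort = 56.5 + 19.0 * rng.standard_normal(50)
        kept, _ = cs.iqr_trim(cohort)
        twice, removed = cs.iqr_trim(kept)
        assert len(removed) == 0
        assert list(twice) == list(kept)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            cs.iqr_trim([1.0, 2.0, 3.0])


class TestSynthesizePeriods:
    def test_noiseless_cells_equal_the_model_period(self, params, drug_params):
        dose = DrugDose(0.0, 0.5)
        cells = cs.synthesize_periods(params, drug_params, [dose],
                                      n_cells=6, noise_sd=0.0, seed=1)
        expected = cs.simulate_period(params, drug_params, dose, t_end=6000,
                                      transient_cutoff=1500, method="rk45")
        np.testing.assert_allclose(cells["period_s"], expected.period_mean)

    def test_reproducible_under_seed(self, params, drug_params):
        kw = dict(n_cells=8, noise_sd=5.0, seed=42)
        a = cs.synthesize_periods(params, drug_params, [DrugDose(0, 1.0)], **kw)
        b = cs.synthesize_periods(params, drug_params, [DrugDose(0, 1.0)], **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_non_oscillating_group_flagged(self, params, drug_params):
        # window shorter than the slowed cycle: group flagged, no cells drawn
        cells = cs.synthesize_periods(params, drug_params,
                                      [DrugDose(0.0, 500.0)], n_cells=5,
                                      noise_sd=1.0, seed=0,
                                      t_end=2500.0, transient_cutoff=1000.0)
        assert not cells["oscillating"].any()
        assert cells["period_s"].isna().all()

    def test_group_sem_matches_noise_arithmetic(self, params, drug_params):
        # sd = 9.5 s per cell over 50 cells gives SEM ~ 1.34 s; the trimmed
        # group SEM should sit within 30% of that across seeds
        dose = DrugDose(0.0, 2.0)
        expected_sem = 9.5 / np.sqrt(50)
        sems = []
        for seed in range(20):
            cells = cs.synthesize_periods(params, drug_params, [dose],
                                          n_cells=50, noise_sd=9.5, seed=seed)
            summary = group_summary(cells, trim=True)
            sems.append(summary.loc[0, "sem_s"])
        assert np.median(sems) == pytest.approx(expected_sem, rel=0.3)

    def test_group_means_monotone_along_the_ray(self, params, drug_params):
        doses = [DrugDose(s / 2, s) for s in (0.25, 1.0, 4.0)]
        cells = cs.synthesize_periods(params, drug_params, doses,
                                      n_cells=40, noise_sd=2.0, seed=3)
        means = cells.groupby("S2_uM")["period_s"].mean().sort_index()
        assert np.all(np.diff(means.to_numpy()) > 0)

    def test_trimming_bookkeeping(self, params, drug_params):
        cells = cs.synthesize_periods(params, drug_params, [DrugDose(0, 0.5)],
                                      n_cells=30, noise_sd=8.0, seed=9)
        summary = group_summary(cells, trim=True)
        assert summary.loc[0, "n_raw"] == 30
        assert 0 < summary.loc[0, "n"] <= 30

    def test_contract_errors(self, params, drug_params):
        with pytest.raises(ValueError):
            cs.synthesize_periods(params, drug_params, [DrugDose(0, 0)], n_cells=3)
        with pytest.raises(ValueError):
            cs.synthesize_periods(params, drug_params, [DrugDose(0, 0)],
                                  noise_sd=-1.0)
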