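"""Least-squares calibration: baseline kinetics and drug constants."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import spearmanr

import caoscsim as cs
from caoscsim.calibrate import DosePeriodTable, fit_baseline, fit_drug_params
from caoscsim.parameters import DrugDose

from conftest import period_at


def synthetic_table(params, dp, doses, noise=None, rng=None):
    rows = []
    for dose in doses:
        T = period_at(params, dp, dose)
        if noise:
            T += noise * rng.standard_normal()
        rows.append((dose.S1, dose.S2, T, 1.0))
    return DosePeriodTable(pd.DataFrame(
        rows, columns=["S1_uM", "S2_uM", "period_s", "sem_s"]))


class TestFitBaseline:
    def test_control_period_fit_via_ip3_level(self, params):
        # perturbed IP3 steady state is pulled back to the 32.8 s calibration
        start = params.replace(p_s=0.12)
        result = fit_baseline(32.8, start, free=("p_s",))
        assert result.success
        achieved = cs.simulate_period(result.model_parameters, method="rk45")
        assert achieved.period_mean == pytest.approx(32.8, rel=0.01)

    def test_already_converged_fit_is_a_fixed_point(self, params, baseline_summary):
        result = fit_baseline(baseline_summary.period_mean, params, free=("p_s",))
        assert result.success
        assert result.parameters["p_s"] == pytest.approx(params.p_s, rel=2e-3)

    def test_one_dimensional_bisection_oracle(self, params):
        # the alpha1 reaching a 38 s period by bracketing bisection must
        # match the least-squares answer
        target = 38.0

        def gap(a1):
            T = period_at(params.replace(alpha1=a1), cs.DrugParameters(),
                          DrugDose(0, 0), t_end=4000.0, cutoff=1000.0)
            return (T if np.isfinite(T) else 1e6) - target

        oracle = brentq(gap, 0.2, 0.385, xtol=1e-10)
        result = fit_baseline(target, params, free=("alpha1",))
        assert result.parameters["alpha1"] == pytest.approx(oracle, abs=1e-3)

    def test_invalid_target_rejected(self, params):
        with pytest.raises(ValueError):
            fit_baseline(-5.0, params)
        with pytest.raises(ValueError):
            fit_baseline(32.8, params, free=("K_bar",))


class TestFitDrugParams:
    def test_noise_free_recovery_of_soce_block_constants(self, params, drug_params):
        # periods generated from the known constants; a perturbed start must
        # come back to them (c2, k2 free, singles-arm data)
        doses = [DrugDose(0.0, s2) for s2 in (0.25, 0.5, 1.0, 2.0, 3.0)]
        table = synthetic_table(params, drug_params, doses)
        start = drug_params.replace(c2=0.85, k2=0.75)
        result = fit_drug_params(table, params, dp0=start, free=("c2", "k2"))
        assert result.parameters["c2"] == pytest.approx(drug_params.c2, rel=0.01)
        assert result.parameters["k2"] == pytest.approx(drug_params.k2, rel=0.01)

    def test_refit_from_converged_point_is_stable(self, params, drug_params):
        doses = [DrugDose(0.0, s2) for s2 in (0.5, 1.0, 3.0)]
        table = synthetic_table(params, drug_params, doses)
        first = fit_drug_params(table, params, dp0=drug_params, free=("c2", "k2"))
        again = fit_drug_params(table, params, dp0=first.drug_parameters,
                                free=("c2", "k2"))
        assert again.parameters["c2"] == pytest.approx(first.parameters["c2"], abs=1e-4)
        assert again.parameters["k2"] == pytest.approx(first.parameters["k2"], abs=1e-4)
        assert again.n_evaluations <= first.n_evaluations

    def test_oscillation_death_handled_by_penalty(self, params, drug_params):
        # a dose far beyond oscillation death must not crash the optimizer
        frame = pd.DataFrame({"S1_uM": [0.0, 0.0], "S2_uM": [0.5, 500.0],
                              "period_s": [45.0, 200.0], "sem_s": [1.0, 1.0]})
        result = fit_drug_params(DosePeriodTable(frame), params, dp0=drug_params,
                                 free=("c2", "k2"), max_nfev=4)
        assert np.isfinite(result.cost)

    def test_weighting_agrees_on_the_worst_fitted_row(self, params, drug_params):
        # SEM weighting shifts the compromise between rows but both fits
        # must single out the same worst-described dose and broadly agree
        # on which rows are hard
        table1 = DosePeriodTable(cs.load_fixture("table1"))
        rp_arm = DosePeriodTable(
            table1.frame[(table1.frame.S1_uM == 0) & (table1.frame.S2_uM > 0)]
            .reset_index(drop=True))
        kw = dict(free=("c2", "k2"))
        unweighted = fit_drug_params(rp_arm, params, dp0=drug_params, **kw)
        weighted = fit_drug_params(rp_arm, params, dp0=drug_params,
                                   weight="sem", **kw)
        sem = rp_arm.frame["sem_s"].to_numpy()
        res_u = np.abs(unweighted.residuals)
        res_w = np.abs(weighted.residuals * sem)
        assert np.argmax(res_u) == np.argmax(res_w)
        assert spearmanr(res_u, res_w).statistic > 0.5

    def test_empty_tables_rejected(self, params):
        with pytest.raises(ValueError):
            fit_drug_params([], params)


def test_single_drug_arms_rank_order_matches_experiment(params, drug_params):
    """With the published drug constants, simulated periods rank-match the
    measured dose dependence within each single-drug arm."""
    table1 = cs.load_fixture("table1")
    for arm in ("S1_uM", "S2_uM"):
        sub = table1[(table1[arm] > 0)]
        sub = sub[sub[["S1_uM", "S2_uM"]].min(axis=1) == 0]
        sim = [period_at(params, drug_params, DrugDose(r.S1_uM, r.S2_uM))
               for r in sub.itertuples(index=False)]
        rho = spearmanr(sim, sub["period_s"]).statistic
        assert rho == pytest.approx(1.0)
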