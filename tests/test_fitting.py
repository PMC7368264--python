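import math

import numpy as np
import pandas as pd
import pytest

from matage.fitting import (ConvergenceError, DegenerateFitError,
                            NonIdentifiableError, _weibull_negloglik,
                            _terminal_events, empirical_rates,
                            fit_coale_trussell, fit_weibull)
from matage.synthetic_data import CohortDesign, default_truth, simulate
from matage.vital_rates import (CoaleTrussellParams, WeibullParams,
                                build_vital_rates)


def make_table(rows):
    return pd.DataFrame(rows, columns=["individual_id", "maternal_age", "day",
                                       "alive", "censored", "offspring"])


@pytest.fixture(scope="module")
def sim_medium():
    """Moderate simulated data set shared by several fitting tests."""
    vital = build_vital_rates(*default_truth())
    table = simulate(vital, CohortDesign(n_per_cohort=600, seed=5))
    return vital, table


class TestFitWeibull:
    def test_empty_data_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_weibull(make_table([]))

    def test_no_deaths_non_identifiable(self):
        rows = [(f"i{k}", 3, d, 1, 1 if d == 3 else 0, 0)
                for k in range(10) for d in (1, 2, 3)]
        with pytest.raises(NonIdentifiableError):
            fit_weibull(make_table(rows))

    def test_single_class_needs_fixed_slopes(self):
        rows = [(f"i{k}", 3, 1, 0, 0, 0) for k in range(10)]
        with pytest.raises(NonIdentifiableError):
            fit_weibull(make_table(rows))

    def test_optimum_beats_initial_point(self, sim_medium):
        _, table = sim_medium
        fit = fit_weibull(table, seed=1)
        assert fit.log_likelihood >= fit.log_likelihood_at_init
        assert fit.n_deaths > 0

    def test_single_class_matches_grid_search(self):
        """With slopes pinned at 0 the fit reduces to an ordinary censored
        Weibull MLE; a zooming grid search over (log b, log k) is the
        independent oracle."""
        w = WeibullParams(math.log(9.0), 0.0, math.log(3.0), 0.0)
        ct = CoaleTrussellParams((-1.6, 1.35, -0.15))
        vital = build_vital_rates(w, ct)
        table = simulate(vital, CohortDesign(maternal_ages=(3,),
                                             n_per_cohort=150, seed=2))
        fit = fit_weibull(table, fix_slopes=True, seed=0)
        events = _terminal_events(table)

        def nll(lb, lk):
            return _weibull_negloglik(np.array([lb, 0.0, lk, 0.0]), events)

        lb, lk = math.log(9.0), math.log(3.0)
        half = 0.5
        for _ in range(6):  # zoom: resolution 0.5 * (2/40)^... < 1e-4
            lbs = np.linspace(lb - half, lb + half, 41)
            lks = np.linspace(lk - half, lk + half, 41)
            vals = np.array([[nll(a, b) for b in lks] for a in lbs])
            ia, ib = np.unravel_index(np.argmin(vals), vals.shape)
            lb, lk = lbs[ia], lks[ib]
            half /= 10
        assert fit.params.log_scale_intercept == pytest.approx(lb, abs=1e-3)
        assert fit.params.log_shape_intercept == pytest.approx(lk, abs=1e-3)
        assert fit.params.log_scale_slope == 0.0
        assert fit.params.log_shape_slope == 0.0

    def test_bias_shrinks_with_sample_size(self):
        """Mean absolute coefficient error decreases from n = 200 to
        n = 2000 per cohort (averaged over three seeded replicates)."""
        w, ct = default_truth()
        vital = build_vital_rates(w, ct)
        truth = np.array([w.log_scale_intercept, w.log_scale_slope,
                          w.log_shape_intercept, w.log_shape_slope])
        maes = {}
        for n in (200, 2000):
            errs = []
            for seed in (21, 22, 23):
                table = simulate(vital, CohortDesign(n_per_cohort=n, seed=seed))
                fit = fit_weibull(table, seed=seed)
                est = np.array([fit.params.log_scale_intercept,
                                fit.params.log_scale_slope,
                                fit.params.log_shape_intercept,
                                fit.params.log_shape_slope])
                errs.append(np.abs(est - truth).mean())
            maes[n] = np.mean(errs)
        assert maes[2000] < maes[200]


class TestFitCoaleTrussell:
    def test_all_zero_counts_degenerate(self):
        rows = [(f"i{k}", a, d, 1, 0, 0)
                for k in range(5) for a in (3, 5) for d in (1, 2, 3)]
        with pytest.raises(DegenerateFitError):
            fit_coale_trussell(make_table(rows))

    def test_single_individual_zero_counts_degenerate(self):
        rows = [("i0", 3, d, 1, 0, 0) for d in (1, 2, 3, 4)]
        with pytest.raises(DegenerateFitError):
            fit_coale_trussell(make_table(rows))

    def test_single_class_non_identifiable(self):
        rows = [(f"i{k}", 3, d, 1, 0, 1) for k in range(5) for d in (3, 4)]
        with pytest.raises(NonIdentifiableError):
            fit_coale_trussell(make_table(rows))

    def test_null_effect_recovered_within_two_se(self):
        """Counts generated without any maternal-age effect yield a fitted
        control slope within 2 standard errors of 0."""
        w, _ = default_truth()
        ct = CoaleTrussellParams((-1.6, 1.35, -0.15), control_threshold_age=4,
                                 deviation_slope=0.25, control_intercept=0.0,
                                 control_slope=0.0, min_reproductive_age=3)
        vital = build_vital_rates(w, ct)
        table = simulate(vital, CohortDesign(n_per_cohort=800, seed=9))
        fit = fit_coale_trussell(table)
        se = fit.standard_errors["control_slope"]
        assert abs(fit.params.control_slope) < 2 * se

    def test_recovers_onset_and_satisfies_invariants(self, sim_medium):
        vital, table = sim_medium
        fit = fit_coale_trussell(table)
        assert fit.params.min_reproductive_age == 3
        refit = build_vital_rates(default_truth()[0], fit.params)
        assert np.all(refit.f >= 0)
        # schedules coincide up to the threshold age
        assert np.allclose(refit.f[:, :4], refit.f[0, :4][None, :])


class TestEmpiricalRates:
    def test_all_survive_first_day(self):
        rows = [(f"i{k}", 2, 1, 1, 0, 0) for k in range(10)]
        emp = empirical_rates(make_table(rows))
        assert emp.p_hat[1, 0] == 1.0
        assert emp.at_risk_p[1, 0] == 10

    def test_three_of_four_survive(self):
        rows = [(f"i{k}", 1, 1, 1 if k < 3 else 0, 0, 0) for k in range(4)]
        emp = empirical_rates(make_table(rows))
        assert emp.p_hat[0, 0] == 0.75

    def test_censored_day_excluded_from_risk_set(self):
        rows = [("a", 1, 1, 1, 0, 0), ("b", 1, 1, 1, 1, 0)]
        emp = empirical_rates(make_table(rows))
        assert emp.at_risk_p[0, 0] == 1

    def test_unobserved_cells_flagged_missing(self):
        rows = [("a", 1, 1, 1, 0, 0)]
        emp = empirical_rates(make_table(rows))
        assert np.isnan(emp.p_hat[0, 1])
        assert np.isnan(emp.p_hat[5, 0])

    def test_coverage_against_generator(self):
        """p-hat falls within 3 binomial standard errors of the generating
        rates in at least 95% of well-populated cells (n = 5000/cohort)."""
        vital = build_vital_rates(*default_truth())
        table = simulate(vital, CohortDesign(n_per_cohort=5000, seed=13))
        emp = empirical_rates(table)
        hits = trials = 0
        for i in (3, 5, 7, 9):
            for j in range(1, 17):
                n = emp.at_risk_p[i - 1, j - 1]
                if n < 30:
                    continue
                p = vital.p[i - 1, j - 1]
                se = math.sqrt(max(p * (1 - p), 1e-12) / n)
                trials += 1
                hits += abs(emp.p_hat[i - 1, j - 1] - p) <= 3 * se + 1e-12
        assert trials > 20
        assert hits / trials >= 0.95

    def test_parametric_fit_tracks_empirical_rates(self, sim_medium):
        """Fitted rates lie within 3 standard errors of the nonparametric
        estimates in at least 90% of well-populated cells.

        Cells whose empirical estimate sits on the boundary (no deaths, or
        no offspring, observed) have a vanishing plug-in standard error;
        the rule-of-three floor 1/n replaces it there.
        """
        _, table = sim_medium
        wfit = fit_weibull(table, seed=3)
        cfit = fit_coale_trussell(table)
        fitted = build_vital_rates(wfit.params, cfit.params)
        emp = empirical_rates(table)
        hits = trials = 0
        for i in (3, 5, 7, 9):
            for j in range(1, 17):
                n = int(emp.at_risk_p[i - 1, j - 1])
                if n < 30:
                    continue
                ph = emp.p_hat[i - 1, j - 1]
                se_p = math.sqrt(max(ph * (1 - ph), 1.0 / n) / n)
                trials += 1
                hits += abs(fitted.p[i - 1, j - 1] - ph) <= 3 * se_p
                fh = emp.f_hat[i - 1, j - 1]
                se_f = math.sqrt(max(fh, 1.0 / n) / n)
                trials += 1
                hits += abs(fitted.f[i - 1, j - 1] - fh) <= 3 * se_f
        assert trials > 40
        assert hits / trials >= 0.90
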