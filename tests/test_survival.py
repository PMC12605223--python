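"""Weibull mathematics, transition probabilities, MLE fitting, selection."""
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.optimize import brentq

from osicea.params import WeibullParams
from osicea.survival import (
    FAMILIES,
    apply_hazard_ratio,
    cycle_transition_prob,
    family_survival,
    fit_parametric,
    select_best_family,
    weibull_median,
    weibull_survival,
)
from osicea.synthetic import PseudoIPD, generate_ipd

PBO_PFS = WeibullParams(0.12138, 0.96416)
OSI_PFS = WeibullParams(0.033281, 0.849111)
OS_STEEP = WeibullParams(0.000005603, 2.931)
U = 28 * 12 / 365.25


class TestWeibullSurvival:
    def test_survival_at_zero_is_one(self):
        assert weibull_survival(PBO_PFS, 0.0) == 1.0

    def test_median_matches_root_finding_oracle(self):
        # independent oracle: solve S(t) = 0.5 numerically
        t_med = brentq(lambda t: weibull_survival(PBO_PFS, t) - 0.5, 1e-6, 100.0)
        assert weibull_median(PBO_PFS) == pytest.approx(t_med, rel=1e-9)
        assert t_med == pytest.approx(6.09, abs=0.01)
        assert weibull_survival(PBO_PFS, weibull_median(PBO_PFS)) == pytest.approx(0.5)

    def test_steep_os_curve_nearly_exhausted_at_fifteen_years(self):
        assert weibull_survival(OS_STEEP, 180.0) < 0.01

    def test_treated_pfs_median_plausible_vs_trial(self):
        # fitted curve median ~35.7 months; trial reported 38.9 (plausibility)
        assert weibull_median(OSI_PFS) == pytest.approx(35.7, abs=0.5)
        assert 30 < weibull_median(OSI_PFS) < 40

    def test_unit_rate_exponential_median(self):
        assert weibull_median(WeibullParams(math.log(2), 1.0)) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(PBO_PFS, -1.0)


class TestHazardRatio:
    def test_identity_at_unity(self):
        assert apply_hazard_ratio(PBO_PFS, 1.0) == PBO_PFS

    def test_power_identity_on_grid(self):
        hr = 2.0
        scaled = apply_hazard_ratio(PBO_PFS, hr)
        t = np.linspace(0, 120, 241)
        np.testing.assert_allclose(
            weibull_survival(scaled, t), weibull_survival(PBO_PFS, t) ** hr, atol=1e-12
        )

    def test_subgroup_scale_value(self):
        sub = apply_hazard_ratio(PBO_PFS, 0.33)
        assert sub.scale == pytest.approx(0.0400554)
        assert sub.shape == PBO_PFS.shape

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(PBO_PFS, 0.0)


class TestTransitionProbabilities:
    def test_exponential_is_memoryless(self):
        p = WeibullParams(0.05, 1.0)
        tps = [cycle_transition_prob(p, k, U) for k in (1, 5, 50, 150)]
        assert all(tp == pytest.approx(1 - math.exp(-0.05 * U)) for tp in tps)

    def test_first_cycle_value(self):
        # direct evaluation oracle: 1 - S(u)
        expected = 1.0 - math.exp(-PBO_PFS.scale * U**PBO_PFS.shape)
        assert cycle_transition_prob(PBO_PFS, 1, U) == pytest.approx(expected)
        assert expected == pytest.approx(0.106, abs=0.002)

    def test_vanishing_cycle_length_limit(self):
        assert cycle_transition_prob(PBO_PFS, 3, 1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_exhausted_curve_is_absorbing(self):
        steep = WeibullParams(5.0, 3.0)  # numerically dead after a few months
        assert cycle_transition_prob(steep, 500, 1.0) == 1.0

    def test_chained_probabilities_telescope_to_survival(self):
        K = 120
        surv = 1.0
        for k in range(1, K + 1):
            surv *= 1.0 - cycle_transition_prob(OSI_PFS, k, U)
        assert surv == pytest.approx(weibull_survival(OSI_PFS, K * U), abs=1e-12)


@st.composite
def family_and_params(draw):
    fam = draw(st.sampled_from(FAMILIES))
    a = draw(st.floats(0.001, 2.0))
    b = draw(st.floats(0.3, 3.0))
    if fam == "exponential":
        return fam, (a,)
    if fam == "gompertz":
        c = draw(st.floats(-0.05, 0.2))
        return fam, (a, c)
    if fam == "lognormal":
        return fam, (draw(st.floats(-1.0, 4.0)), b)
    if fam == "loglogistic":
        return fam, (draw(st.floats(0.5, 50.0)), b)
    return fam, (a, b)


class TestFamilyProperties:
    @hsettings(max_examples=60, deadline=None, derandomize=True)
    @given(family_and_params())
    def test_survival_is_a_proper_curve(self, fp):
        fam, params = fp
        t = np.linspace(0, 150, 301)
        s = family_survival(fam, params, t)
        assert s[0] == pytest.approx(1.0)
        assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)
        assert np.all(np.diff(s) <= 1e-9)


class TestFitting:
    def test_recovers_generating_weibull(self):
        ipd = generate_ipd(PBO_PFS, 5000, seed=1)
        fr = fit_parametric(ipd, "weibull")
        assert fr.converged
        scale, shape = fr.curve.params
        assert scale == pytest.approx(PBO_PFS.scale, rel=0.05)
        assert shape == pytest.approx(PBO_PFS.shape, rel=0.05)

    def test_matches_independent_lifelines_fit(self):
        # dual route: lifelines parameterises S(t) = exp(-(t/lambda)^rho)
        from lifelines import WeibullFitter

        ipd = generate_ipd(PBO_PFS, 2000, censor_rate=0.2,
                           max_followup_months=30, seed=9)
        mine = fit_parametric(ipd, "weibull").curve.params
        wf = WeibullFitter().fit(ipd.times, ipd.events)
        theirs = (wf.lambda_ ** -wf.rho_, wf.rho_)
        assert mine[0] == pytest.approx(theirs[0], rel=1e-3)
        assert mine[1] == pytest.approx(theirs[1], rel=1e-3)
        assert fit_parametric(ipd, "weibull").loglik == pytest.approx(
            wf.log_likelihood_, rel=1e-6
        )

    def test_weibull_nests_exponential(self):
        expo = WeibullParams(0.08, 1.0)
        ipd = generate_ipd(expo, 4000, seed=21)
        fr = fit_parametric(ipd, "weibull")
        assert fr.curve.params[1] == pytest.approx(1.0, rel=0.05)

    def test_aic_prefers_parsimony_under_true_exponential(self):
        wins = 0
        for seed in range(20):
            ipd = generate_ipd(WeibullParams(0.08, 1.0), 300, seed=seed)
            aic_e = fit_parametric(ipd, "exponential").aic
            aic_w = fit_parametric(ipd, "weibull").aic
            wins += aic_e < aic_w
        assert wins > 10

    def test_information_criteria_definitions(self):
        ipd = generate_ipd(PBO_PFS, 500, seed=2)
        fr = fit_parametric(ipd, "weibull")
        assert fr.aic == pytest.approx(2 * 2 - 2 * fr.loglik)
        assert fr.bic == pytest.approx(2 * math.log(500) - 2 * fr.loglik)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_parametric(PseudoIPD(np.array([1.0, 2.0]), np.array([1, 1])), "weibull")
        ipd = PseudoIPD(np.linspace(1, 12, 12), np.zeros(12, dtype=int))
        with pytest.raises(ValueError):
            fit_parametric(ipd, "weibull")

    def test_parameter_recovery_under_five_percent_at_n2000(self):
        errs_scale, errs_shape = [], []
        for seed in range(20):
            ipd = generate_ipd(PBO_PFS, 2000, seed=100 + seed)
            scale, shape = fit_parametric(ipd, "weibull").curve.params
            errs_scale.append(abs(scale / PBO_PFS.scale - 1))
            errs_shape.append(abs(shape / PBO_PFS.shape - 1))
        assert np.median(errs_scale) < 0.05
        assert np.median(errs_shape) < 0.05


class TestFamilySelection:
    def test_weibull_data_selects_weibull(self):
        ipd = generate_ipd(WeibullParams(0.000005603, 2.931), 3000, seed=7)
        best = select_best_family(ipd)
        assert best.curve.family == "weibull"
        assert list(best.ranked_table.aic) == sorted(best.ranked_table.aic)

    def test_lognormal_data_selects_lognormal(self):
        rng = np.random.default_rng(13)
        times = np.exp(rng.normal(2.0, 0.75, size=3000))
        ipd = PseudoIPD(times=times, events=np.ones(3000, dtype=int))
        assert select_best_family(ipd).curve.family == "lognormal"

    def test_single_family_menu(self):
        ipd = generate_ipd(PBO_PFS, 400, seed=3)
        best = select_best_family(ipd, families=("gompertz",))
        assert best.curve.family == "gompertz"

    def test_ranked_table_has_export_columns(self):
        ipd = generate_ipd(PBO_PFS, 400, seed=3)
        table = select_best_family(ipd).ranked_table
        assert {"family", "params", "loglik", "aic", "bic"} <= set(table.columns)
        assert len(table) == len(FAMILIES)
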