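"""Cohort trace, accrual rules, discounting, engine conventions."""
import numpy as np
import pytest

from osicea.cohort import (
    CohortTrace,
    Conventions,
    accumulate_outcomes,
    compute_trace,
    run_strategy,
)
from osicea.params import (
    ArmSurvival,
    CountryInputs,
    ModelSettings,
    UtilityInputs,
    WeibullParams,
)
from osicea.survival import weibull_survival


def _free_country(r=0.0):
    return CountryInputs(
        country_label="toy",
        drug_cost_per_cycle=0.0,
        ae_cost_oneoff={"osimertinib": 0.0, "placebo": 0.0},
        lab_cost_per_cycle=0.0,
        radiology_cost_per_cycle=0.0,
        bsc_cost_per_cycle=0.0,
        palliative_cost_oneoff=0.0,
        discount_rate_annual=r,
        wtp_per_qaly=100000.0,
        subsequent_therapy_rate={"osimertinib": 0.294, "placebo": 0.781},
    )


class TestTrace:
    def test_cohort_starts_progression_free(self, bundle, settings):
        tr = compute_trace(bundle.arms["osimertinib"], settings)
        assert (tr.pfs[0], tr.pd[0], tr.death[0]) == (1.0, 0.0, 0.0)

    def test_occupancy_conserved_and_death_monotone(self, bundle, settings):
        for arm in bundle.arms.values():
            for structure in ("partitioned", "product", "chain"):
                tr = compute_trace(arm, settings, Conventions(structure=structure))
                np.testing.assert_allclose(tr.pfs + tr.pd + tr.death, 1.0, atol=1e-9)
                assert np.all(np.diff(tr.death) >= -1e-12)

    def test_over_99_percent_dead_at_horizon_in_both_arms(self, bundle, settings):
        for arm in bundle.arms.values():
            tr = compute_trace(arm, settings)
            assert tr.death[-1] > 0.99

    def test_partitioned_pd_matches_direct_formula(self, bundle, settings):
        arm = bundle.arms["placebo"]
        tr = compute_trace(arm, settings, Conventions(structure="partitioned"))
        s_os = weibull_survival(arm.os, tr.t_months)
        s_pfs = weibull_survival(arm.pfs, tr.t_months)
        expected = np.where(s_pfs < s_os, s_os - s_pfs, 0.0)
        np.testing.assert_allclose(tr.pd, expected, atol=1e-12)

    def test_chain_realisation_equals_partitioned(self, bundle, settings):
        # per-cycle transition probabilities telescope back to the curves
        for arm in bundle.arms.values():
            a = compute_trace(arm, settings, Conventions(structure="partitioned"))
            b = compute_trace(arm, settings, Conventions(structure="chain"))
            np.testing.assert_allclose(a.pfs, b.pfs, atol=1e-12)
            np.testing.assert_allclose(a.pd, b.pd, atol=1e-12)

    def test_product_occupancy_never_exceeds_either_curve(self, bundle, settings):
        arm = bundle.arms["osimertinib"]
        tr = compute_trace(arm, settings, Conventions(structure="product"))
        s_os = weibull_survival(arm.os, tr.t_months)
        s_pfs = weibull_survival(arm.pfs, tr.t_months)
        assert np.all(tr.pfs <= np.minimum(s_os, s_pfs) + 1e-12)

    def test_malformed_occupancy_rejected(self):
        with pytest.raises(AssertionError):
            CohortTrace(
                arm_label="bad",
                t_months=np.array([0.0, 1.0]),
                t_years=np.array([0.0, 1 / 12]),
                pfs=np.array([1.0, 0.8]),
                pd=np.array([0.0, 0.3]),  # sums to 1.1
                death=np.array([0.0, 0.0]),
            )


class TestAccrual:
    def test_qalys_equal_lys_with_flat_unit_utility(self, bundle, settings, flat_utilities):
        tr = compute_trace(bundle.arms["placebo"], settings)
        out = accumulate_outcomes(tr, _free_country(0.0), flat_utilities, "placebo", settings)
        assert out.total_qaly == pytest.approx(out.total_ly, abs=1e-9)
        assert out.total_cost == 0.0

    def test_toy_two_cycle_trace_hand_identity(self):
        settings = ModelSettings(cycle_length_days=28, horizon_years=0.2, n_cycles=2)
        tr = CohortTrace(
            arm_label="placebo",
            t_months=np.array([0.0, 1.0, 2.0]) * settings.months_per_cycle,
            t_years=np.array([0.0, 1.0, 2.0]) * settings.years_per_cycle,
            pfs=np.ones(3),
            pd=np.zeros(3),
            death=np.zeros(3),
        )
        out = accumulate_outcomes(
            tr, _free_country(0.0), UtilityInputs(0.5, 0.5), "placebo", settings,
            Conventions(accrual="end"),
        )
        assert out.total_qaly == pytest.approx(2 * settings.years_per_cycle * 0.5)

    def test_doubling_drug_cost_touches_only_costs(self, bundle, settings):
        from dataclasses import replace

        arm = bundle.arms["osimertinib"]
        c1 = bundle.country("usa")
        c2 = replace(c1, drug_cost_per_cycle=2 * c1.drug_cost_per_cycle)
        o1 = run_strategy(arm, c1, bundle.utilities, settings)
        o2 = run_strategy(arm, c2, bundle.utilities, settings)
        assert o2.total_cost > o1.total_cost
        assert o2.total_ly == o1.total_ly
        assert o2.total_qaly == o1.total_qaly

    def test_discounting_strictly_shrinks_every_outcome(self, bundle, settings):
        from dataclasses import replace

        arm = bundle.arms["osimertinib"]
        c0 = replace(bundle.country("usa"), discount_rate_annual=0.0)
        c5 = replace(bundle.country("usa"), discount_rate_annual=0.05)
        o0 = run_strategy(arm, c0, bundle.utilities, settings)
        o5 = run_strategy(arm, c5, bundle.utilities, settings)
        assert o0.total_cost > o5.total_cost
        assert o0.total_ly > o5.total_ly
        assert o0.total_qaly > o5.total_qaly

    def test_discounted_never_exceeds_undiscounted(self, bundle, settings):
        out = run_strategy(
            bundle.arms["placebo"], bundle.country("china"), bundle.utilities, settings
        )
        assert out.total_cost <= out.undiscounted_cost
        assert out.total_ly <= out.undiscounted_ly
        assert out.total_qaly <= out.undiscounted_qaly

    def test_half_cycle_switch_changes_less_than_one_cycle_accrual(self, bundle, settings):
        arm = bundle.arms["osimertinib"]
        country = bundle.country("usa")
        conv_tr = Conventions(accrual="halfcycle")
        conv_end = Conventions(accrual="end")
        a = run_strategy(arm, country, bundle.utilities, settings, conv_tr)
        b = run_strategy(arm, country, bundle.utilities, settings, conv_end)
        one_cycle_ly = settings.years_per_cycle
        one_cycle_cost = country.drug_cost_per_cycle + country.lab_cost_per_cycle
        assert abs(a.total_ly - b.total_ly) < one_cycle_ly
        assert abs(a.total_cost - b.total_cost) < one_cycle_cost

    def test_mismatched_settings_rejected(self, bundle, settings):
        tr = compute_trace(bundle.arms["placebo"], settings)
        other = ModelSettings(horizon_years=7.5, n_cycles=100)
        with pytest.raises(ValueError, match="cycles"):
            accumulate_outcomes(tr, bundle.country("usa"), bundle.utilities,
                                "placebo", other)

    def test_ae_burden_hits_treated_arm_once(self, bundle, settings):
        # placebo carries no AE cost or disutility; the treated arm's AE
        # QALY loss is a one-off, so totals differ by a constant offset
        usa = bundle.country("usa")
        out_t = run_strategy(bundle.arms["osimertinib"], usa, bundle.utilities, settings)
        assert out_t.ledger.cost_ae.iloc[0] > 0
        assert (out_t.ledger.cost_ae.iloc[1:] == 0).all()
        out_p = run_strategy(bundle.arms["placebo"], usa, bundle.utilities, settings)
        assert (out_p.ledger.cost_ae == 0).all()


class TestBaseCaseLevels:
    """Reference totals for the two payer perspectives."""

    @pytest.mark.parametrize(
        "country, arm, cost, ly, qaly",
        [
            ("usa", "osimertinib", 898107, 5.11, 3.71),
            ("usa", "placebo", 719154, 4.66, 3.15),
            ("china", "osimertinib", 49565, 4.80, 3.49),
            ("china", "placebo", 31692, 4.40, 2.98),
        ],
    )
    def test_strategy_totals_reproduce_reference(self, bundle, settings, country,
                                                 arm, cost, ly, qaly):
        from osicea.analysis import conventions_for

        out = run_strategy(
            bundle.arms[arm], bundle.country(country), bundle.utilities,
            settings, conventions_for(bundle, country),
        )
        assert out.total_cost == pytest.approx(cost, rel=0.10)
        assert out.total_ly == pytest.approx(ly, rel=0.10)
        assert out.total_qaly == pytest.approx(qaly, rel=0.10)
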