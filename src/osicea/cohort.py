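"""Three-state cohort engine: trace, accrual, discounting.

States are progression-free (PFS), progressed disease (PD) and death.
Occupancy is read directly off the two extrapolated curves (partitioned
survival): death(t) = 1 - S_OS(t), pfs(t) = min(S_PFS(t), S_OS(t)), and PD
takes the remainder.  A transition-probability chain realisation and a
product-form occupancy (independent risks, as a decision-tree engine
evaluates them) are available behind the ``structure`` switch.

Accounting conventions that published cohort models frequently leave
unstated (accrual point within a cycle, the cycle-vs-month time grid,
where monitoring costs accrue, how post-progression therapy is priced) are
collected in :class:`Conventions`; the defaults are the calibrated set that
reproduces the reference base case, and every switch is reported in run
manifests.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .params import (
    PLACEBO,
    ArmSurvival,
    CountryInputs,
    ModelSettings,
    UtilityInputs,
)
from .survival import weibull_survival

__all__ = ["Conventions", "CohortTrace", "OutcomeSummary", "compute_trace",
           "accumulate_outcomes", "run_strategy"]


@dataclass(frozen=True)
class Conventions:
    """Flagged accrual/accounting switches of the cohort engine."""

    #: partitioned | chain | product — how state occupancy is derived
    structure: Literal["partitioned", "chain", "product"] = "partitioned"
    #: end | start | halfcycle — where within a cycle rewards are accrued
    accrual: Literal["end", "start", "halfcycle"] = "halfcycle"
    #: exact  — a 4-week cycle advances curve time, rewards and discounting
    #:          by 28 days;
    #: cycle_as_month — curve time advances 28 days per cycle but each cycle
    #:          accrues 1/12 year and discounts by 1/12 year (the cycle is
    #:          book-kept as a calendar month)
    time_grid: Literal["exact", "cycle_as_month"] = "exact"
    #: none | pfs | pfs_pd | treated_pfs — states (and arms) in which
    #: monitoring costs accrue; treated_pfs restricts them to on-treatment
    #: (drug-receiving) progression-free cycles
    monitoring_site: Literal["none", "pfs", "pfs_pd", "treated_pfs"] = "none"
    #: which monitoring components are billed where monitoring accrues
    monitoring_components: Literal["both", "lab", "radiology"] = "both"
    #: rate_weighted: PD costs rate*drug + (1-rate)*BSC per cycle;
    #: rate_only: rate*drug; bsc_all: rate*drug + BSC for everyone
    pd_cost_rule: Literal["rate_weighted", "rate_only", "bsc_all"] = "rate_weighted"
    #: all_deaths | none — one-off terminal-care cost attached to the death
    #: increment of every cycle, or omitted
    palliative: Literal["all_deaths", "none"] = "all_deaths"
    #: cycle: recurring costs are priced once per booked cycle;
    #: calendar: when cycles are book-kept as calendar months
    #: (time_grid="cycle_as_month") a 28-day price recurs 365.25/336 times
    #: per booked month, so recurring per-cycle costs scale by that factor
    cost_basis: Literal["cycle", "calendar"] = "cycle"

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONVENTIONS = Conventions()


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one strategy arm."""

    arm_label: str
    t_months: np.ndarray  # curve time at each cycle boundary, length N+1
    t_years: np.ndarray   # reward/discount time at each boundary
    pfs: np.ndarray
    pd: np.ndarray
    death: np.ndarray

    def __post_init__(self) -> None:
        occ = self.pfs + self.pd + self.death
        if not np.allclose(occ, 1.0, atol=1e-9):
            raise AssertionError("state occupancy must sum to 1 at every cycle")
        if np.any(np.diff(self.death) < -1e-12):
            raise AssertionError("death occupancy must be non-decreasing")
        for name in ("pfs", "pd", "death"):
            v = getattr(self, name)
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise AssertionError(f"{name} occupancy must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return len(self.t_months) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.t_months)),
                "t_months": self.t_months,
                "t_years": self.t_years,
                "pfs": self.pfs,
                "pd": self.pd,
                "death": self.death,
            }
        )


@dataclass
class OutcomeSummary:
    """Discounted and undiscounted totals for one strategy and country."""

    arm_label: str
    country_label: str
    total_cost: float
    total_ly: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_ly: float
    undiscounted_qaly: float
    ledger: pd.DataFrame  # per-cycle cost/QALY contributions by category
    conventions: Conventions = DEFAULT_CONVENTIONS

    def __post_init__(self) -> None:
        for disc, undisc in (
            (self.total_cost, self.undiscounted_cost),
            (self.total_ly, self.undiscounted_ly),
            (self.total_qaly, self.undiscounted_qaly),
        ):
            if disc < 0 or undisc < 0:
                raise AssertionError("outcome totals must be non-negative")
            if disc > undisc + 1e-9:
                raise AssertionError("discounted total exceeds undiscounted")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm_label,
            "country": self.country_label,
            "cost": self.total_cost,
            "ly": self.total_ly,
            "qaly": self.total_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_ly": self.undiscounted_ly,
            "undiscounted_qaly": self.undiscounted_qaly,
        }


def compute_trace(
    arm: ArmSurvival,
    settings: ModelSettings,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> CohortTrace:
    """State occupancy at every cycle boundary over the model horizon.

    The whole cohort starts progression-free; death occupancy follows the
    OS curve and is therefore non-decreasing by construction.
    """
    n = settings.n_cycles
    u = settings.months_per_cycle
    k = np.arange(n + 1, dtype=float)
    t_months = k * u
    if conventions.time_grid == "cycle_as_month":
        t_years = k / 12.0
    else:
        t_years = k * settings.years_per_cycle

    s_os = np.asarray(weibull_survival(arm.os, t_months))
    s_pfs = np.asarray(weibull_survival(arm.pfs, t_months))

    death = 1.0 - s_os
    if conventions.structure in ("partitioned", "chain"):
        # The chain realisation (per-cycle transition probabilities from the
        # two curves, death applied to all alive) telescopes back to exactly
        # these occupancies while the curves do not cross; with crossing
        # curves both clamp PFS at overall survival.
        pfs = np.minimum(s_pfs, s_os)
    elif conventions.structure == "product":
        pfs = s_pfs * s_os  # independent progression and death risks
    else:  # pragma: no cover
        raise ValueError(f"unknown structure {conventions.structure!r}")
    pd_state = np.clip(s_os - pfs, 0.0, 1.0)

    return CohortTrace(
        arm_label=arm.arm_label,
        t_months=t_months,
        t_years=t_years,
        pfs=pfs,
        pd=pd_state,
        death=death,
    )


def _accrual_weights(x: np.ndarray, accrual: str) -> np.ndarray:
    """Per-cycle state membership used for rewards, from boundary occupancy."""
    if accrual == "end":
        return x[1:]
    if accrual == "start":
        return x[:-1]
    if accrual == "halfcycle":
        return 0.5 * (x[:-1] + x[1:])
    raise ValueError(f"unknown accrual {accrual!r}")


def _discount_factors(t_years: np.ndarray, rate: float, accrual: str) -> np.ndarray:
    """Discount factor per cycle, evaluated at the accrual point."""
    if accrual == "end":
        t = t_years[1:]
    elif accrual == "start":
        t = t_years[:-1]
    else:
        t = 0.5 * (t_years[:-1] + t_years[1:])
    return (1.0 + rate) ** (-t)


def accumulate_outcomes(
    trace: CohortTrace,
    country: CountryInputs,
    utilities: UtilityInputs,
    arm_label: str | None = None,
    settings: ModelSettings | None = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> OutcomeSummary:
    """Accrue discounted costs, life-years and QALYs over a cohort trace.

    Per cycle: PFS members accrue on-treatment drug cost (treated arm only)
    plus any monitoring costs and the PFS utility; PD members accrue
    post-discontinuation therapy priced by ``pd_cost_rule`` and the PD
    utility; the cycle's death increment accrues the one-off terminal-care
    cost.  The adverse-event cost and the incidence-weighted AE disutility
    are one-off hits at model entry (treated arm only, as priced).
    """
    arm_label = arm_label or trace.arm_label
    settings = settings or ModelSettings()
    if trace.n_cycles != settings.n_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but settings expect {settings.n_cycles}"
        )
    u_years = 1.0 / 12.0 if conventions.time_grid == "cycle_as_month" else settings.years_per_cycle
    # half_cycle_correction=False demotes trapezoid accrual to end-of-cycle
    accrual = conventions.accrual
    if not settings.half_cycle_correction and accrual == "halfcycle":
        accrual = "end"

    w_pfs = _accrual_weights(trace.pfs, accrual)
    w_pd = _accrual_weights(trace.pd, accrual)
    d_death = np.diff(trace.death)  # death increment per cycle

    r_eff = country.discount_rate_annual
    r_cost = country.effective_cost_rate()
    v_eff = _discount_factors(trace.t_years, r_eff, accrual)
    v_cost = _discount_factors(trace.t_years, r_cost, accrual)
    ones = np.ones_like(v_eff)

    on_treatment = arm_label != PLACEBO
    rate = country.subsequent_therapy_rate.get(arm_label, 0.0)

    # recurring 28-day prices recur 365.25/336 times per booked month
    recur = 1.0
    if conventions.cost_basis == "calendar" and conventions.time_grid == "cycle_as_month":
        recur = (1.0 / 12.0) / settings.years_per_cycle

    # --- per-cycle cost components (undiscounted per-cycle amounts) -------
    drug_pfs = (country.drug_cost_per_cycle if on_treatment else 0.0) * w_pfs * recur

    if conventions.monitoring_components == "lab":
        monitoring_cycle = country.lab_cost_per_cycle
    elif conventions.monitoring_components == "radiology":
        monitoring_cycle = country.radiology_cost_per_cycle
    else:
        monitoring_cycle = country.lab_cost_per_cycle + country.radiology_cost_per_cycle
    if conventions.monitoring_site == "pfs":
        monitoring = monitoring_cycle * w_pfs * recur
    elif conventions.monitoring_site == "pfs_pd":
        monitoring = monitoring_cycle * (w_pfs + w_pd) * recur
    elif conventions.monitoring_site == "treated_pfs":
        monitoring = monitoring_cycle * w_pfs * recur * (1.0 if on_treatment else 0.0)
    else:  # none
        monitoring = np.zeros_like(w_pfs)

    if conventions.pd_cost_rule == "rate_weighted":
        pd_unit = rate * country.drug_cost_per_cycle + (1.0 - rate) * country.bsc_cost_per_cycle
    elif conventions.pd_cost_rule == "rate_only":
        pd_unit = rate * country.drug_cost_per_cycle
    else:  # bsc_all
        pd_unit = rate * country.drug_cost_per_cycle + country.bsc_cost_per_cycle
    pd_cost = pd_unit * w_pd * recur

    palliative = (
        country.palliative_cost_oneoff * d_death
        if conventions.palliative == "all_deaths"
        else np.zeros_like(d_death)
    )

    ae_cost = np.zeros_like(w_pfs)
    ae_cost[0] = country.ae_cost_oneoff.get(arm_label, 0.0)

    # --- per-cycle effect components --------------------------------------
    ly = (w_pfs + w_pd) * u_years
    qaly = (w_pfs * utilities.u_pfs + w_pd * utilities.u_pd) * u_years
    ae_qaly = np.zeros_like(qaly)
    if on_treatment:
        ae_qaly[0] = utilities.entry_ae_qaly_loss(u_years)

    def _tot(x: np.ndarray, v: np.ndarray) -> float:
        return float(np.sum(x * v))

    cost_cols = {
        "drug": drug_pfs,
        "monitoring": monitoring,
        "post_progression": pd_cost,
        "palliative": palliative,
        "ae": ae_cost,
    }
    total_cost = sum(_tot(x, v_cost) for x in cost_cols.values())
    undisc_cost = sum(_tot(x, ones) for x in cost_cols.values())
    total_ly = _tot(ly, v_eff)
    total_qaly = _tot(qaly, v_eff) - _tot(ae_qaly, v_eff)
    undisc_ly = _tot(ly, ones)
    undisc_qaly = _tot(qaly, ones) - _tot(ae_qaly, ones)

    ledger = pd.DataFrame(
        {
            "cycle": np.arange(1, trace.n_cycles + 1),
            "discount_effect": v_eff,
            "discount_cost": v_cost,
            **{f"cost_{k}": v for k, v in cost_cols.items()},
            "ly": ly,
            "qaly": qaly - ae_qaly,
        }
    )

    return OutcomeSummary(
        arm_label=arm_label,
        country_label=country.country_label,
        total_cost=total_cost,
        total_ly=total_ly,
        total_qaly=max(total_qaly, 0.0),
        undiscounted_cost=undisc_cost,
        undiscounted_ly=undisc_ly,
        undiscounted_qaly=max(undisc_qaly, 0.0),
        ledger=ledger,
        conventions=conventions,
    )


def run_strategy(
    arm: ArmSurvival,
    country: CountryInputs,
    utilities: UtilityInputs,
    settings: ModelSettings | None = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> OutcomeSummary:
    """Trace + accrual for one strategy arm; deterministic."""
    settings = settings or ModelSettings()
    trace = compute_trace(arm, settings, conventions)
    return accumulate_outcomes(trace, country, utilities, arm.arm_label, settings, conventions)
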