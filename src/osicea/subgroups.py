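"""Subgroup cost-effectiveness driven by PFS hazard ratios.

The trial reports, per subgroup, only the PFS hazard ratio of treatment
vs. control.  Each subgroup is therefore modelled by proportional-hazards
rescaling of the progression-free survival baseline: the treated arm's
subgroup PFS curve is the control-arm PFS curve raised to the power of the
subgroup hazard ratio (Weibull: scale * hr, shape unchanged), while both
overall-survival curves, all costs and all utilities stay at their
base-case values.  An alternative realisation that rescales the treated
arm's own fitted PFS curve by hr / hr_overall is available behind
``mode="treated_rescaled"``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import run_base_case
from .params import OSIMERTINIB, ArmSurvival, ParameterBundle, SubgroupSpec
from .survival import apply_hazard_ratio
from .uncertainty import run_psa

__all__ = ["SubgroupResult", "subgroup_bundle", "analyze_subgroup", "run_all_subgroups"]

#: overall trial PFS hazard ratio, used only by the treated_rescaled mode
OVERALL_PFS_HR = 0.19


@dataclass
class SubgroupResult:
    """Incremental outcomes for one subgroup in one country."""

    subgroup_label: str
    country_label: str
    pfs_hr: float | None
    icer_per_qaly: float | str | None
    inhb: float | None
    delta_cost: float | None
    delta_qaly: float | None
    prob_cost_effective: float | None  # at the country's WTP; None if no PSA

    @property
    def is_na(self) -> bool:
        return self.pfs_hr is None


def subgroup_bundle(
    bundle: ParameterBundle, hr: float, mode: str = "placebo_reference"
) -> ParameterBundle:
    """A bundle whose treated-arm PFS curve reflects the subgroup HR."""
    new = bundle.copy()
    if mode == "placebo_reference":
        pfs = apply_hazard_ratio(bundle.arms["placebo"].pfs, hr)
    elif mode == "treated_rescaled":
        pfs = apply_hazard_ratio(bundle.arms[OSIMERTINIB].pfs, hr / OVERALL_PFS_HR)
    else:
        raise ValueError(f"unknown subgroup mode {mode!r}")
    new.arms[OSIMERTINIB] = ArmSurvival(
        arm_label=OSIMERTINIB, os=bundle.arms[OSIMERTINIB].os, pfs=pfs
    )
    return new


def analyze_subgroup(
    spec: SubgroupSpec,
    bundle: ParameterBundle,
    country_label: str,
    psa_draws: int = 0,
    seed: int = 0,
    mode: str = "placebo_reference",
) -> SubgroupResult:
    """Rerun the full pipeline for one subgroup in one country.

    ``psa_draws > 0`` additionally estimates the probability that the
    treated strategy is cost-effective at the country's WTP threshold
    (a reduced number of draws is usually sufficient for this column).
    """
    country_label = country_label.lower()
    if spec.is_na:
        return SubgroupResult(
            subgroup_label=spec.subgroup_label,
            country_label=country_label,
            pfs_hr=None,
            icer_per_qaly=None,
            inhb=None,
            delta_cost=None,
            delta_qaly=None,
            prob_cost_effective=None,
        )
    sub = subgroup_bundle(bundle, spec.pfs_hr, mode=mode)
    res = run_base_case(sub, country_label).incremental
    prob = None
    if psa_draws > 0:
        prob = run_psa(sub, country_label, n_draws=psa_draws, seed=seed).prob_cost_effective
    return SubgroupResult(
        subgroup_label=spec.subgroup_label,
        country_label=country_label,
        pfs_hr=spec.pfs_hr,
        icer_per_qaly=res.icer_per_qaly,
        inhb=res.inhb,
        delta_cost=res.delta_cost,
        delta_qaly=res.delta_qaly,
        prob_cost_effective=prob,
    )


def run_all_subgroups(
    bundle: ParameterBundle,
    countries: tuple[str, ...] | None = None,
    psa_draws: int = 0,
    seed: int = 0,
    mode: str = "placebo_reference",
) -> pd.DataFrame:
    """Subgroup table across countries; rows without an HR carry NA flags."""
    countries = countries or tuple(bundle.countries)
    rows = []
    for spec in bundle.subgroups:
        for cl in countries:
            r = analyze_subgroup(spec, bundle, cl, psa_draws=psa_draws, seed=seed, mode=mode)
            rows.append(
                {
                    "subgroup": r.subgroup_label,
                    "country": r.country_label,
                    "pfs_hr": r.pfs_hr if r.pfs_hr is not None else np.nan,
                    "icer_per_qaly": (
                        r.icer_per_qaly if isinstance(r.icer_per_qaly, (float, str)) else np.nan
                    ),
                    "inhb": r.inhb if r.inhb is not None else np.nan,
                    "delta_cost": r.delta_cost if r.delta_cost is not None else np.nan,
                    "delta_qaly": r.delta_qaly if r.delta_qaly is not None else np.nan,
                    "prob_cost_effective": (
                        r.prob_cost_effective if r.prob_cost_effective is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
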