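"""Base-case orchestration and named parameter overrides.

One place maps the sensitivity-analysis parameter names (the keys of
``ParameterBundle.ranges``) onto the typed inputs, so the tornado, the
scenario machinery and the probabilistic sensitivity analysis all perturb
the model through the same code path the base case uses.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .cohort import Conventions, OutcomeSummary, run_strategy
from .economics import IncrementalResult, compare
from .params import (
    OSIMERTINIB,
    PLACEBO,
    AEDisutility,
    ParameterBundle,
    ParameterError,
)

__all__ = ["BaseCaseResult", "conventions_for", "apply_overrides", "run_base_case"]


@dataclass
class BaseCaseResult:
    """Both strategies plus their incremental comparison for one country."""

    country_label: str
    summaries: dict[str, OutcomeSummary]
    incremental: IncrementalResult

    def to_dict(self) -> dict:
        return {
            "country": self.country_label,
            "strategies": {k: v.to_dict() for k, v in self.summaries.items()},
            "incremental": self.incremental.to_dict(),
        }


def conventions_for(bundle: ParameterBundle, country_label: str) -> Conventions:
    """The calibrated engine switches for one country preset."""
    raw = bundle.conventions.get(country_label.lower())
    return Conventions(**raw) if raw else Conventions()


def apply_overrides(
    bundle: ParameterBundle, overrides: Mapping[str, float]
) -> ParameterBundle:
    """A bundle with the named parameters replaced by new values.

    Keys follow the ``ranges`` naming scheme, e.g. ``usa.drug_cost``,
    ``utility.pfs``, ``incidence.pneumonitis``,
    ``rate.post_discontinuation.placebo``.  The input bundle is never
    mutated.  Unknown keys raise :class:`ParameterError`.
    """
    countries = dict(bundle.countries)
    utilities = bundle.utilities
    country_field = {
        "drug_cost": "drug_cost_per_cycle",
        "lab_cost": "lab_cost_per_cycle",
        "radiology_cost": "radiology_cost_per_cycle",
        "bsc_cost": "bsc_cost_per_cycle",
        "palliative_cost": "palliative_cost_oneoff",
        "discount_rate": "discount_rate_annual",
    }
    for key, value in overrides.items():
        parts = key.split(".")
        if parts[0] in countries and len(parts) == 2:
            c = countries[parts[0]]
            if parts[1] == "ae_cost":
                ae = dict(c.ae_cost_oneoff)
                ae[OSIMERTINIB] = float(value)
                countries[parts[0]] = replace(c, ae_cost_oneoff=ae)
            elif parts[1] in country_field:
                countries[parts[0]] = replace(c, **{country_field[parts[1]]: float(value)})
            else:
                raise ParameterError(f"unknown parameter key {key!r}")
        elif parts[0] == "utility" and len(parts) == 2 and parts[1] in ("pfs", "pd"):
            utilities = replace(utilities, **{f"u_{parts[1]}": float(value)})
        elif parts[0] in ("disutility", "incidence") and len(parts) == 2:
            found = False
            new = []
            for a in utilities.ae_disutilities:
                if a.event_label == parts[1]:
                    found = True
                    if parts[0] == "disutility":
                        a = AEDisutility(a.event_label, float(value), a.incidence)
                    else:
                        a = AEDisutility(a.event_label, a.disutility, float(value))
                new.append(a)
            if not found:
                raise ParameterError(f"unknown adverse event in key {key!r}")
            utilities = replace(utilities, ae_disutilities=tuple(new))
        elif parts[:2] == ["rate", "post_discontinuation"] and len(parts) == 3:
            arm = parts[2]
            if arm not in (OSIMERTINIB, PLACEBO):
                raise ParameterError(f"unknown arm in key {key!r}")
            for cl, c in countries.items():
                rates = dict(c.subsequent_therapy_rate)
                rates[arm] = float(value)
                countries[cl] = replace(c, subsequent_therapy_rate=rates)
        else:
            raise ParameterError(f"unknown parameter key {key!r}")
    return ParameterBundle(
        arms=bundle.arms,
        countries=countries,
        utilities=utilities,
        settings=bundle.settings,
        ranges=bundle.ranges,
        subgroups=bundle.subgroups,
        conventions=bundle.conventions,
    )


def run_base_case(
    bundle: ParameterBundle,
    country_label: str,
    conventions: Conventions | None = None,
    wtp: float | None = None,
) -> BaseCaseResult:
    """Run both strategies for one country and compare them.

    The comparison is osimertinib (comparator) vs. placebo (reference) at
    the country's willingness-to-pay threshold unless ``wtp`` overrides it.
    """
    country = bundle.country(country_label)
    conv = conventions or conventions_for(bundle, country_label)
    summaries = {
        label: run_strategy(arm, country, bundle.utilities, bundle.settings, conv)
        for label, arm in bundle.arms.items()
    }
    incremental = compare(
        summaries[PLACEBO], summaries[OSIMERTINIB], wtp or country.wtp_per_qaly
    )
    return BaseCaseResult(
        country_label=country.country_label,
        summaries=summaries,
        incremental=incremental,
    )
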