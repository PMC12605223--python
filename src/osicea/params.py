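"""Typed, validated model inputs and the structured-config (YAML) round trip.

Every number the cohort model consumes lives here: Weibull survival
parameters per arm and endpoint, per-cycle costs and one-off costs for the
two payer perspectives (USA, China), health-state utilities and adverse-event
disutilities, discount rates and willingness-to-pay thresholds, one-way
sensitivity ranges with their PSA distribution families, and the subgroup
progression-free-survival hazard ratios.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "WeibullParams",
    "ArmSurvival",
    "CountryInputs",
    "AEDisutility",
    "UtilityInputs",
    "ParamRange",
    "SubgroupSpec",
    "ModelSettings",
    "ParameterBundle",
    "expand_range",
    "load_parameters",
    "save_parameters",
    "default_bundle",
    "usa_preset",
    "china_preset",
    "ParameterError",
]

OSIMERTINIB = "osimertinib"
PLACEBO = "placebo"
DAYS_PER_YEAR = 365.25


class ParameterError(ValueError):
    """A model input failed validation; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival law S(t) = exp(-scale * t**shape), t in months.

    ``scale`` multiplies the cumulative hazard; ``shape`` is the
    dimensionless exponent (shape > 1: rising hazard, < 1: falling).
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        _require(self.scale > 0, "scale", f"must be > 0, got {self.scale}")
        _require(self.shape > 0, "shape", f"must be > 0, got {self.shape}")


@dataclass(frozen=True)
class ArmSurvival:
    """The two fitted endpoint curves (OS, PFS) for one treatment arm."""

    arm_label: str
    os: WeibullParams
    pfs: WeibullParams


@dataclass(frozen=True)
class CountryInputs:
    """Costs, discounting and the WTP threshold for one payer perspective.

    All monetary values are 2024 US dollars.  Per-cycle costs are per
    4-week model cycle as priced; one-off costs are per patient.
    ``subsequent_therapy_rate`` maps arm label to the fraction of
    progressed patients receiving post-discontinuation systemic therapy
    (the remainder receive best supportive care).
    """

    country_label: str
    drug_cost_per_cycle: float
    ae_cost_oneoff: Mapping[str, float]
    lab_cost_per_cycle: float
    radiology_cost_per_cycle: float
    bsc_cost_per_cycle: float
    palliative_cost_oneoff: float
    discount_rate_annual: float
    wtp_per_qaly: float
    subsequent_therapy_rate: Mapping[str, float]
    discount_rate_costs_annual: float | None = None  # optional split rate

    def __post_init__(self) -> None:
        lbl = self.country_label
        for name in (
            "drug_cost_per_cycle",
            "lab_cost_per_cycle",
            "radiology_cost_per_cycle",
            "bsc_cost_per_cycle",
            "palliative_cost_oneoff",
        ):
            _require(getattr(self, name) >= 0, f"{lbl}.{name}", "cost must be >= 0")
        for arm, c in self.ae_cost_oneoff.items():
            _require(c >= 0, f"{lbl}.ae_cost_oneoff[{arm}]", "cost must be >= 0")
        _require(
            0.0 <= self.discount_rate_annual <= 0.2,
            f"{lbl}.discount_rate_annual",
            f"must lie in [0, 0.2], got {self.discount_rate_annual}",
        )
        _require(self.wtp_per_qaly > 0, f"{lbl}.wtp_per_qaly", "must be > 0")
        for arm, r in self.subsequent_therapy_rate.items():
            _require(
                0.0 <= r <= 1.0,
                f"{lbl}.subsequent_therapy_rate[{arm}]",
                f"must lie in [0, 1], got {r}",
            )

    def effective_cost_rate(self) -> float:
        if self.discount_rate_costs_annual is not None:
            return self.discount_rate_costs_annual
        return self.discount_rate_annual


@dataclass(frozen=True)
class AEDisutility:
    """One grade >=3 adverse event: utility decrement and incidence."""

    event_label: str
    disutility: float
    incidence: float

    def __post_init__(self) -> None:
        _require(
            0.0 <= self.disutility <= 1.0,
            f"ae[{self.event_label}].disutility",
            "must lie in [0, 1]",
        )
        _require(
            0.0 <= self.incidence <= 1.0,
            f"ae[{self.event_label}].incidence",
            "must lie in [0, 1]",
        )


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities plus AE disutilities (treated arm only)."""

    u_pfs: float
    u_pd: float
    ae_disutilities: tuple[AEDisutility, ...] = ()

    def __post_init__(self) -> None:
        _require(0.0 <= self.u_pfs <= 1.0, "u_pfs", "must lie in [0, 1]")
        _require(0.0 <= self.u_pd <= 1.0, "u_pd", "must lie in [0, 1]")
        if self.u_pd > self.u_pfs:
            import warnings

            warnings.warn(
                "u_pd exceeds u_pfs; progressed disease is usually valued "
                "below progression-free health",
                stacklevel=2,
            )

    def entry_ae_qaly_loss(self, years_exposed: float) -> float:
        """Incidence-weighted one-off QALY decrement applied at model entry."""
        return sum(a.disutility * a.incidence for a in self.ae_disutilities) * years_exposed


@dataclass(frozen=True)
class ParamRange:
    """Baseline value with its one-way range and PSA distribution family."""

    baseline: float
    low: float
    high: float
    distribution: str = "fixed"  # beta | gamma | uniform | fixed

    def __post_init__(self) -> None:
        _require(
            self.low <= self.baseline <= self.high,
            "ParamRange",
            f"requires low <= baseline <= high, got ({self.low}, {self.baseline}, {self.high})",
        )
        _require(
            self.distribution in {"beta", "gamma", "uniform", "fixed"},
            "ParamRange.distribution",
            f"unknown family {self.distribution!r}",
        )


def expand_range(baseline: float, fraction: float = 0.20, distribution: str = "fixed") -> ParamRange:
    """Symmetric +/- ``fraction`` range around ``baseline`` (default 20%)."""
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction: must lie in (0, 1), got {fraction}")
    lo, hi = baseline * (1.0 - fraction), baseline * (1.0 + fraction)
    if baseline < 0:
        lo, hi = hi, lo
    return ParamRange(baseline=baseline, low=lo, high=hi, distribution=distribution)


@dataclass(frozen=True)
class SubgroupSpec:
    """A trial subgroup with its PFS hazard ratio (treated vs control)."""

    subgroup_label: str
    pfs_hr: float | None
    hr_ci_low: float | None = None
    hr_ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.pfs_hr is None:
            return
        _require(self.pfs_hr > 0, f"{self.subgroup_label}.pfs_hr", "must be > 0")
        if self.hr_ci_low is not None and self.hr_ci_high is not None:
            _require(
                0 < self.hr_ci_low <= self.pfs_hr <= self.hr_ci_high,
                f"{self.subgroup_label}.hr_ci",
                "requires 0 < ci_low <= hr <= ci_high",
            )

    @property
    def is_na(self) -> bool:
        return self.pfs_hr is None


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure and horizon of the cohort model."""

    cycle_length_days: float = 28.0
    horizon_years: float = 15.0
    half_cycle_correction: bool = True
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        _require(self.cycle_length_days > 0, "cycle_length_days", "must be > 0")
        _require(self.horizon_years > 0, "horizon_years", "must be > 0")
        if self.n_cycles is None:
            object.__setattr__(
                self,
                "n_cycles",
                int(math.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)),
            )
        _require(
            self.n_cycles * self.cycle_length_days
            >= self.horizon_years * DAYS_PER_YEAR - self.cycle_length_days,
            "n_cycles",
            "cycles do not cover the stated horizon",
        )

    @property
    def months_per_cycle(self) -> float:
        return self.cycle_length_days * 12.0 / DAYS_PER_YEAR

    @property
    def years_per_cycle(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass
class ParameterBundle:
    """Everything one model run needs, as loaded from a config file."""

    arms: dict[str, ArmSurvival]
    countries: dict[str, CountryInputs]
    utilities: UtilityInputs
    settings: ModelSettings
    ranges: dict[str, ParamRange] = field(default_factory=dict)
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    #: per-country engine accounting-convention switches (calibrated presets)
    conventions: dict[str, dict] = field(default_factory=dict)

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)

    def arm(self, label: str) -> ArmSurvival:
        try:
            return self.arms[label]
        except KeyError:
            raise ParameterError(f"arms: no arm labelled {label!r}") from None

    def country(self, label: str) -> CountryInputs:
        key = label.lower()
        if key not in self.countries:
            raise ParameterError(f"countries: no country labelled {label!r}")
        return self.countries[key]


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _weibull_from(d: Mapping, ctx: str) -> WeibullParams:
    for k in ("scale", "shape"):
        _require(k in d, f"{ctx}.{k}", "missing key")
    return WeibullParams(scale=float(d["scale"]), shape=float(d["shape"]))


def _get(d: Mapping, key: str, ctx: str):
    _require(key in d, f"{ctx}.{key}", "missing key")
    return d[key]


def _range_from(d: Mapping, ctx: str) -> ParamRange:
    return ParamRange(
        baseline=float(_get(d, "baseline", ctx)),
        low=float(_get(d, "low", ctx)),
        high=float(_get(d, "high", ctx)),
        distribution=str(d.get("distribution", "fixed")),
    )


def load_parameters(source: str | Path | Mapping) -> ParameterBundle:
    """Parse and validate a parameter bundle.

    ``source`` may be a mapping, a YAML string, or a path to a YAML file.
    Missing keys raise :class:`ParameterError` naming the key; out-of-bound
    values raise :class:`ParameterError` naming the field.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        raw = yaml.safe_load(text)
        _require(isinstance(raw, Mapping), "config", "top level must be a mapping")

    arms: dict[str, ArmSurvival] = {}
    for arm_label, spec in _get(raw, "survival", "config").items():
        arms[arm_label] = ArmSurvival(
            arm_label=arm_label,
            os=_weibull_from(_get(spec, "os", f"survival.{arm_label}"), f"survival.{arm_label}.os"),
            pfs=_weibull_from(
                _get(spec, "pfs", f"survival.{arm_label}"), f"survival.{arm_label}.pfs"
            ),
        )

    countries: dict[str, CountryInputs] = {}
    conventions: dict[str, dict] = {}
    for c_label, spec in _get(raw, "countries", "config").items():
        ctx = f"countries.{c_label}"
        if "conventions" in spec:
            conventions[c_label.lower()] = dict(spec["conventions"])
        countries[c_label.lower()] = CountryInputs(
            country_label=c_label.lower(),
            drug_cost_per_cycle=float(_get(spec, "drug_cost_per_cycle", ctx)),
            ae_cost_oneoff=dict(_get(spec, "ae_cost_oneoff", ctx)),
            lab_cost_per_cycle=float(_get(spec, "lab_cost_per_cycle", ctx)),
            radiology_cost_per_cycle=float(_get(spec, "radiology_cost_per_cycle", ctx)),
            bsc_cost_per_cycle=float(_get(spec, "bsc_cost_per_cycle", ctx)),
            palliative_cost_oneoff=float(_get(spec, "palliative_cost_oneoff", ctx)),
            discount_rate_annual=float(_get(spec, "discount_rate_annual", ctx)),
            wtp_per_qaly=float(_get(spec, "wtp_per_qaly", ctx)),
            subsequent_therapy_rate=dict(_get(spec, "subsequent_therapy_rate", ctx)),
            discount_rate_costs_annual=(
                float(spec["discount_rate_costs_annual"])
                if spec.get("discount_rate_costs_annual") is not None
                else None
            ),
        )

    u = _get(raw, "utilities", "config")
    utilities = UtilityInputs(
        u_pfs=float(_get(u, "u_pfs", "utilities")),
        u_pd=float(_get(u, "u_pd", "utilities")),
        ae_disutilities=tuple(
            AEDisutility(
                event_label=str(_get(a, "event", "utilities.ae_disutilities")),
                disutility=float(_get(a, "disutility", "utilities.ae_disutilities")),
                incidence=float(_get(a, "incidence", "utilities.ae_disutilities")),
            )
            for a in u.get("ae_disutilities", [])
        ),
    )

    s = raw.get("settings", {})
    settings = ModelSettings(
        cycle_length_days=float(s.get("cycle_length_days", 28)),
        horizon_years=float(s.get("horizon_years", 15)),
        half_cycle_correction=bool(s.get("half_cycle_correction", True)),
        n_cycles=s.get("n_cycles"),
    )

    ranges = {
        key: _range_from(spec, f"ranges.{key}") for key, spec in raw.get("ranges", {}).items()
    }

    subgroups = [
        SubgroupSpec(
            subgroup_label=str(_get(g, "label", "subgroups")),
            pfs_hr=(None if g.get("pfs_hr") in (None, "NA") else float(g["pfs_hr"])),
            hr_ci_low=(None if g.get("ci_low") in (None, "NA") else float(g["ci_low"])),
            hr_ci_high=(None if g.get("ci_high") in (None, "NA") else float(g["ci_high"])),
        )
        for g in raw.get("subgroups", [])
    ]

    return ParameterBundle(
        arms=arms,
        countries=countries,
        utilities=utilities,
        settings=settings,
        ranges=ranges,
        subgroups=subgroups,
        conventions=conventions,
    )


def _bundle_to_dict(bundle: ParameterBundle) -> dict:
    return {
        "survival": {
            label: {
                "os": {"scale": a.os.scale, "shape": a.os.shape},
                "pfs": {"scale": a.pfs.scale, "shape": a.pfs.shape},
            }
            for label, a in bundle.arms.items()
        },
        "countries": {
            label: {
                "drug_cost_per_cycle": c.drug_cost_per_cycle,
                "ae_cost_oneoff": dict(c.ae_cost_oneoff),
                "lab_cost_per_cycle": c.lab_cost_per_cycle,
                "radiology_cost_per_cycle": c.radiology_cost_per_cycle,
                "bsc_cost_per_cycle": c.bsc_cost_per_cycle,
                "palliative_cost_oneoff": c.palliative_cost_oneoff,
                "discount_rate_annual": c.discount_rate_annual,
                "discount_rate_costs_annual": c.discount_rate_costs_annual,
                "wtp_per_qaly": c.wtp_per_qaly,
                "subsequent_therapy_rate": dict(c.subsequent_therapy_rate),
                **(
                    {"conventions": dict(bundle.conventions[label])}
                    if label in bundle.conventions
                    else {}
                ),
            }
            for label, c in bundle.countries.items()
        },
        "utilities": {
            "u_pfs": bundle.utilities.u_pfs,
            "u_pd": bundle.utilities.u_pd,
            "ae_disutilities": [
                {"event": a.event_label, "disutility": a.disutility, "incidence": a.incidence}
                for a in bundle.utilities.ae_disutilities
            ],
        },
        "settings": {
            "cycle_length_days": bundle.settings.cycle_length_days,
            "horizon_years": bundle.settings.horizon_years,
            "half_cycle_correction": bundle.settings.half_cycle_correction,
            "n_cycles": bundle.settings.n_cycles,
        },
        "ranges": {
            key: {
                "baseline": r.baseline,
                "low": r.low,
                "high": r.high,
                "distribution": r.distribution,
            }
            for key, r in bundle.ranges.items()
        },
        "subgroups": [
            {
                "label": g.subgroup_label,
                "pfs_hr": g.pfs_hr,
                "ci_low": g.hr_ci_low,
                "ci_high": g.hr_ci_high,
            }
            for g in bundle.subgroups
        ],
    }


def save_parameters(bundle: ParameterBundle, path: str | Path) -> Path:
    """Write a bundle back to YAML; load_parameters(save(...)) round-trips."""
    path = Path(path)
    path.write_text(yaml.safe_dump(_bundle_to_dict(bundle), sort_keys=False))
    return path


def default_bundle() -> ParameterBundle:
    """The built-in parameter presets (both countries, all subgroups)."""
    with resources.files("osicea.data").joinpath("parameters.yaml").open() as fh:
        return load_parameters(yaml.safe_load(fh))


def usa_preset() -> CountryInputs:
    return default_bundle().country("usa")


def china_preset() -> CountryInputs:
    return default_bundle().country("china")
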