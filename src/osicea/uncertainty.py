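"""Deterministic and probabilistic sensitivity analysis.

* One-way (tornado) analysis: each distributed parameter is pushed to the
  ends of its range with everything else at baseline, and the ICER per
  QALY is recomputed; entries are ranked by spread.
* Scenario analysis: named health-utility overrides through the base-case
  pipeline.
* Probabilistic sensitivity analysis: joint Monte-Carlo resampling of all
  distributed parameters (Gamma for costs, Beta for utilities, adverse
  event incidences and therapy rates, Uniform for discount rates), with
  distributions parameterised by method of moments from the baseline
  (mean) and the +/-20% range (SE = (high - low) / (2 * 1.96)).  Survival
  parameters are held fixed: the published inputs assign them no
  distribution and no covariance matrix is available.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import apply_overrides, conventions_for, run_base_case
from .economics import IncrementalResult
from .params import OSIMERTINIB, PLACEBO, ParamRange, ParameterBundle

log = logging.getLogger(__name__)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "one_way_tornado",
    "scenario_analysis",
    "sample_distribution",
    "run_psa",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's one-way impact on the ICER per QALY."""

    parameter_label: str
    icer_at_low: float
    icer_at_high: float
    spread: float


def _relevant_range_keys(bundle: ParameterBundle, country_label: str) -> list[str]:
    """Range keys that can influence one country's model."""
    others = {c for c in bundle.countries if c != country_label}
    keys = []
    for key in bundle.ranges:
        prefix = key.split(".", 1)[0]
        if prefix in others:
            continue
        keys.append(key)
    return keys


def _icer_value(res: IncrementalResult) -> float:
    icer = res.icer_per_qaly
    if not isinstance(icer, float):
        raise RuntimeError(f"ICER not a ratio under this input set: {icer}")
    return icer


def one_way_tornado(
    bundle: ParameterBundle,
    country_label: str,
    ranges: dict[str, ParamRange] | None = None,
) -> pd.DataFrame:
    """Ranked one-way sensitivity table for one country.

    Returns a DataFrame (parameter, icer_at_low, icer_at_high, spread,
    icer_base) sorted by descending spread.
    """
    country_label = country_label.lower()
    ranges = ranges if ranges is not None else bundle.ranges
    base = _icer_value(run_base_case(bundle, country_label).incremental)
    rows = []
    for key in _relevant_range_keys(bundle, country_label):
        if key not in ranges:
            continue
        rng = ranges[key]
        icers = {}
        skip = False
        for side, value in (("low", rng.low), ("high", rng.high)):
            try:
                perturbed = apply_overrides(bundle, {key: value})
                icers[side] = _icer_value(
                    run_base_case(perturbed, country_label).incremental
                )
            except Exception as exc:
                log.warning("skipping %s (%s end): %s", key, side, exc)
                skip = True
        if skip:
            continue
        rows.append(
            TornadoEntry(
                parameter_label=key,
                icer_at_low=icers["low"],
                icer_at_high=icers["high"],
                spread=abs(icers["high"] - icers["low"]),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "spread", ascending=False, kind="mergesort"
    )
    df["icer_base"] = base
    return df.reset_index(drop=True)


def scenario_analysis(
    bundle: ParameterBundle,
    country_label: str,
    scenario: dict[str, float],
    scenario_label: str = "scenario",
) -> IncrementalResult:
    """Base-case pipeline under named utility overrides.

    ``scenario`` maps {"u_pfs": ..., "u_pd": ...} (either key optional);
    values must lie in [0, 1].
    """
    overrides = {}
    for k, v in scenario.items():
        if k not in ("u_pfs", "u_pd"):
            raise ValueError(f"scenario overrides utilities only, got {k!r}")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{k} must lie in [0, 1], got {v}")
        overrides[f"utility.{k.removeprefix('u_')}"] = v
    res = run_base_case(apply_overrides(bundle, overrides), country_label).incremental
    log.info("scenario %s: ICER/QALY = %s", scenario_label, res.icer_per_qaly)
    return res


#: The +/-20% bounds are read as mean +/- one standard error (a common
#: interpretation in this literature, and the one that reproduces the
#: reference probabilistic results); pass ``se_denominator=3.92`` to read
#: them as a 95% confidence interval instead.
SE_DENOMINATOR = 2.0


def sample_distribution(
    rng_range: ParamRange,
    rng: np.random.Generator,
    se_denominator: float = SE_DENOMINATOR,
) -> float:
    """One draw from a range's assigned distribution.

    Method-of-moments parameterisation with mean = baseline and
    SE = (high - low) / se_denominator; Beta falls back to Uniform (with a
    logged warning) when the implied variance is infeasible for [0, 1].
    """
    m = rng_range.baseline
    if rng_range.high == rng_range.low:
        return m
    se = (rng_range.high - rng_range.low) / se_denominator
    kind = rng_range.distribution
    if kind == "fixed":
        return m
    if kind == "uniform":
        return float(rng.uniform(rng_range.low, rng_range.high))
    if kind == "gamma":
        shape = m * m / (se * se)
        scale = se * se / m
        return float(rng.gamma(shape, scale))
    if kind == "beta":
        if se * se >= m * (1.0 - m) or not 0.0 < m < 1.0:
            log.warning(
                "beta infeasible for mean %.4g, SE %.4g; falling back to uniform", m, se
            )
            return float(rng.uniform(rng_range.low, rng_range.high))
        alpha = m * (m * (1.0 - m) / (se * se) - 1.0)
        beta = alpha * (1.0 - m) / m
        return float(rng.beta(alpha, beta))
    raise ValueError(f"unknown distribution {kind!r}")


def default_wtp_grid(country_label: str, n_points: int = 201) -> np.ndarray:
    """WTP grid for the acceptability curve (0-500k USA, 0-100k China)."""
    upper = 500_000.0 if country_label.lower() == "usa" else 100_000.0
    return np.linspace(0.0, upper, n_points)


@dataclass
class PSAResult:
    """Draws, acceptability curve and provenance of one PSA run."""

    country_label: str
    seed: int
    draws: pd.DataFrame  # sampled parameters + delta_cost, delta_qaly, inmb
    ceac: pd.DataFrame   # wtp, p_osimertinib, p_placebo
    wtp_used: float
    n_invalid: int = 0

    @property
    def prob_cost_effective(self) -> float:
        """P(comparator cost-effective) at the country's WTP threshold."""
        return float((self.draws["inmb"] > 0).mean())

    def ceac_at(self, wtp: float) -> float:
        return float(
            (wtp * self.draws["delta_qaly"] - self.draws["delta_cost"] > 0).mean()
        )


def run_psa(
    bundle: ParameterBundle,
    country_label: str,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    se_denominator: float = SE_DENOMINATOR,
) -> PSAResult:
    """Probabilistic sensitivity analysis for one country.

    Per draw every distributed parameter is resampled jointly, both
    strategies are rerun, and (delta cost, delta QALY) recorded.  The CEAC
    reports, for each willingness-to-pay value w, the fraction of draws in
    which osimertinib has positive incremental net monetary benefit
    (w * dQ - dC > 0), and the complement for placebo.  Deterministic
    under a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    country_label = country_label.lower()
    rng = np.random.default_rng(seed)
    keys = [k for k in _relevant_range_keys(bundle, country_label)
            if bundle.ranges[k].distribution != "fixed"]
    wtp = bundle.country(country_label).wtp_per_qaly
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(country_label)

    records = []
    n_invalid = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # u_pd may exceed u_pfs in a draw
        for _ in range(n_draws):
            for _attempt in range(100):
                sampled = {
                    k: sample_distribution(bundle.ranges[k], rng, se_denominator)
                    for k in keys
                }
                try:
                    perturbed = apply_overrides(bundle, sampled)
                except Exception:
                    n_invalid += 1
                    continue
                break
            else:  # pragma: no cover - would need a pathological range
                raise RuntimeError("could not draw a valid parameter set")
            res = run_base_case(perturbed, country_label).incremental
            records.append(
                {
                    **sampled,
                    "delta_cost": res.delta_cost,
                    "delta_qaly": res.delta_qaly,
                    "inmb": wtp * res.delta_qaly - res.delta_cost,
                }
            )
    draws = pd.DataFrame(records)
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    p_osi = (wtp_grid[:, None] * dq[None, :] - dc[None, :] > 0).mean(axis=1)
    ceac = pd.DataFrame(
        {"wtp": wtp_grid, "p_osimertinib": p_osi, "p_placebo": 1.0 - p_osi}
    )
    if n_invalid:
        log.info("resampled %d invalid draws", n_invalid)
    return PSAResult(
        country_label=country_label,
        seed=seed,
        draws=draws,
        ceac=ceac,
        wtp_used=wtp,
        n_invalid=n_invalid,
    )
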