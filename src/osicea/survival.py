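"""Survival mathematics for the cohort model.

Weibull evaluation and medians, proportional-hazard rescaling, per-cycle
transition probabilities, and right-censored maximum-likelihood fitting of
five candidate parametric families (exponential, Weibull, log-normal,
log-logistic, Gompertz) with AIC/BIC-based selection.

Parameterisations (t in months):

* exponential      S(t) = exp(-rate * t)
* weibull          S(t) = exp(-scale * t**shape)
* lognormal        S(t) = 1 - Phi((ln t - mu) / sigma)
* loglogistic      S(t) = 1 / (1 + (t / alpha)**beta)
* gompertz         S(t) = exp(-(b / c) * (exp(c * t) - 1)), c may be negative

The Weibull convention matches the model's input tables: ``scale``
multiplies the cumulative hazard (so a hazard ratio multiplies the scale).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .params import WeibullParams

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import PseudoIPD

log = logging.getLogger(__name__)

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
}


def weibull_survival(p: WeibullParams, t) -> np.ndarray | float:
    """S(t) = exp(-scale * t**shape); vectorised over ``t`` (months)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-p.scale * np.power(t, p.shape, where=t > 0, out=np.zeros_like(t)))
    out = np.where(t == 0, 1.0, out)
    return out if out.ndim else float(out)


def weibull_median(p: WeibullParams) -> float:
    """Closed-form median survival time, (ln 2 / scale)**(1/shape) months."""
    return (math.log(2.0) / p.scale) ** (1.0 / p.shape)


def weibull_mean(p: WeibullParams) -> float:
    """Mean survival time, scale**(-1/shape) * Gamma(1 + 1/shape) months."""
    return p.scale ** (-1.0 / p.shape) * math.gamma(1.0 + 1.0 / p.shape)


def apply_hazard_ratio(p: WeibullParams, hr: float) -> WeibullParams:
    """Proportional hazards on a Weibull: scale *= hr, shape unchanged.

    Equivalently S'(t) = S(t)**hr for every t.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return WeibullParams(scale=p.scale * hr, shape=p.shape)


def cycle_transition_prob(p: WeibullParams, k: int, cycle_months: float) -> float:
    """Probability of leaving the curve's state during cycle ``k``.

    tp(k) = 1 - S(k*u) / S((k-1)*u) for k >= 1 and cycle length u months.
    If the curve is already exhausted at the cycle start the state is
    treated as absorbingly emptied (probability 1).
    """
    if k < 1:
        raise ValueError(f"cycle index must be >= 1, got {k}")
    if cycle_months <= 0:
        raise ValueError(f"cycle length must be > 0, got {cycle_months}")
    s_prev = weibull_survival(p, (k - 1) * cycle_months)
    s_now = weibull_survival(p, k * cycle_months)
    if s_prev == 0.0:
        log.warning("survival exhausted before cycle %d; transition prob set to 1", k)
        return 1.0
    return float(min(max(1.0 - s_now / s_prev, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Parametric families: survival and log-density on natural parameters.


def family_survival(family: str, params: Sequence[float], t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if family == "exponential":
        (rate,) = params
        return np.exp(-rate * t)
    if family == "weibull":
        scale, shape = params
        return np.asarray(weibull_survival(WeibullParams(scale, shape), t))
    if family == "lognormal":
        mu, sigma = params
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
        return np.where(t == 0, 1.0, stats.norm.sf(z))
    if family == "loglogistic":
        alpha, beta = params
        return np.where(t == 0, 1.0, 1.0 / (1.0 + (np.maximum(t, 1e-300) / alpha) ** beta))
    if family == "gompertz":
        b, c = params
        if abs(c) < 1e-12:
            return np.exp(-b * t)
        return np.exp(-(b / c) * np.expm1(c * t))
    raise ValueError(f"unknown family {family!r}")


def _family_loghazard(family: str, params: Sequence[float], t: np.ndarray) -> np.ndarray:
    """log h(t) for event contributions; t > 0."""
    logt = np.log(t)
    if family == "exponential":
        (rate,) = params
        return np.full_like(t, math.log(rate))
    if family == "weibull":
        scale, shape = params
        return math.log(scale * shape) + (shape - 1.0) * logt
    if family == "lognormal":
        mu, sigma = params
        z = (logt - mu) / sigma
        return stats.norm.logpdf(z) - math.log(sigma) - logt - stats.norm.logsf(z)
    if family == "loglogistic":
        alpha, beta = params
        la = math.log(alpha)
        return (
            math.log(beta)
            + (beta - 1.0) * (logt - la)
            - la
            - np.log1p(np.exp(beta * (logt - la)))
        )
    if family == "gompertz":
        b, c = params
        return math.log(b) + c * t
    raise ValueError(f"unknown family {family!r}")


def _log_cumhazard_neg(family: str, params: Sequence[float], t: np.ndarray) -> np.ndarray:
    """-H(t) = log S(t), computed stably."""
    if family == "exponential":
        (rate,) = params
        return -rate * t
    if family == "weibull":
        scale, shape = params
        return -scale * t**shape
    if family == "lognormal":
        mu, sigma = params
        z = (np.log(t) - mu) / sigma
        return stats.norm.logsf(z)
    if family == "loglogistic":
        alpha, beta = params
        return -np.log1p((t / alpha) ** beta)
    if family == "gompertz":
        b, c = params
        if abs(c) < 1e-12:
            return -b * t
        return -(b / c) * np.expm1(c * t)
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class SurvivalCurve:
    """A fitted (or specified) parametric survival curve."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def sf(self, t) -> np.ndarray:
        return family_survival(self.family, self.params, t)

    def as_weibull(self) -> WeibullParams:
        if self.family != "weibull":
            raise ValueError(f"curve family is {self.family}, not weibull")
        return WeibullParams(*self.params)


@dataclass(frozen=True)
class FitResult:
    """One family's maximum-likelihood fit under right censoring."""

    curve: SurvivalCurve
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    diagnostics: str = ""
    ranked_table: pd.DataFrame | None = field(default=None, compare=False)


def _loglik(family: str, params: Sequence[float], times: np.ndarray, events: np.ndarray) -> float:
    # positivity requirements per family (lognormal mu may be negative)
    if family == "lognormal":
        if params[1] <= 0:
            return -np.inf
    elif params[0] <= 0 or (family not in ("exponential", "gompertz") and params[1] <= 0):
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        logS = _log_cumhazard_neg(family, params, times)
        ll = float(np.sum(logS))
        if events.any():
            ll += float(np.sum(_family_loghazard(family, params, times[events])))
    return ll if np.isfinite(ll) else -np.inf


def _transform(family: str, theta: np.ndarray) -> np.ndarray:
    """Unconstrained optimiser space -> natural parameters.

    Positive parameters are log-transformed; the Gompertz rate ``c`` is kept
    linear (it may legitimately be negative) but bounded by the optimiser.
    """
    if family == "gompertz":
        return np.array([math.exp(theta[0]), theta[1]])
    return np.exp(theta)


def _start_points(family: str, times: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
    t_ev = times[events] if events.any() else times
    med = float(np.median(t_ev))
    rate0 = max(events.sum(), 1) / float(times.sum())
    starts: list[np.ndarray] = []
    if family == "exponential":
        for f in (1.0, 0.3, 3.0):
            starts.append(np.log([rate0 * f]))
    elif family == "weibull":
        for shape0 in (1.0, 0.7, 2.0):
            scale0 = math.log(2.0) / med**shape0
            starts.append(np.log([scale0, shape0]))
    elif family == "lognormal":
        mu0 = float(np.mean(np.log(t_ev)))
        sd0 = float(np.std(np.log(t_ev))) or 1.0
        # mu stays linear in optimiser space (it may be negative)
        starts = [np.array([mu0, math.log(sd0 * f)]) for f in (1.0, 0.5, 2.0)]
    elif family == "loglogistic":
        for beta0 in (1.0, 0.7, 2.0):
            starts.append(np.log([med, beta0]))
    elif family == "gompertz":
        for c0 in (0.01, 0.05, -0.01):
            starts.append(np.array([math.log(rate0), c0]))
    return starts


def _lognormal_transform(theta: np.ndarray) -> np.ndarray:
    return np.array([theta[0], math.exp(theta[1])])  # mu linear, sigma > 0


def fit_parametric(ipd: "PseudoIPD", family: str) -> FitResult:
    """Right-censored MLE of one parametric family.

    Multi-start quasi-Newton optimisation on transformed (unconstrained)
    parameters; a non-converged fit is flagged, never raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    times = np.asarray(ipd.times, dtype=float)
    events = np.asarray(ipd.events, dtype=bool)
    if times.size < 10:
        raise ValueError("need at least 10 observations to fit")
    if not events.any():
        raise ValueError("need at least one event to fit")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")

    transform = _lognormal_transform if family == "lognormal" else lambda th: _transform(family, th)

    def neg(theta: np.ndarray) -> float:
        return -_loglik(family, transform(theta), times, events)

    best = None
    for theta0 in _start_points(family, times, events):
        try:
            res = optimize.minimize(neg, theta0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            res = optimize.minimize(neg, res.x, method="BFGS")
        except Exception:  # pragma: no cover - optimiser blow-up
            continue
        if best is None or res.fun < best.fun:
            best = res

    k = _N_PARAMS[family]
    n = times.size
    if best is None or not np.isfinite(best.fun):
        return FitResult(
            curve=SurvivalCurve(family, tuple([np.nan] * k)),
            loglik=-np.inf, aic=np.inf, bic=np.inf, n_obs=n,
            converged=False, diagnostics="all starts failed",
        )
    params = tuple(float(x) for x in transform(best.x))
    ll = -float(best.fun)
    return FitResult(
        curve=SurvivalCurve(family, params),
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        bic=k * math.log(n) - 2.0 * ll,
        n_obs=n,
        converged=bool(np.isfinite(ll)),
        diagnostics="" if np.isfinite(ll) else str(best),
    )


def select_best_family(ipd: "PseudoIPD", families: Sequence[str] = FAMILIES) -> FitResult:
    """Fit every candidate family and return the minimum-AIC fit.

    Ties are broken by BIC, then by fewer free parameters.  The returned
    result carries the full ranked comparison table in ``ranked_table``.
    """
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for fam in families:
        try:
            fr = fit_parametric(ipd, fam)
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover
            failures[fam] = str(exc)
            continue
        if fr.converged:
            fits[fam] = fr
        else:
            failures[fam] = fr.diagnostics or "did not converge"
    if not fits:
        raise RuntimeError(f"every family failed to fit: {failures}")

    table = pd.DataFrame(
        [
            {
                "family": fam,
                "params": fr.curve.params,
                "loglik": fr.loglik,
                "aic": fr.aic,
                "bic": fr.bic,
                "n_params": _N_PARAMS[fam],
            }
            for fam, fr in fits.items()
        ]
    ).sort_values(["aic", "bic", "n_params"], kind="mergesort").reset_index(drop=True)

    winner = fits[table.iloc[0]["family"]]
    return FitResult(
        curve=winner.curve,
        loglik=winner.loglik,
        aic=winner.aic,
        bic=winner.bic,
        n_obs=winner.n_obs,
        converged=winner.converged,
        ranked_table=table,
    )
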