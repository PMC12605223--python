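"""Pairwise incremental cost-effectiveness: ICER, INHB, NMB, dominance.

Definitions (for comparator vs. reference at willingness-to-pay ``wtp``):

    ICER  = dC / dE              (per QALY and per LY)
    INHB  = dQ - dC / wtp        [QALYs]
    INMB  = wtp * dQ - dC        [USD]  (= wtp * INHB)

Deltas are always taken on full-precision model totals, never on rounded
display values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import OutcomeSummary

__all__ = ["IncrementalResult", "icer", "compare", "incremental_table"]

DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective
UNDEFINED = "undefined"    # zero effect difference


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental outcomes of comparator vs. reference strategy."""

    comparator: str
    reference: str
    country_label: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | str
    icer_per_ly: float | str
    inhb: float
    nmb: float
    wtp_used: float

    def is_cost_effective(self) -> bool:
        return self.nmb > 0

    def to_dict(self) -> dict:
        return {
            "comparator": self.comparator,
            "reference": self.reference,
            "country": self.country_label,
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "inhb": self.inhb,
            "nmb": self.nmb,
            "wtp": self.wtp_used,
        }


def icer(delta_cost: float, delta_effect: float) -> float | str:
    """Exact incremental cost-effectiveness quotient, or a dominance flag.

    Sign conventions: more effect for less cost is ``dominant``; less
    effect for more cost is ``dominated``; a zero effect difference leaves
    the ratio ``undefined``.
    """
    if delta_effect == 0.0:
        return UNDEFINED
    if delta_effect > 0 and delta_cost < 0:
        return DOMINANT
    if delta_effect < 0 and delta_cost > 0:
        return DOMINATED
    return delta_cost / delta_effect


def compare(
    reference: OutcomeSummary,
    comparator: OutcomeSummary,
    wtp: float,
) -> IncrementalResult:
    """Incremental result of ``comparator`` relative to ``reference``."""
    if reference.country_label != comparator.country_label:
        raise ValueError(
            "strategies were run under different country inputs: "
            f"{reference.country_label!r} vs {comparator.country_label!r}"
        )
    if not wtp > 0 or not math.isfinite(wtp):
        raise ValueError(f"wtp must be a positive finite number, got {wtp}")
    d_cost = comparator.total_cost - reference.total_cost
    d_ly = comparator.total_ly - reference.total_ly
    d_qaly = comparator.total_qaly - reference.total_qaly
    inhb = d_qaly - d_cost / wtp
    return IncrementalResult(
        comparator=comparator.arm_label,
        reference=reference.arm_label,
        country_label=reference.country_label,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_qaly=icer(d_cost, d_qaly),
        icer_per_ly=icer(d_cost, d_ly),
        inhb=inhb,
        nmb=wtp * inhb,
        wtp_used=wtp,
    )


def incremental_table(
    summaries: dict[str, OutcomeSummary],
    result: IncrementalResult,
) -> pd.DataFrame:
    """A strategy-by-outcome table in the layout of a base-case report.

    Dollars are rounded to integers and (Q)ALYs to two decimals for
    display; the incremental columns come from the full-precision result.
    """
    rows = []
    for label, s in summaries.items():
        is_cmp = label == result.comparator
        rows.append(
            {
                "country": s.country_label,
                "strategy": label,
                "total_cost": round(s.total_cost),
                "ly": round(s.total_ly, 2),
                "qaly": round(s.total_qaly, 2),
                "icer_per_ly": (
                    round(result.icer_per_ly)
                    if is_cmp and isinstance(result.icer_per_ly, float)
                    else result.icer_per_ly if is_cmp else None
                ),
                "icer_per_qaly": (
                    round(result.icer_per_qaly)
                    if is_cmp and isinstance(result.icer_per_qaly, float)
                    else result.icer_per_qaly if is_cmp else None
                ),
                "inhb": round(result.inhb, 2) if is_cmp else None,
            }
        )
    return pd.DataFrame(rows)
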