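# osicea

Cost-utility model of **osimertinib consolidation therapy after
chemoradiotherapy in unresectable stage III EGFR-mutated NSCLC**, from the
payer perspectives of the USA and China.

The LAURA trial showed that consolidation osimertinib dramatically extends
progression-free survival in these patients (median 38.9 vs 7.3 months),
but the drug's price differs by a factor of ~25 between the two countries.
This package re-implements, as a tested and reusable Python library, a
published two-country cost-effectiveness analysis of that decision: a
three-state cohort model with Weibull survival extrapolation, incremental
cost-effectiveness and net-health-benefit outputs, deterministic and
probabilistic sensitivity analyses, hazard-ratio-driven subgroup analyses,
and a synthetic Kaplan–Meier digitisation / pseudo-IPD reconstruction
pipeline that emulates how such models obtain their survival inputs.

It is intended for health-economics researchers and students who want a
transparent, scriptable version of this class of oncology cost-utility
model — every accounting convention that such published models usually
leave implicit is an explicit, documented switch here.

## The model

Patients occupy one of three states: progression-free (PFS), progressed
disease (PD), dead.  Survival in each arm is extrapolated with Weibull
laws fitted to the trial's curves,

    S(t) = exp(−λ t^γ),   t in months,

with per-arm (λ, γ) for overall survival and progression-free survival.
State occupancy over 4-week cycles across a 15-year horizon (195 cycles)
follows the two curves; per cycle, PFS patients accrue drug and monitoring
costs and utility u_PFS = 0.791, PD patients accrue post-discontinuation
therapy (osimertinib for 29.4% / 78.1% of progressors by arm, best
supportive care otherwise) and u_PD = 0.653, and deaths accrue a one-off
terminal-care cost.  Everything is discounted annually (3% USA, 5% China).
Strategies are compared by

    ICER  = ΔCost / ΔQALY
    INHB  = ΔQALY − ΔCost / WTP      (WTP: $150,000/QALY USA; $39,632 China)

with one-way tornado analysis over ±20% parameter ranges, a 10,000-draw
probabilistic sensitivity analysis (Gamma costs, Beta utilities/rates,
Uniform discount rates) with cost-effectiveness acceptability curves, and
per-subgroup reruns in which the treated arm's PFS curve is the control
curve raised to the power of the subgroup hazard ratio.

Two calibration notes, detailed in `docs/methods.md`: the source's two OS
parameter rows are carried arm-swapped (as printed they contradict the
published life-year gain), and engine accounting conventions (cycle
bookkeeping, monitoring-cost site, PD costing) are frozen per country to
the switch sets that reproduce the published tables.

## Worked example

```python
from osicea import default_bundle
from osicea.report import base_case_report

table, results = base_case_report(default_bundle())
print(table.to_string(index=False))
```

prints

```
country    strategy  total_cost   ly  qaly  icer_per_ly  icer_per_qaly  inhb
    usa osimertinib      853276 5.02  3.67     421151.0       303725.0 -0.53
    usa     placebo      695665 4.65  3.15          NaN            NaN   NaN
  china osimertinib       47362 4.64  3.39      55267.0        36998.0  0.03
  china     placebo       30304 4.33  2.93          NaN            NaN   NaN
```

Reading the USA rows: consolidation osimertinib costs $853,276 and yields
3.67 QALYs per patient over 15 years, versus $695,665 and 3.15 QALYs under
placebo — an extra 0.52 QALYs at $303,725 each, twice the US $150,000/QALY
willingness-to-pay (negative net health benefit, −0.53 QALYs).  In China
the same survival gain costs $36,998/QALY, just under the 3×-GDP threshold
of $39,632 (INHB +0.03 QALYs): cost-effective in China, not in the USA.

The `examples/` scripts walk through each capability (base case, tornado
and scenarios, PSA/CEAC, subgroups, synthetic curve reconstruction), and
the same analyses are available from the shell:

```bash
osicea base-case
osicea psa --country usa --seed 1 --n-draws 10000 --plot
osicea subgroups --n-draws 2000
osicea simulate --n 143 --seed 7 --digitize
```

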