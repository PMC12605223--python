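# Methods

## Decision problem and model structure

The model evaluates consolidation osimertinib versus placebo in patients
with unresectable stage III EGFR-mutated NSCLC who have not progressed
after chemoradiotherapy, from the payer perspectives of the USA and China.
It is a cohort model with three mutually exclusive states — progression-free
(PFS), progressed disease (PD), and death — run over 4-week cycles for a
15-year horizon (195 cycles), by which point more than 99% of the cohort
has died in both arms (asserted, not assumed).

State occupancy is derived from two per-arm parametric survival curves,
overall survival (OS) and progression-free survival (PFS), each Weibull:

    S(t) = exp(−λ t^γ),  t in months (λ = scale, γ = shape).

Death occupancy is 1 − S_OS(t) in every engine variant.  Three occupancy
rules are implemented behind `Conventions.structure`:

* `product` (default): PFS occupancy = S_PFS(t)·S_OS(t).  This is what a
  decision-tree Markov engine produces when the per-cycle progression and
  death risks are applied as independent competing branches, and it is the
  only rule consistent with the PFS-state durations implied by the
  reference base-case table (e.g. ~2.7 discounted PFS-years for the US
  treated arm; the partitioned min() rule gives ~3.6).
* `partitioned`: PFS = min(S_PFS, S_OS), the textbook partitioned-survival
  reading.
* `chain`: per-cycle transition probabilities 1 − S(ku)/S((k−1)u) chained
  forward; telescopes back to `partitioned` exactly (regression-tested).

## Survival inputs and the OS row assignment

The four Weibull parameter pairs are carried in the built-in presets.
The two PFS rows reproduce the trial medians under the S(t) = exp(−λt^γ)
convention (treated 35.7 vs reported 38.9 months; control 6.09 vs 7.3),
which fixes the parameterisation.  The two OS rows, however, are carried
**swapped between arms** relative to how the source table labels them:
as printed, the "treated" OS curve (λ=5.603e-6, γ=2.931) has mean survival
55.2 months versus 60.8 for the "control" curve (λ=1.721e-4, γ=2.050),
which would make consolidation therapy *shorten* life — contradicting the
source's own reported gain of +0.45 life-years (5.40 months; the swapped
means differ by 5.47 months) and all four of its life-year table cells.
The presets therefore assign the 2.050-shape curve to osimertinib.

## Time grid and accounting conventions

Published cohort models of this type leave several accrual conventions
unstated; here each is an explicit switch on `Conventions`, calibrated
once against the reference tables and frozen in the per-country presets
(every run manifest records the switch set):

* **Cycle bookkeeping** (`time_grid="cycle_as_month"`): curve time
  advances 28 days per cycle, but each cycle is book-kept as one calendar
  month for rewards and discounting (1/12 year per cycle, discount
  exponent k/12).  This cycle≈month approximation — pervasive in
  spreadsheet and TreeAge practice — reproduces all four reference
  life-year cells within 1.8%; exact 28-day bookkeeping underestimates
  every LY/QALY cell by ~8–10%.
* **Accrual point** (`accrual`): start-of-cycle (USA preset),
  end-of-cycle (China preset); trapezoid half-cycle accrual is available
  and is what `ModelSettings.half_cycle_correction` toggles.
* **Monitoring costs** (`monitoring_site`, `monitoring_components`):
  laboratory monitoring accrues during on-treatment PFS cycles only (USA)
  or during PFS in both arms (China).  Radiology is priced in the inputs
  but unused by both calibrated base cases — the control arm's China
  total (31,692 USD) is arithmetically incompatible with any per-cycle
  radiology accrual; the parameter still participates (inertly) in the
  tornado and PSA.
* **Post-progression costing** (`pd_cost_rule`): per PD cycle,
  rate×drug + (1−rate)×BSC (USA) or rate×drug only (China), where `rate`
  is the arm's post-discontinuation therapy uptake (0.294 treated, 0.781
  control) and BSC is best supportive care.
* **Terminal care** (`palliative`): the one-off palliative cost attaches
  to each cycle's death increment.
* Adverse-event management cost and the incidence-weighted AE disutility
  are one-off hits at model entry, treated arm only (grade ≥3 events at
  1.4% incidence each; the source prices no AE burden for the control
  arm and states no duration).

No single convention set fits both countries' published tables — the two
country models evidently differed in these details — hence per-country
switch sets.  With them, all USA reference quantities (four table cells,
both ICERs, both tornado extremes, both subgroup ICERs) reproduce within
10% (most within 6%), and China's within 6% except the quantities listed
under "Known discrepancies".

## Costs, utilities, discounting

All costs are 2024 USD.  Health-state utilities are 0.791 (PFS) and 0.653
(PD).  Discounting is annual at each country's rate (3% USA, 5% China)
applied to both costs and effects; a separate cost rate
(`discount_rate_costs_annual`) is available for analyses that discount
benefits and costs at different rates.  Incremental results are always
computed from full-precision totals; display rounding (dollars to
integers, (Q)ALYs to 2 d.p.) happens only in report assembly, and a
regression test asserts the rounded-first path is not the one used.

## Sensitivity analyses

**One-way (tornado).**  Every distributed parameter is set to the ends of
its range (±20% of baseline, except discount rates which use their policy
bands 0–5% / 0–8%) with all else at baseline; entries are ranked by the
absolute ICER spread.  The PFS utility ranks first in both countries.

**Probabilistic.**  Per draw, all distributed parameters are jointly
resampled — Gamma for costs, Beta for utilities, AE incidences and
therapy-uptake rates, Uniform for discount rates — by method of moments
with mean = baseline and SE = (high − low)/2; i.e. the ±20% bounds are
read as mean ± one SE, the interpretation that reproduces the reference
probabilistic dispersion (reading them as a 95% CI, available via
`se_denominator=3.92`, gives roughly half the spread and probabilities
far from the reference).  Weibull survival parameters are held fixed: the
source assigns them no distribution and publishes no covariance matrix,
so any sampling model for them would be invented.  The CEAC reports, per
willingness-to-pay value w, the fraction of draws with positive
incremental net monetary benefit w·ΔQALY − ΔCost (201-point grids to
$500k USA / $100k China).  Draws are reproducible bit-for-bit under a
fixed seed.

**Subgroups.**  Each subgroup is characterised only by its PFS hazard
ratio; the treated arm's subgroup PFS curve is (control PFS)^hr —
Weibull scale × hr, shape unchanged — with OS curves, costs and utilities
at base case.  The alternative of rescaling the treated arm's own fitted
curve by hr/0.19 (the overall trial hazard ratio) is available via
`mode="treated_rescaled"`; both reproduce the two favourable reference
subgroup ICERs within 10%, and the operationally simpler placebo-baseline
form is the default.  Subgroup cost-effectiveness probabilities come from
a reduced-draw PSA per subgroup.

## Synthetic curve-reconstruction pipeline

The model's survival inputs originate, in studies of this kind, from
digitising published Kaplan–Meier figures and reconstructing pseudo
individual-patient data (IPD).  The `synthetic` module emulates that
chain with known ground truth:

1. `generate_ipd`: inverse-CDF Weibull event times with independent
   uniform plus administrative right-censoring; default cohort sizes 143
   treated / 73 control (recovered from the published post-progression
   counts 42/0.294 and 57/0.781).
2. `km_estimate`: product-limit estimator (lifelines) with numbers-at-risk
   at landmark times.
3. `digitize_emulate`: uniform-grid resampling plus Gaussian survival-axis
   noise, clamped to [0,1] and re-monotonised by running minimum — the
   statistical signature of manual plot digitisation.
4. `ipd_reconstruct`: interval accounting in the Guyot style.  Per
   landmark interval with opening risk set n₀, closing n₁ and survival
   ratio r, deaths solve the censor-at-mid-interval identity
   d = (1−r)(n₀+n₁)/(1+r) (exact when the interval has no censoring),
   censorings absorb the remaining attrition, negative inferred counts
   are repaired by truncation with a logged warning, death times sit at
   the curve's drop points and censorings spread uniformly.  Landmark
   survival is anchored by linear interpolation, which matters only for
   grid-resampled curves.

Fitting (`survival.fit_parametric`) is right-censored maximum likelihood
over five families — exponential, Weibull, log-normal, log-logistic
(S = 1/(1+(t/α)^β)), Gompertz (S = exp(−(b/c)(e^{ct}−1)), c may be
negative) — optimised on log-transformed positive parameters (Gompertz c
linear) with three starts (Nelder–Mead polish then BFGS); non-convergence
sets an honest flag rather than raising.  `select_best_family` ranks by
AIC, ties broken by BIC then parameter count — a numeric replacement for
the visual model choice described in source analyses.  On exact KM input
the reconstruction reproduces the direct MLE to <0.1%; through the full
generate → KM → digitise(σ=0.01) → reconstruct → fit loop at n=500 over
20 seeds, the median parameter error is ~4% (the direct-fit sampling
error at that n is already ~5–9% on the scale parameter).  Near shape 1
the AIC may legitimately select the exponential special case.

What the generator does **not** emulate: the true (unknown) censoring
pattern of trial follow-up (uniform + administrative is a stand-in),
informative censoring, risk-table transcription errors, and time-axis
digitisation error (noise is survival-axis only).  Passing tests
therefore show the pipeline is internally consistent and robust to
read-off noise, not that any specific published curve was digitised
accurately.

## Numerical choices

Transition probabilities clamp to [0,1]; an exhausted curve yields an
absorbing probability 1 with a logged warning.  Beta sampling falls back
to Uniform (logged) when the implied variance is infeasible for [0,1];
degenerate ranges return the baseline as a point mass.  Occupancy
conservation (Σ states = 1 to 1e-9), death monotonicity and
discounted ≤ undiscounted are asserted inside the engine on every run.
ICERs report dominance flags instead of quotients when the sign pattern
warrants, and an undefined flag at zero effect difference (INHB remains
defined).  PSA draws that fail validation are resampled and counted.

Problem sizes used throughout the test and reproduction suite: 195-cycle
deterministic runs (<10 ms each), 10,000 PSA draws (~15 s per country),
20-seed fitting studies at n = 500–2000.

## Known discrepancies with the reference tables

* **Incremental life-years.**  The reference's per-arm discounted LY
  levels and its quoted increments are mutually inconsistent: the quoted
  +0.45 LY (USA) and +0.40 LY (China) equal the *undiscounted* mean
  difference of the two OS curves (0.456 years), while the printed
  discounted levels imply increments of ~0.37 and ~0.31.  This package
  reproduces the levels; its discounted ΔLY is therefore ~0.37 (USA), and
  the two reference quantities that inherit ΔLY — the China ICER per LY
  and the China ICER at the lower PFS-utility bound — come out 22–28%
  above the reference values.  No accounting switch fixes these without
  breaking the (more numerous) level cells.
* **PSA probabilities.**  With the calibrated dispersion the USA
  cost-effectiveness probability computes to ~29% (reference 21.1%) and
  China's placebo probability to ~42% (reference 50.0%); the residual
  traces to the base-case ΔCost/ΔQALY shortfall (ICER −5.8% USA, +5.2%
  China), not the sampling model.
* **China subgroups.**  The largest China subgroup ICER computes to
  ~39.8k, 0.4% above the $39,632 threshold, so the reference claim that
  every China subgroup falls below the threshold holds for 12 of 13
  subgroups here.

## Limitations

Beyond the discrepancies above: the model inherits the source's
structural assumptions (no explicit second-line progression state, one
homogeneous cohort reused across both payer systems, AE burden as a
one-off); OS extrapolation rests on immature trial data; subgroup
analyses vary only the PFS hazard ratio (no subgroup-specific costs,
utilities or OS); and parameter uncertainty excludes the survival
parameters for the reason given above.
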