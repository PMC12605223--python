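"""Base-case cost-utility analysis for both payer perspectives.

Runs the three-state cohort model (progression-free / progressed / dead,
4-week cycles over 15 years) for osimertinib consolidation vs. placebo
under the built-in USA and China presets and prints the strategy table.
"""
from osicea import default_bundle
from osicea.report import base_case_report

bundle = default_bundle()
table, results = base_case_report(bundle)
print(table.to_string(index=False))
print()
for country, res in results.items():
    inc = res.incremental
    verdict = "below" if inc.icer_per_qaly < inc.wtp_used else "above"
    print(
        f"{country}: osimertinib adds {inc.delta_qaly:.2f} QALYs for "
        f"${inc.delta_cost:,.0f} -> ICER ${inc.icer_per_qaly:,.0f}/QALY, "
        f"{verdict} the ${inc.wtp_used:,.0f} willingness-to-pay "
        f"(INHB {inc.inhb:+.2f} QALYs)."
    )
# A positive incremental net health benefit means the health gained exceeds
# the health displaced elsewhere by spending the budget at this threshold:
# cost-effective in China, not in the USA.
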