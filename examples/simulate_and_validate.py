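"""Simulate a healthy+diseased cohort and run the validation statistics.

Generates 10 healthy and 18 diseased kidneys with collagen linearly tied
to the modified elliptical area (plus noise), then reproduces the
standard method-validation battery: correlations of each calculated
area with the measured area, percent agreement, and the OLS calibration
line fitted back from the noisy data.
"""

from renalmorph import (
    CohortSpec,
    cohort_to_table,
    fit_collagen_line,
    simulate_cohort,
    validation_report,
)

spec = CohortSpec(seed=1)
records = simulate_cohort(spec)
table = cohort_to_table(records)

report, summary = validation_report(table)
print(summary)
print()

model, diag = fit_collagen_line(table["Ae_mm2"], table["collagen_ug"])
print(
    f"refit calibration line: collagen = {model.slope:.2f} * A_e "
    f"{model.intercept:+.1f}  (R^2 = {diag.r_squared:.2f}, n = {diag.n})"
)
print(f"injected line:          collagen = 7.70 * A_e -188.5")
print()
print("A_vs_Am shows the standard formula reading low; Ae_vs_Am shows the")
print("extended-minor-axis formula agreeing with measured area; the refit")
print("slope/intercept recover the injected calibration within sampling error.")
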