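"""Fit the buffet-intake fixed-effects linear model.

Outcome = arm + sex + buffet time + arm x sex, treatment-coded against the
(PS-LE1, female) reference cell, with t-based 95% confidence intervals.
"""

from gastrokin import StudyDesign, fit_intake_model, simulate_intake

design = StudyDesign(seed=1)
intake = simulate_intake(design, noise_sd=120.0)
table = fit_intake_model(intake, "kcal_total")
print(table.to_string(index=False, float_format=lambda v: f"{v:8.1f}"))
# With the default generator coefficients the intercept is the mean total
# intake (kcal) of a female subject in the reference arm at the reference
# buffet time; the "MC-LE6 x male" row is the arm-by-sex interaction.
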