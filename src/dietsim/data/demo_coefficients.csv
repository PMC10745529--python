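# Demonstration log-triglyceride coefficient file -- NOT survey-fitted.
# The regression coefficients actually fitted to the restricted-access
# survey microdata are not publicly available, so this package ships a
# nutrient-only stand-in calibrated by least squares so that (a) the
# baseline fixture intake predicts 0.935 mmol/L with 95% CI (0.893, 0.979)
# and (b) the built-in scenario library tracks the published headline
# percent changes in triglycerides to within ~0.5 percentage points.
# Coefficients are on the log(mmol/L) scale per daily unit of each nutrient.
# All uncertainty is carried on the intercept (delta-method CI half-width
# constant on the log scale).
term,beta,se
intercept,-0.03468264948133002,0.02345537287092125
protein,-0.00391313,0.0
fat,0.00940273,0.0
fibre,-0.00113779,0.0
saturated_fat,-0.00632692,0.0
monounsaturated_fat,0.00489836,0.0
linoleic_acid,-0.0326414,0.0
lc_omega3,-3.38087e-05,0.0
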