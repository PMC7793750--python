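"""Estimate an absorbed dose from an observed dicentric count.

A hypothetical casualty sample shows 141 dicentrics in 1,303 scored
metaphases (yield 0.108/cell).  Inverting the published assisted-scoring
curve gives the absorbed dose with 95% limits that combine the Poisson
error of the count with the calibration-curve error, plus the triage
category (1: < 2 Gy, discharge and follow up; 2: 2-5 Gy, admission;
3: > 5 Gy, intensive care).
"""

from dcacalib import CalibrationCurve, estimate_dose, minimum_resolvable_dose

curve = CalibrationCurve.from_coefficients(
    0.0020, 0.0369, 0.0689, se_c=0.0002, se_alpha=0.0019, se_beta=0.0009
)

est = estimate_dose(curve, cells=1303, dicentrics=141)
print(f"yield  = {est.yield_:.3f} dicentrics/cell")
print(f"dose   = {est.dose:.2f} Gy  (se {est.se_dose:.2f})")
print(f"95% CI = [{est.ci95[0]:.2f}, {est.ci95[1]:.2f}] Gy")
print(f"triage category {est.triage_category} (below 2 Gy: no urgent care)")

mrd = minimum_resolvable_dose(curve, aberrations=6, per_cells=1000)
print(f"\nminimum resolvable dose (6 aberrations / 1,000 cells): {mrd:.2f} Gy")
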