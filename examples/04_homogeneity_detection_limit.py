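"""Is the lowest tested dose distinguishable from background?

Compares the 0 Gy (76 dicentrics / 37,954 cells) and 0.1 Gy (156 / 24,220)
rows of the assisted reference table with the pooled-yield chi-squared
homogeneity test.  A highly significant statistic means 0.1 Gy is a usable
lower detection limit for this calibration curve.
"""

from dcacalib import homogeneity_test, load_table1_assisted

table = load_table1_assisted()
r0, r01 = table.rows[0], table.rows[1]

res = homogeneity_test(
    [(r0.cells, r0.total_dicentrics), (r01.cells, r01.total_dicentrics)]
)
print(f"background yield: {r0.total_dicentrics / r0.cells:.4f} dicentrics/cell")
print(f"0.1 Gy yield:     {r01.total_dicentrics / r01.cells:.4f} dicentrics/cell")
print(f"chi2 = {res.chi2:.1f}, DF = {res.dof}, P = {res.p_value:.2g}")
print("-> 0.1 Gy is statistically distinguishable from background.")
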