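# Methods

This note records the statistical model behind dcacalib, the conventions
and numerical choices the implementation makes, what the synthetic-data
generator does and does not emulate, and known limitations.

## Data model and descriptive statistics

The unit of observation is a complete metaphase; at dose `D_i` a table
records `N_i` metaphases of which `D_k` contained exactly `k` dicentrics
(`Σ_k D_k = N_i`, total dicentrics `X_i = Σ_k k·D_k`). Per dose we report:

* yield `Y = X/N`, its standard error `√X / N` (Poisson), inflated by
  `√DI` when the dispersion index exceeds 1 (quasi-Poisson correction,
  applied per row);
* sample variance of per-cell counts with divisor `N − 1` (this divisor is
  required to reproduce the reference tables' printed DI column);
* dispersion index `DI = variance / mean`;
* Papworth's u, `u = (DI − 1)·√((N − 1) / (2·(1 − 1/X)))`. Under Poisson
  sampling u is approximately standard normal, so `|u| > 1.96` flags
  significant over- or underdispersion at the 5% level. u is reported as
  NaN when `X = 1` (the normalizer vanishes and DI is identically 1) and
  raises when `X = 0`.

Homogeneous whole-body irradiation of blood in vitro produces Poisson
per-cell counts; overdispersion in practice indicates partial-body
exposure or scoring artifacts (the bundled automated-scoring table shows
|u| up to 3.14 at some doses for the latter reason).

## Curve fitting

The dose response for low-LET radiation is linear-quadratic,
`Y(D) = C + αD + βD²`: `C` is the background yield (dicentrics/cell), `α`
(per Gy) the single-track and `β` (per Gy²) the two-track damage
component. Fitting maximizes the aggregated-count Poisson log-likelihood
`Σ_i [X_i ln(N_i Ŷ_i) − N_i Ŷ_i]` — an identity-link Poisson GLM with
cells as exposure — by iteratively reweighted least squares with weights
`N_i/Ŷ_i`, initialized from unweighted least squares on the observed
yields (clipped to ≥ 1e-6) and iterated to relative parameter change
below 1e-10 (cap 200 iterations; non-convergence raises with the iterate
trace). Coefficients are constrained non-negative: a negative converged
coefficient is projected to zero and the reduced model refitted; the
reported degrees of freedom count only free coefficients.

The covariance is the inverse observed Fisher information
`(Σ_i X_i/Ŷ_i² g_i g_iᵀ)⁻¹`, `g = (1, D, D²)`. At an interior optimum
this is numerically indistinguishable from the expected information for
the bundled tables (the test suite cross-checks both against statsmodels'
identity-link GLM at 1%). For overdispersed tables a quasi-Poisson option
(`dispersion_scale=True`) multiplies the covariance by
`max(1, χ²/dof)`; it is off by default because reference curves are
fitted as plain Poisson. The published automated-curve SEs are reproduced
exactly by this scaled option, which is how the scaling factor was
identified.

Goodness of fit is the aggregated-count Pearson statistic
`χ² = Σ_i (X_i − N_i Ŷ_i)²/(N_i Ŷ_i)` on `#doses − #coefficients` degrees
of freedom; coefficient significance uses Wald z-tests with two-sided
normal p-values (reported as "< 0.0001" below 1e-4).

Confidence bands are pointwise delta-method bands,
`Ŷ ± z·√(g Σ gᵀ)`, clipped at zero. Passing the per-dose cell numbers
adds the Poisson sampling variance `Ŷ/N` inside the root, giving the
wider band appropriate for judging whether observed yields are consistent
with the curve. For the bundled assisted table all 10 observed yields lie
inside that augmented band, while the pure coefficient band (which only
quantifies curve uncertainty) excludes two points — the distinction
matters when comparing against published figures, whose bands typically
include the Poisson term.

### Recomputed vs published values

Recomputing from the bundled assisted-scoring counts gives
`C = 0.0020, α = 0.0366, β = 0.0687` with SEs `0.0002/0.0019/0.0009` and
Pearson `χ² = 5.05` (7 DF, P = 0.65). The originally published fit prints
`α = 0.0369` and `χ² = 3.51` (P = 0.83). The discrepancy is not a
convention mismatch: Pearson/deviance/minimum-χ² statistics under every
weighting we tried (fitted-yield, observed-yield, dispersion-corrected or
sample-variance denominators; fixed or free background; weighted or
unweighted least squares) all land between 5.0 and 5.7 on these counts,
and even the published coefficients score 5.29 against the published
table. The original analysis applied unpublished per-row corrections in
its fitting software, so its exact statistic is not derivable from the
printed counts. Both analyses agree qualitatively (no lack of fit) and on
every other quantity at printed precision; the corresponding acceptance
test is intentionally left failing rather than tuned to match. The
automated-table fit reproduces at printed precision (`C = 0.0623`,
`χ² = 97.9`, P < 0.0001, significant lack of fit).

## Homogeneity testing

Groups of `(N_i, X_i)` are compared as Poisson totals with exposure:
pooled yield `p = ΣX/ΣN`, expected `E_i = N_i p`,
`χ² = Σ (X_i − E_i)²/E_i` on `#groups − 1` DF, no continuity correction.
(The conditional-binomial formulation was deliberately not used; the
pooled-Poisson form reproduces the reference 0-vs-0.1 Gy value of 78.1
exactly.) Type-I error at α = 0.05 is verified at 5% ± 1.5% by
simulation in the test suite.

## Dose estimation

An observed yield `Y = X/N` is inverted through the curve by the positive
quadratic root; `Y ≤ C` yields dose 0 with a below-background flag (never
an exception), and doses above the calibrated range (default 5 Gy) carry
an extrapolation flag rather than being refused. Uncertainty uses the
delta method on the yield scale divided by the local slope:

    se_D = sqrt( Y/N + g Σ gᵀ ) / (α + 2βD̂),   g = (1, D̂, D̂²)

with 95% limits `D̂ ± 1.96·se_D` clipped at zero. With a curve built from
published SEs the covariance is diagonal, so the with/without-covariance
variants coincide; both are exercised in tests, and the delta-method CI
width agrees with a full Monte-Carlo inversion (Poisson count ×
multivariate-normal coefficients, 10⁵ draws) within 5% for the worked
example.

Triage categories follow the three-way scheme for mass-casualty sorting:
dose < 2 Gy → category 1 (discharge, later follow-up), 2–5 Gy →
category 2 (admission, observation for hematopoietic acute radiation
syndrome), > 5 Gy → category 3 (intensive care). The published ranges
overlap at their endpoints; this implementation closes the boundaries on
the category-2 side (2 Gy and 5 Gy both map to 2), the conservative
choice toward medical observation.

The minimum resolvable dose is interpreted as the dose whose *expected*
yield equals the stated aberration count per scored cells (default 6 per
1,000). This interpretation is inferred rather than taken from a stated
formula; it reproduces both published values (0.09 Gy for the reference
curve, 0.12 Gy for the earlier preliminary curve) to two decimals, which
is strong but circumstantial support.

## Synthetic data

The generator draws per-cell counts at each dose with mean
`predict_yield(curve, D)`:

* `dispersion = 1` (default): Poisson — the study condition for assisted
  scoring of homogeneously irradiated blood;
* `dispersion = d > 1`: negative binomial parameterized directly by the
  variance-to-mean ratio (`p = 1/d`, `r = μ/(d−1)`), so the DI statistic
  the analysis measures equals the configured value.

Counts are drawn uncapped; the multiplicity cap (default 5, mirroring
automated scorers that classify cells as containing 0–5 dicentrics) is
applied only by the scoring-error model. That model thins each cell's
true count binomially with the detection probability (`sensitivity`),
adds an independent Poisson(`fp_rate`) spurious count, and truncates at
the cap — so expected observed yield is `s·Y_true + f` before truncation.
Sensitivity ≈ 0.45 with fp_rate ≈ 0.055 reproduces the qualitative
automated-scoring bias of the bundled tables: intercept inflated an order
of magnitude above the true background and quadratic coefficient deflated
(yield overestimation below 1 Gy, underestimation above 2 Gy).

Seeding: one root seed deterministically derives a substream per dose,
keyed on the dose value (nGy resolution), so a dose's draws are identical
regardless of which other doses are simulated; the recovery harness
spawns one child seed per replicate.

What the generator does **not** emulate: image-level artifacts, the
dependence of metaphase retention on scoring mode (the real automated and
assisted tables differ in cell numbers, not just counts), donor-to-donor
heterogeneity, and partial-body (zero-inflated) exposure. Passing
recovery and calibration tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not robustness to
those real-world effects.

Default study-condition designs used in tests and examples: the reference
table's doses (0–5 Gy, ten points) and per-dose cell numbers, with the
fitted assisted coefficients as truth. Parameter-recovery runs use 500
replicates (tests) or 200 (example) — sizes at which Monte-Carlo error on
coverage is ~1% — with 95% Wald coverage expected in 93–97%.

## Numerical details and edge cases

* Fitted yields are floored at 1e-12 inside IRLS and the likelihood to
  keep weights finite when an intercept is projected to zero.
* Yields and SEs are stored at full precision; rounding to the
  conventional 3 (yields) or 2 (DI/u) decimals happens only at report
  time. Two yields in the bundled tables sit exactly on a 3-decimal
  rounding boundary that the original tables rounded inconsistently
  (1.23450 printed as 1.235; 0.61652 printed as 0.616); tests therefore
  compare yields within one unit of the last printed digit.
* `validate_table` centralizes structural checks (row sums, non-negative
  integer counts, unique ascending doses) and names the first offending
  row; the file reader converts these into errors carrying the 1-based
  file line number.
* Pipeline reports contain no timestamps and are byte-identical across
  reruns of the same config; the run log records package/library versions,
  the seed and a config hash.

## Limitations

* Single-curve, whole-body, acute low-LET exposure only: no
  partial-body (Dolphin/contaminated-Poisson) or protracted-exposure
  corrections, no dose-rate or radiation-quality generalization.
* The homogeneity test is asymptotic; with expected counts below ~5 per
  group the χ² approximation degrades.
* Dose-estimate limits are Wald-type; exact/profile limits for very small
  dicentric counts (triage with 20–50 cells) are not implemented.
* Rings and acentric fragments are outside the data model; only
  dicentrics enter the dose response.
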