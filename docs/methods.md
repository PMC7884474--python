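# Methods

## Model

The vulnerability curve is the Weibull CDF, LC(Ψ) = 1 − exp[−(Ψ/a)ᵇ], with
scale a > 0 (MPa) and shape b > 0. Water potentials are handled throughout
as positive tension magnitudes; negative inputs are rejected rather than
silently negated, because mixed sign conventions are the commonest source
of silent error in hydraulic data.

The analytic derivatives reduce to, with u = Ψ/a and x = uᵇ,

    y′  = (b/a)  e⁻ˣ u^(b−1)
    y″  = (b/a²) e⁻ˣ u^(b−2) (b − 1 − bx)
    y‴  = (b/a³) e⁻ˣ u^(b−3) (b²x² − 3b(b−1)x + (b−1)(b−2))

so the inflection solves b − 1 − bx = 0 and the turning points solve the
quadratic in x, giving the closed forms

    Ψₘ = a((b−1)/b)^(1/b),
    Ψₑ,ₗ = a·u^(1/b),  u = [3(b−1) ∓ √((b−1)(5b−1))]/(2b).

**Domain of validity.** The inflection exists only for b > 1 (b ≤ 1 raises a
domain error). The lower turning-point root is positive iff b > 2 — algebra:
3(b−1) > √((b−1)(5b−1)) ⇔ 9(b−1) > 5b−1 ⇔ b > 2 — so for 1 < b ≤ 2 the
air-entry point is reported as an explicit `None`, never a NaN or a silent
zero, and four-period classification refuses to run without it.

**Traditional points.** All three quantile points are computed from the
single inversion Ψₚ = a(−ln(1−p))^(1/b) at p ∈ {0.12, 0.50, 0.88}, which is
the unambiguous closed form of the 50% and 88% points and resolves the 12%
point as a(2 ln5 − ln22)^(1/b).

**Ordering caveat.** On the fitted curve used throughout (a = 2.23,
b = 2.50) every quantile point exceeds its differential counterpart
(Ψ₁₂ > Ψₑ, Ψ₅₀ > Ψₘ, Ψ₈₈ > Ψₗ). That ordering is *not* universal in b (for
large shapes the loss at the lower turning point exceeds 0.12), so the
package asserts it only at those parameters and makes no general claim.

**Numeric oracle.** `numeric_key_points` re-derives all key points by
Brent root-finding on the analytic y″ and y‴ over (0, Ψ_max], with
Ψ_max = 2 × the 99.99% loss quantile — parameter-adaptive rather than a
fixed window, so every derivative root lies strictly inside the bracket for
any admissible (a, b). Closed form and oracle are required to agree to
1 × 10⁻⁸ MPa; a missing sign change where the closed form predicts a root is
raised as an internal error because it can only mean a derivative bug.

**Periods.** The key points partition Ψ ≥ 0 into half-open intervals,
boundaries belonging to the higher period: stationary [0, Ψₑ), accelerated
decline [Ψₑ, Ψₘ), decelerated decline [Ψₘ, Ψₗ), platform [Ψₗ, ∞).

## Fitting

`WeibullVulnerabilityCurve` minimises the unweighted sum of squared LC
residuals with `scipy.optimize.least_squares` (analytic Jacobian, positivity
bounds, relative tolerances 10⁻¹⁰, at most 200 iterations — a smooth
two-parameter problem where tight tolerances cost nothing). The start value
comes from the Weibull-plot linearisation: OLS of log(−log(1 − LC)) on
log Ψ, whose slope is b and intercept −b·log a; points with LC ∈ {0, 1} are
excluded from the linearisation (log singularities) but kept in the
nonlinear objective, where full-embolism observations are informative.
R² is 1 − SS_res/SS_tot on LC. Fits are pooled across stems by default —
one curve from all observations — with `fit_per_sample` available when
per-stem curves (mean ± SE of parameters) are wanted instead.

Parameter uncertainty is by **case-resampling bootstrap** (percentile
intervals, default 95%). Case rather than residual resampling because the
LC error model is unknown and visibly heteroscedastic near the bounds
LC ∈ {0, 1}. Degenerate resamples (fewer than three points, a single
distinct tension, all-zero LC) are redrawn and counted. Every stochastic
path takes a single integer seed and is bit-reproducible from it.

## Raw hydraulics

K_s = L·(m/t)/(A·p); LC against the flushed maximum either as
(K_m − K_s)/K_m or, with geometry and driving pressure fixed, as the
algebraically identical 1 − T/tᵢ in conductance times. Negative LC (a step
conducting better than the flushed reference) is physically suspect but
measurement QC is the user's call: values are returned raw with a
`supra_maximal` flag and a warning, never clamped.

Stem water gain is WG = K_m·ΔΨ·A·(1 − LC)/L with ΔΨ the magnitude of the
soil-to-stem tension difference. Leaf water loss E·LA (E in mol m⁻² s⁻¹)
is converted through the molar mass of water (0.018015 kg mol⁻¹) by default
so WG and WL share kg s⁻¹ and their net difference is meaningful;
`convert_to_kg=False` keeps the bare molar flux for callers who want the
unconverted product. The default air-injection pressure schedule is
0.00–4.00 MPa in 0.20 MPa steps then 4.50, 5.00, 6.00 MPa (24 levels),
shipped as `DEFAULT_PRESSURE_SCHEDULE`.

## Validation statistics

A calculated point is compared to a measured group by a one-sample t-test
(t = (x̄ − μ₀)/(s/√n), df = n − 1). Direction defaults to two-sided for
equality claims; a zero-variance group is an error unless its common value
equals the point, where p = 1 by convention. The bracketing ("squeeze")
test formalises "the point lies strictly between the two groups" as two
one-sided tests — lower group below the point, upper group above it — both
required to reject at α (default 0.05). `method_comparison_report` runs the
two-sided test for the differential and quantile point of each named group
and labels each method "consistent", "overestimates" or "underestimates".

## Synthetic experiments

The generators emulate the measurement design the package targets: for each
of n stems (default 10), the true curve (default a = 2.23 MPa, b = 2.50) is
sampled on the 24-level schedule and additive Gaussian LC noise (default
sd 0.02, chosen to reproduce the near-unity R² typical of careful
air-injection curves) is truncated to [0, 1]. Injection-time series invert
LC to t = T/(1 − LC) with LC capped at 1 − 10⁻⁴ so fully embolised steps
keep finite times (exact round trip below the cap); treatment groups are
Gaussian draws about a chosen centre, defaults mirroring the recovering /
non-recovering groups at 2.73 and 2.93 MPa (sd 0.03, n = 10) that bracket
the lethal point.

What the generators do **not** emulate: between-stem parameter
heterogeneity (every stem shares one true curve), autocorrelated or
Ψ-dependent noise, censoring at high pressures, and open-vessel artefacts
of the air-injection technique. Passing tests therefore demonstrate
correctness of the estimators and statistics under a clean additive-noise
model, not robustness to those field realities.

## Problem sizes and numerical choices

Monte-Carlo sizes used by the test suite are the package's own choices:
500 single-curve replicates for median parameter-recovery error, 1000
seeded replicates for bracketing power, 300 for estimator bias, and
40 outer × 200 bootstrap draws for interval coverage (coverage asserted
conservatively at ≥ 80% of a nominal 95% given the small outer sample).
Root-finding tolerances are 10⁻¹³ absolute on tension; closed-form/oracle
agreement is asserted at 10⁻⁸ MPa. JSON reports carry full double
precision; only human-readable summaries round to two decimals. Report
files embed a schema version (major checked on read) and the SHA-256 of
their inputs plus the seed, so any report is reproducible from its
provenance block.

## Known limitations

* Only the Weibull form is implemented; no sigmoidal/exponential
  alternatives or model selection between them.
* The quantile-vs-differential orderings are curve-specific (see above);
  the package does not test them away from the fitted parameters.
* The p-value conventionally attached to R² is not reproduced (no defined
  test), and no ANOVA/multiple-comparison machinery is included — off-the-
  shelf tools cover those.
* No plotting: reports are numbers; figures are a caller concern.
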