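# Methods

## Model

For a stratum's Lexis table (A equal-width age bands × P calendar periods
of the same width, deaths `d_ap` ≥ 0, person-years `n_ap` > 0), the log
rate is modelled additively in age, period and birth cohort:

    ρ_ap = log(d_ap / n_ap) = α_a + π_p + γ_c ,   c = p − a .

Because `c = p − a` exactly, the three linear trends trade off against
each other and individual effect levels are not identified.  The package
works in the longitudinal reparameterization

    ρ = μ + (α_L + π_L)(a − ā) + (π_L + γ_L)(c − c̄) + ᾶ_a + π̃_p + γ̃_c ,

where `(α_L + π_L)` is the longitudinal age trend, `(π_L + γ_L)` the net
drift, and the deviation vectors ᾶ, π̃, γ̃ are constrained to be orthogonal
to both the constant and the linear index within their own dimension.
That constraint is one arbitrary but convenient resolution of the
identifiability problem; every reported quantity is an estimable function
and is provably unchanged under any other full-rank choice.  The design
has `1 + 2 + (A−2) + (P−2) + (C−2)` free parameters (32 on the 12×6 study
grid, leaving 40 residual degrees of freedom from 72 cells).  Deviation
blocks are built by projecting category indicators onto the orthogonal
complement of {1, linear index} and orthonormalizing (SVD), which keeps
the constraint-invariance comparisons sharp at machine precision.

## Fitting

Coefficients minimize Σ w_ap (y_ap − x_apᵀβ)² with `y = log(d/n)` and
weights `w = d`: under the Poisson assumption the delta-method variance
of a log rate is `1/d`, so observed counts are the natural single-pass
WLS weights.  Weights are **not** iterated to fitted counts; the
iteratively reweighted (maximum-likelihood Poisson GLM) route is kept in
the test suite as an independent oracle, and at study-scale counts the
two agree on all estimable functions to well below one part in a
thousand (log scale).  Conventions pinned where the literature leaves
room:

- **Zero cells.**  `log 0` is undefined, so a cell with `d = 0` gets the
  substitute `d* = 0.5` for both its log rate and its weight, with a
  warning; `zero_cell="strict"` raises instead.  Real burden-of-disease
  estimates are never exactly zero at study scale, but synthetic and
  sparse tables need a defined behaviour.
- **Dispersion.**  Pearson χ²/df is always reported.  The coefficient
  covariance is `(XᵀWX)⁻¹` (plain Poisson Wald intervals); it is inflated
  by the dispersion only when the user opts in (`overdispersion=True`)
  *and* the dispersion exceeds 1.
- **Rank.**  The weighted design is factored by SVD; singular values
  below `1e-10 ×` the largest raise a rank error naming the offending
  parameter block, and underdetermined grids (fewer cells than
  parameters, e.g. a single period) are rejected outright.
- **Units.**  Linear trends are estimated per interval (5 years) and
  divided by the interval width at reporting time, so all drifts are
  per-year quantities.

## Estimable functions

All outputs are computed from the fitted log-rate surface: the surface is
projected back onto the canonical orthogonal basis (`θ = X⁺ρ̂`, exact
because ρ̂ lies in the model space), and each output is a linear map of θ
with delta-method 95% CIs on the log scale.  Since the fitted surface and
its covariance are basis-independent, so is every output — the test suite
demonstrates this by refitting under corner (dummy) constraints.

- **Net drift** = (π_L + γ_L)/width per year; reported as
  `100(e^slope − 1)` percent per year.
- **Local drift** for age band `a` = the least-squares calendar slope of
  that row of fitted log rates, per year.  Period deviations have zero
  linear trend by construction, so this equals the net drift plus the
  age-specific slope of the cohort deviations along the row; the
  row-slope formulation is used because it is manifestly
  constraint-invariant.
- **Longitudinal age curve** = `exp(μ + (α_L+π_L)(a−ā) + drift·(c₀−c̄)
  + ᾶ_a + γ̃_{c₀})` per 100,000: the reference cohort followed across age
  with period deviations set to zero.
- **Cross-sectional age curve** = `exp(μ + (α_L−γ_L)(a−ā) + drift·(p₀−p̄)
  + ᾶ_a + π̃_{p₀})` per 100,000.  The two curves' log slopes differ by
  exactly the net drift, so they coincide (up to a constant) only when
  the net drift is zero.
- **Rate ratios**: `RR_p = exp(drift·(p−p₀) + π̃_p − π̃_{p₀})` and
  `RR_c = exp(drift·(c−c₀) + γ̃_c − γ̃_{c₀})`.  Both series deliberately
  carry the full drift — each is the fitted rate ratio at fixed age,
  adjusted for the deviations of the remaining time scale — which is the
  convention under which published endpoint ratios of long series imply
  the same annual change as the net drift.  The reference entry is 1
  exactly with a degenerate [1, 1] interval.
- **Wald tests**: χ² = (Lθ)ᵀ(LΣLᵀ)⁻¹(Lθ) with df = rank(L), two-sided
  α = 0.05.  Named hypotheses: zero net drift (1 df), equal local drifts
  (A−1), all period RRs = 1 (P−1), all cohort RRs = 1 (C−1).  Contrasts
  supplied over raw category parameters are first checked for
  estimability (orthogonality to the null space of the category design)
  and rejected otherwise.

## Data preparation

Bands are closed integer ranges labelled `start-end`; arithmetic uses
midpoints in continuous years.  Annual records are **summed** into
periods (period person-years = total person-time at risk over its five
years; estimable functions are invariant to sum-vs-mean up to a constant
shift of the intercept, which only moves the absolute age-curve level).
A cohort's mid-year is period midpoint − age midpoint and its label is
the same-width band centred there, so the 12×6 grid over 1990–2019 yields
the 17 cohorts 1913-1917 … 1993-1997.  Median-category references follow
from the grid itself: 2000-2004 / 1953-1957 for ages 20–79, and
1948-1952 for the 30–79 tables used for risk-factor-attributable
mortality.  Death counts may be non-integer (model-based estimates) and
are never rounded.  Direct age standardization (`Σ w_a r_a` per 100,000,
weights renormalized over the supplied bands) is provided as a
convenience for users who want age-standardized rates from age-specific
ones.

## Synthetic data

`SimScenario` generates tables with exactly known structure: per-band
baseline log rates (or a quadratic in age midpoint), period and cohort
log-linear slopes per calendar year, curvature vectors auto-projected
onto the orthogonal-deviation space (the removed component's norm is
logged, so a "curvature" input cannot smuggle in extra drift), and
Poisson counts at user-set person-years.  The default preset emulates a
lung-cancer-like stratum: a Gompertz-like log-quadratic age curve
spanning ~0.1 to ~400 deaths per 100,000 across ages 20–79, a −0.2%/yr
period trend and −0.8%/yr cohort trend (net drift ≈ −1%/yr,
cohort-dominated), a mild mid-cohort hump echoing a smoking-epidemic
pattern, and 2×10⁶ person-years per cell — within the 10⁵–10⁷ range of
real national tables.  At that population size the youngest band expects
only ~2 deaths per cell, so occasional zero cells exercise the
substitution rule exactly as sparse real strata would.

What the generator does *not* emulate: estimation uncertainty of the
input counts themselves (real burden-of-disease values are smoothed model
outputs with correlated errors and 95% uncertainty intervals, which this
package carries as metadata only), migration or cause-misclassification
artefacts, and sub-five-year age detail.  Passing the simulation suite
therefore shows correctness of the estimators under the stated sampling
model, not robustness to upstream estimation error.

## Validation problem sizes

The statistical checks run entirely on synthetic 12×6 tables: constraint
invariance over 20 random scenarios (tolerance 1e-8 relative); WLS vs
IRLS-GLM agreement over 10 scenarios at cell counts ≥ ~10³ (agreement
required to 0.005 on the log scale, i.e. ~0.5%); net-drift CI coverage
over the grid drift ∈ {−2, 0, +2}%/yr × mean counts ∈ {10², 10⁴} with 200
replicates per point (coverage required in [0.93, 0.97]); null test size
with 1000 replicates (99% binomial band around 0.05); and an age-curve
recovery check using a Bonferroni-simultaneous 95% band across the 12
ages.  Comparisons between fitting routes are made on additive scales
(log rates, log ratios, log slopes) because relative error is ill-posed
for percent-change quantities near zero.

## Known limitations

- Single-pass WLS with observed-count weights differs from the Poisson
  MLE at very small counts; below ~100 deaths per cell the zero-cell rule
  and weight noise start to matter, and pointwise CIs for the sparsest
  cells undercover slightly (visible in the young-age bands of the
  preset).
- Equal-width, contiguous, pre-merged bands are required; tables with
  ragged or sub-five-year age groups must be merged upstream.
- No Bayesian, penalized, or continuous-age spline APC variants, and no
  propagation of the input estimates' own uncertainty intervals.
- Both rate-ratio series carry the net drift by convention; users
  wanting drift-free "curvature only" effect curves should subtract the
  drift term themselves.
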