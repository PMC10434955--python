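# Methods

## The amplified sine family

The package implements a generator that maps any baseline lifetime CDF
G(t; κ) with density g into

    F(t; λ, κ) = 1 − λ (1 − s) / (λ − s),    s = sin[(π/2) G(t; κ)],   λ > 1,

with density

    f(t; λ, κ) = π λ (λ − 1) g cos[(π/2) G] / ( 2 (λ − s)² ).

λ is a dimensionless *amplification* parameter: as λ → ∞ the family
collapses to the plain sine transform sin[(π/2)G], and the extra parameter
tilts mass between the body and the upper tail. The transform preserves
regular tail variation of the baseline (the survival ratio
S(t; λ)/(1 − s) tends to λ/(λ−1) in the upper tail), so a heavy-tailed
baseline stays heavy-tailed.

The family is degenerate at λ = 1 (the CDF collapses to 0 pointwise), and
the package enforces λ ≥ 1 + 1e−6 everywhere. The boundary is not a
removable irregularity: writing ε = λ − 1 and letting ε → 0 while the
baseline drifts so that 1 − G = O(√ε), the CDF tends to a proper
logistic-type limit, F → 1/(1 + θ e^{−2αt^δ}) for the Weibull baseline.
This matters for fitting (below).

**Numerical stability.** 1 − sin[(π/2)G] cancels catastrophically as
G → 1. All survival-side quantities are computed through the identity
1 − sin x = 2 sin²(π/4 − x/2), i.e. from the *baseline survival*
S_G = 1 − G:

    1 − s = 2 sin²[(π/4) S_G],    λ − s = (λ − 1) + (1 − s),

which keeps ~15 significant digits into the far tail. The CDF is evaluated
in the algebraically identical form (λ−1)s/(λ−s), stable in both tails.
These forms are what make the tail-ratio property test and the hazard of
near-saturated designs computable at G = 1 − 1e−9.

**Quantile and sampling.** The inverse CDF is closed-form,
t_q = G⁻¹((2/π) arcsin(uλ/(λ−1+u))); sampling is inverse-transform with
uniforms clipped to (1e−12, 1 − 1e−12).

**Moments.** Raw moments are computed as ∫₀¹ Q(u)^r du by 201-node
Gauss–Legendre quadrature on the clipped interval u ∈ [1e−10, 1−1e−10].
A closed series expansion exists in principle but is not used as a code
path. Divergent moments are detected by the decay of the tail contribution
Q(1−c)^r · c between c = 1e−6 and c = 1e−10 and reported as `inf`; the
probe catches Pareto-type tails that the quadrature nodes never see.

## The Weibull member and competitors

The Weibull baseline is used in rate-scale form G = 1 − exp(−α t^δ)
(shape δ > 0, rate-scale α > 0 in units time^{−δ}), giving a
three-parameter lifetime model whose hazard covers decreasing,
increasing, bathtub and decreasing–increasing–decreasing shapes (the test
suite pins the four shapes at catalogued parameter sets on the central
0.1%–90% probability window; in the extreme tail the hazard reverts to
baseline-Weibull behaviour, which plotting windows never show).

Five benchmark models are provided for model comparison: plain Weibull,
exponentiated Weibull, sine-Weibull (the λ→∞ limit), sine inverse-Weibull,
and the alpha-power cosine Weibull
S = (α₁ − α₁^{sin[(π/2)G]})/(α₁ − 1), α₁ > 0, α₁ ≠ 1. The sine
inverse-Weibull uses the inverse-Weibull baseline exp(−α t^{−δ}) — the
only reading under which it is a valid survival function, and the one that
reproduces the published comparison values.

## Maximum likelihood

The log-likelihood is evaluated in the expanded form

    n log λ + n log(λ−1) + Σ log g + n log(π/2) + Σ log cos[(π/2)G] − 2Σ log(λ−s)

with the same stable tail pieces. Invalid parameters or observations
outside the support yield −∞ rather than exceptions so optimisers can
recover.

`fit_mle` runs box-constrained L-BFGS-B from a deterministic start set:
Menon-type Weibull moment estimates for (δ, α) at shape scales
{1, 0.5, 0.25} (α re-matched at each scale), crossed with
λ ∈ {1.01, 1.1, 1.5, 2} — 12 starts — followed by up to three restarts at
the incumbent optimum. Bounds: δ ∈ [1e−3, 50], α ∈ [1e−8, 1e3],
λ ∈ [1+1e−6, 1e4]. The shrunken-shape starts are essential: the
likelihood of this family can have *two branches* — a large-λ branch
(where the model approximates its sine-transform limit and λ is nearly
unidentified) and a small-shape ridge running to the λ → 1 boundary
(the logistic-type limit family above). On the bundled survival-time data
the ridge wins: the λ-profile rises monotonically as λ → 1⁺ and the
global constrained optimum sits at λ̂ ≈ 1.00002 with a markedly better
fit than any interior point. `FitResult.at_bound` reports estimates on
their box bounds, and a λ̂ at its lower bound should be read as "the data
prefer the boundary limit family". Profile likelihoods (`profile_loglik`)
re-maximise the remaining parameters per grid point and make the branch
structure visible; on this data the shape profile is bimodal.

Standard errors, when requested, come from a central-difference Hessian
with step 1e−4·(1+|θ|); along the weakly identified λ direction the
Hessian is frequently near-singular and `se` is then `None` rather than a
fabricated number.

## Goodness of fit

Cramér–von Mises, Anderson–Darling and two-sided Kolmogorov–Smirnov are
computed from the fitted CDF at the order statistics with the classical
finite-n formulas; AD clips CDF values to [1e−15, 1−1e−15] with a warning.
The KS p-value is the asymptotic Kolmogorov tail
2Σ(−1)^{k−1}exp(−2k²nD²) with no estimated-parameter correction — the
convention under which the published comparison p-values reproduce
(0.9152 at D = 0.04926, n = 128). Note that EDF statistics evaluated at
*estimated* parameters are optimistically biased as absolute tests; here
they are used comparatively, to rank candidate models on the same data.

## Monte-Carlo recovery study

`run_study` draws N replicate samples per size n by inverse-CDF sampling
(replicate r at the i-th sample size uses seed base + 10⁶·i + r, so any
cell is reproducible in isolation), fits each replicate, and tabulates
mean MLE, MSE and bias. Defaults are the full study conditions: n ∈
{25, 50, 75, 100, 150, 200, 300, 400, 500}, N = 500; N = 200 gives a
faster run with the same qualitative pattern and is what the CLI defaults
to. Replicate fits use a single quasi-Newton run started at the
generating truth — the conventional recovery-study protocol. This choice
is substantive: a full multi-start fit instead finds the global (often
large-λ) optimum in the ~10–15% of replicates where the flat direction
dominates, which inflates the mean shape estimate and explodes the
amplification MSE. With the truth-start protocol the study reproduces the
published pattern: shape biased upward, rate-scale biased slightly
downward, amplification biased upward, and every MSE decaying with n.
Non-convergent replicates are excluded and counted; a cell with > 20%
failures is flagged unreliable.

## The truncated-life-test np chart

Subgroups of n items are tested until t₀ = τ·ξ₀, where ξ₀ is the
specified q-percentile life (q = 0.5, median life, by default — the value
under which all published worked numbers reproduce) and τ a truncation
multiplier. Because α = η_q / t_q^δ with
η_q = −log[1 − (2/π)arcsin(λq/(λ−1+q))], the in-control failure
probability depends only on (δ, λ, τ, q):

    p₀ = 1 − λ(1 − s)/(λ − s),   s = sin[(π/2)(1 − e^{−τ^δ η_q})].

Control limits are np₀ ± k√(np₀(1−p₀)) (lower clipped at 0); the integer
decision set is {⌊LCL⌋+1, …, ⌊UCL⌋}, degenerating to {0, …, ⌊UCL⌋} when
the lower limit clips to 0. The in-control probability is the binomial
mass on that set and ARL = 1/(1 − P_in). `apply_chart` uses exactly the
same set, so chart decisions and ARL arithmetic cannot disagree. The
decision bounds sit at integer floors, so ARLs are discontinuous in
(k, τ): rounding published constants to 3 decimals can flip ⌊LCL⌋ when
the raw limit is within ~1e−3 of an integer. The shipped worked design
(n = 30, k = 2.981, τ = 0.948) is comfortably interior.

**Shift semantics.** A process shift multiplies the monitored life scale
by c (Weibull scale 1/α moves, shape fixed), which divides the exponent
by c: p₁(c) uses τ^δ η_q / c. The alternative reading — scaling the
truncation multiplier, exponent η_q(τ/c)^δ — differs for δ ≠ 1 and does
not reproduce the published run-length profiles; it is available as
`variant="tau"` for comparison.

**Design search.** `design_chart` scans k ∈ [2, 4] and τ ∈ (0, 1.25] at
step 0.001 and returns the pair with the smallest ARL₀ ≥ r₀, ties broken
by smaller k then smaller τ (deterministic). Decision sets covering the
whole support are excluded (they can never signal). Feasible (k, τ) pairs
are highly non-unique; the search reproduces target ARLs, not any
particular published constant pair.

**Applying the chart to lifetime series.** A real truncated test records
counts directly; `counts_from_times` reconstructs counts from a plain
lifetime series by consecutive blocks of n (final partial block dropped),
counting failures at or below t₀. This is a documented reconstruction for
demonstration, not part of the chart proper.

## What the synthetic data does and does not emulate

Fixture generators produce (i) inverse-CDF lifetime samples at catalogued
parameter sets and (ii) binomial subgroup failure counts at the exact
in-control or shifted failure probability of a design. These match the
chart's operating assumptions by construction — independent items,
constant process parameters within a subgroup, counts exactly binomial.
Real truncated life tests violate these in ways the generators do not
emulate: within-subgroup dependence, drifting parameters, inspection
error, and censoring schemes other than simple time truncation. Passing
tests therefore certify the arithmetic chain (probability → limits → run
lengths → decisions) and estimator behaviour *under the model*, not
robustness to such violations. The one reference dataset (128 published
survival times, in months) ships verbatim as a package fixture.

## Known limitations

- The amplification parameter is weakly identified at moderate n; interval
  statements about λ̂ from the numerical Hessian are unreliable.
- EDF criteria at estimated parameters are comparative tools here, not
  calibrated hypothesis tests.
- Censored-data likelihoods and Bayesian estimation are out of scope.
- The chart assumes the in-control (δ, λ) are known (or estimated
  upstream); estimation error in them propagates to p₀ and is not
  accounted for in the ARL arithmetic. `empirical_limits` offers the
  data-driven D̄ ± k√(D̄(1−D̄/n)) alternative when p₀ is unknown.
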