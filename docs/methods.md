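# Methods

## The problem

An FDR-controlled analysis ends with a set S of features whose q-values
fall at or below a level α (here 0.05, inclusive). Reporting only the
point estimates hides three sources of variation: the spread of the
*local* FDRs inside S (an "average 5%" set can contain features with
individual false-positive probabilities far above 5%), the sampling
error of the q-value estimate itself, and the randomness of the
realized false discovery proportion (FDP) around its expectation.
`fdrboot` quantifies all three with a bootstrap whose resampling unit
is the P-value.

## Mixture model and estimators

P-values are modelled as the two-component mixture

    f(p) = η₀ · 1 + (1 − η₀) · f₁(p),   p ∈ [0, 1],

with a uniform null of weight η₀ and a nonincreasing alternative
density f₁. The local FDR is the posterior null probability
fdr(p) = η₀ / f(p), capped at 1.

**Density.** f is estimated by the Grenander estimator: the derivative
of the least concave majorant (LCM) of the empirical CDF. ECDF heights
use plotting positions c_k/(m+1) and the curve is anchored at (0, 0)
and (1, 1). The anchor at (1, 1) makes the density integrate to one
over [0, 1] exactly; the m+1 denominator keeps the terminal step
strictly positive even though the largest observed P-value is below 1
(with raw c_k/m heights the majorant is flat beyond the largest
observation and the terminal step degenerates to zero). The LCM
derivative is computed as the weighted antitonic regression of the raw
ECDF slopes with the knot spacings as weights — the classical
pool-adjacent-violators identity — via `scipy.optimize`. The step
density is evaluated right-continuously on [0, 1); f(1) is the last
step's value; exact-zero P-values get a knot at half the smallest
positive value so no step has zero width.

**Null proportion.** The default η₀ estimator is the fixed-λ tail-count
rule η₀ = #{p > λ} / (m(1 − λ)) with λ = 0.5, capped at 1 (floored at
1/(m(1 − λ)) if the tail is empty, keeping η₀ > 0). The terminal
Grenander step min(1, f̂(1)) is available as `eta0_method="terminal"`,
but it is not the default: the Grenander estimator is inconsistent at
the boundary of its support, and in simulation the terminal step runs
some 30% below the truth under a pure null (mean ≈ 0.70 at m = 2000)
while the λ = 0.5 rule is nearly unbiased (mean ≈ 0.99 under the null;
0.90 under the default mixture with true η₀ = 0.9). λ = 0.5 is the
standard compromise between bias (alternative mass above λ) and
variance (short tail window); it is exposed as a parameter.

**q-values.** The q-value of a feature is defined as the running mean
of the local FDRs of all features with P-values at or below its own
(ties share the mean at the last tied rank). Under a monotone density
this is the tail-area FDR, and it makes the bootstrap's replicate-level
q — the mean bootstrapped local FDR over S — reduce *exactly* to q on
the identity resample, an invariant the tests assert. A BH-style
η₀·t/F̂(t) estimate would differ by O(1/m) and break that exactness.

## The P-value bootstrap

Each of B replicates (default 10 000):

1. draws m indices uniformly with replacement and takes their P-values;
2. refits the full estimator (density and η₀) on the resample, giving
   fdr\*ⱼ for every resampled value;
3. assigns every original feature a bootstrapped local FDR fdrᴮᵢ:
   directly, fdrᴮᵢ = fdr\*ⱼ with Gⱼ = i, when the feature was
   resampled; otherwise by linear interpolation between its flanks —
   the largest resampled P-value ≤ pᵢ (left) and the smallest ≥ pᵢ
   (right). An empty left flank is anchored at (0, 0), an empty right
   flank at (1, 1); coincident flanks (an exactly tied value) return
   the right flank's fdr\*. When several resampled features tie for a
   flank one is picked at random, but tied values share one fdr\* (the
   estimator is a function of the P-value alone), so the pick can never
   change the imputed value — the implementation asserts this when
   handed an externally supplied fdr\*;
4. computes qᴮ = mean of fdrᴮ over S, and FDPᴮ = (1/r) Σ_{i∈S}
   Bernoulli(fdrᴮᵢ) with independent draws — a simulated count of
   false positives among the declared discoveries.

SEs are sample standard deviations over replicates (B − 1 denominator);
intervals are the empirical 2.5%/97.5% quantiles. Per-feature
local-FDR SEs use fdrᴮᵢ from *all* replicates, including those where
feature i was imputed: fdrᴮᵢ is defined in every replicate by
construction, and restricting to replicates containing i would reduce
the effective B by a factor ≈ 1 − e⁻¹ without a compensating benefit.

**Reproducibility.** One seed; replicate b consumes an independent
substream spawned from (seed, b), in a fixed order: resample indices,
flank tie-break pairs (one per interpolated feature), Bernoulli
uniforms. Identical seeds give bit-identical summaries; results do not
depend on any parallel execution order.

**Degenerate sets.** r = 0 is an error (there is nothing to bootstrap
over); r = 1 is allowed (qᴮ is a single fdrᴮ, FDPᴮ ∈ {0, 1}).

## Synthetic data and what it does (not) emulate

The generator draws z_i = μ·label_i + ε_i with labels Bernoulli(1 − η₀)
and ε standard normal, optionally equicorrelated (ρ) within consecutive
blocks of `block_size` features, and maps one-sidedly p = 1 − Φ(z)
(two-sided is a flag). Defaults m = 2000, η₀ = 0.9, μ = 2.5, ρ = 0:
the scale of a classic two-group expression study, a signal strength
that puts the q ≤ 0.05 set near r ≈ 100, and independence as the
baseline the percentile interval is calibrated for. The closed forms

    f₁(p) = φ(z_p − μ)/φ(z_p),  z_p = Φ⁻¹(1 − p)
    fdr(p) = η₀ / (η₀ + (1 − η₀) f₁(p))
    q(p)   = η₀ p / (η₀ p + (1 − η₀)(1 − Φ(z_p − μ)))

provide exact truth for every test (limits: fdr → 0 as p → 0 and
fdr → 1 as p → 1 for μ > 0; fdr ≡ η₀ when μ = 0). The generator does
not emulate heavy-tailed test statistics, composite nulls
(mis-calibrated P-values), signal strength heterogeneity, or realistic
gene-network correlation — so passing tests demonstrate calibration
under a clean mixture, not robustness to those violations.

## Coverage study

For each simulated dataset and each P-value cutoff t the significant
set is {i : pᵢ ≤ t} (a cutoff on p, not on q, so the set has a fixed
population analogue). Coverage is recorded for (a) the percentile CI
of the boundary feature's local FDR against the analytic fdr at that
feature's realized P-value — the per-feature claim a Figure-style
error bar makes — and (b) the percentile CI of qᴮ against the analytic
tail FDR at t, which is the probability limit of the plug-in estimate
E[fdr_true(p) | p ≤ t] = η₀t/F(t). Simulations where the cutoff leaves
an empty set are counted and reported separately, not dropped.

At full scale (independent features, 200 simulations, B = 1000, seed
20150804) the q-value CI coverage is 0.970–0.985 across cutoffs
{0.001, 0.01, 0.05} and the local-FDR coverage 0.935–0.955, consistent
with the 0.95 nominal level to within 3 binomial SEs; with block
correlation (ρ = 0.5, blocks of 50) q coverage collapses to ≈ 0.6.
Bootstrap SEs computed under correlation are therefore best read as
lower bounds on the real variability.

## Numerical and design choices

- Knot spacings below 1e-290 are clustered onto one knot before
  differentiation (slope overflow guard); this is far below any
  meaningful P-value resolution.
- The t-test front end uses pooled-variance Student's t (df = n₁+n₂−2),
  Welch behind a flag; zero-pooled-variance features get p = 1 (equal
  means) or p = 0 (separated means). No expression preprocessing is
  applied — normalization/log-transform choices are left to the caller,
  and published analyses may not be numerically reproducible without
  the original preprocessing.
- α thresholds are inclusive (q ≤ α).
- Output tables preserve input feature order; significance is a flag
  column.
- Problem sizes in the test-suite and acceptance computations (200
  simulations × B = 1000 for coverage; B = 5000 for the FDP/q identity;
  m = 10000 for parameter recovery) were chosen to hold Monte-Carlo
  error near the width of the assertion bands while keeping a full run
  in minutes on one core.

## Known limitations

- The bootstrap treats P-values as exchangeable draws; under strong
  dependence its SEs understate the truth (see the coverage study).
- η₀ from a fixed λ is mildly conservative (upward-biased) when the
  alternative has mass above λ; with μ = 2.5 one-sided this mass is
  Φ(−μ) ≈ 0.006 per alternative feature and negligible.
- The Grenander density is inconsistent at the boundaries; local FDRs
  at the extreme right are clipped to 1, and the feature with the
  largest P-value always receives fdr = 1 when its value tops the
  resample's support.
- Exact numeric agreement with any particular R implementation of
  local-FDR estimation is not guaranteed (estimator variants differ in
  their η₀ rule and boundary conventions); the package's claims are
  calibrated against the analytic truth of its generating model
  instead.
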