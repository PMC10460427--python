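# Methods

## The model

An ego communicates with a fixed set of `k` alters. Every alter starts with
activity `a0` (its baseline number of events), and events arrive one at a
time: at event time `τ` the alter with current activity `a` receives the
next event with probability

    π_a = (a + α) / (τ + k α),

a linear (Price/Pólya-urn) kernel. The offset `α` interpolates between pure
cumulative advantage (`α → −a0`: the busiest ties capture almost all new
events) and uniformly random alter choice (`α → ∞`: flat kernel `1/k`). In
reduced coordinates `α_r = α + a0`, `t = τ/k` (mean alter activity, the
model's clock), `t_r = t − a0`, the single shape parameter is the
**preferentiality** `β = t_r / α_r`.

In the large-`τ`, large-`k` limit the activity distribution solves the
master equation

    d_t p_a = [(a−1+α) p_{a−1} − (a+α) p_a] / (t + α),   p_a(a0) = δ_{a,a0},

whose generating function is `g(z,t) = z^{a0} [z + (1−z)(1+β)]^{−α_r}`. The
solution is a negative binomial in relative activity `a_r = a − a0`, with
shape `α_r` and success odds `β`:

    p_a = C(a_r+α_r−1, a_r) (1+β)^{−α_r} (β/(1+β))^{a_r},

equivalently the beta-function form `p_0 · a_r^{−1}/B(a_r, α_r) ·
(1+1/β)^{−a_r}` with `p_0 = (1+β)^{−α_r}`. Mean is `t`, variance
`σ² = t_r (1+β)`, and the dispersion index

    d = (σ² − t_r) / (σ² + t_r) = β / (2 + β)

depends on `β` alone. `β = 1` (`d = 1/3`) separates the homogeneous,
Poisson-like regime (`β < 1`, Gaussian scaling at large `t_r`) from the
heterogeneous, gamma-like regime (`β > 1`).

### Numerical choices

- All pmf evaluation is in log space through `gammaln`; the beta function is
  never called directly (it overflows for `a_r` in the hundreds).
- Support truncation extends until the cumulative tail is below a tolerance
  (default `1e−12`), starting from a moment-based guess and growing
  geometrically; the truncation point and leaked mass are reported. An
  explicit `a_max` cap is available when only CDF values on a window are
  needed (partial sums are exact regardless of truncation).
- `β = 0` / `t_r = 0` return an explicit point mass at `a0`.
- `classify_regime` labels `|β − 1| ≤ 1e−9` as "crossover"; exact ties never
  occur on data, the tolerance only matters for tests.
- The master-equation integrator (`DOP853`, rtol `1e−10`) is kept as an
  independent oracle for the closed form; it agrees to ~`1e−13` sup-norm on
  parameter sets spanning both regimes.

## Simulation

The event-level process is a Pólya urn. Two exact samplers are provided:
the literal sequential urn (cumulative-weight inversion, O(k) per event),
and a fast path that exploits exchangeability — the urn sequence is, in
law, an iid categorical sequence with `Dirichlet(α_r, …, α_r)` mixing
weights — drawing the weights once and then `τ_r` iid alter choices. The
terminal composition is Dirichlet-multinomial and can be sampled directly.
Equality in law is tested against an exhaustive enumeration oracle at tiny
`(k, τ_r)` and by two-sample chi-square at `k = 3`.

Population synthesis draws per-ego parameters from independent log-uniform
ranges (defaults: `k ∈ [10, 100]`, `α_r ∈ [0.1, 10]`, `t_r ∈ [5, 50]`,
`a0 = 1`), chosen to emulate the broadly distributed degrees and activity
levels of real communication channels; every range is configurable. Each
ego gets its own spawned RNG substream, so generation is order-independent
and byte-reproducible under a fixed seed. Timestamps are consecutive
integers per ego (event order is the only temporal structure the model
uses); optional jitter exists for I/O testing. By default the log carries
each alter's `a0` baseline events as a leading round-robin block, so
aggregation recovers the simulated final activities exactly; an
"empirical-style" mode omits the block, in which case an alter becomes
visible only at its first contact.

What the generator does **not** emulate: circadian/bursty timing, alter
arrival and departure (the model's `k` is fixed), multi-channel coupling,
and any network structure beyond the ego star. Passing tests therefore
validate the estimators under the model's own assumptions, not the model's
adequacy for any particular real channel.

## Fitting

With `k`, `a0` and `t` fixed by the sample, the likelihood has one free
parameter. The profile score is `F_α − ln(1+β)` with
`F_α = mean_i [ψ(a_r,i + α_r) − ψ(α_r)]`; the maximizer solves
`β̂ = e^{F_α} − 1`. The solver evaluates the score on a 49-point log grid
over `α_r ∈ [1e−6, 1e6]` (one sign change for over-dispersed samples, an
asserted property) and polishes the bracketing pair with Brent's method.
Degenerate inputs are explicit: constant samples give `β̂ = 0`
("degenerate-constant"); under-dispersed samples (variance < `t_r`) have no
interior zero and are clamped at the bracket cap ("degenerate-
underdispersed") — such near-Poissonian egos exist in real data and must
not error. Fits use unique-value counts, so cost scales with the number of
distinct activities rather than `k`.

Identifiability is uneven across the parameter space: near the Poisson
corner (small `β`) the Fisher information for the shape parameter is small.
At `β = 0.1`, `t_r = 10`, `k = 10⁴` the Cramér–Rao bound alone implies a
median relative error of ~10% for any estimator, so recovery performance is
assessed over a battery spanning `β ∈ {0.1, 1, 10}`.

## Goodness of fit

The KS statistic `D = max_{a0 ≤ a ≤ a_m} |ΔP_a|` compares empirical and
fitted CDFs on the integer window. Three Cramér–von Mises-family companions
use the standard discrete (Choulakian–Lockhart–Stephens) forms with
model-pmf weights and sample-size factor `k`: `W²`, Anderson–Darling `A²`
(cells with `H(1−H) = 0` dropped) and Watson `U²` (centering with
window-normalized weights). A definition-level direct-sum oracle verifies
all three.

The parametric bootstrap draws `n_sim = 2500` (default) samples of size `k`
from the fitted pmf by inverse CDF on the truncated support, re-fits each
replicate — against its own minimum activity by default, mirroring how the
data pipeline determines `a0`; a switch re-fits against the data's `a0` —
and reports the fraction of simulated statistics at least as large as the
observed one (ties count as extreme, the conservative convention). The fit
is retained when `p > 0.1`. Replicate fit failures are excluded and
counted, never silently dropped.

Calibration caveat: the `a0 := sample minimum` convention is exact only
when the generating distribution places non-negligible mass at `a0`
(`p_0` not tiny). When `p_0` is very small the observed minimum sits above
the true `a0`, the fitted family is slightly misspecified, and bootstrap
p-values skew low. The null-calibration test therefore uses
`α_r = t_r = 1` (`β = 1`, `p_0 = 1/2`), where the convention is exact;
there the p-values are uniform and the `p > 0.1` rule retains ~90% of egos.

## Empirical statistics

- **Dispersion index** uses the population (divide-by-`k`) variance, which
  keeps `d = β/(2+β)` exact in expectation under the model's own moments;
  `k < 2` and all-constant inputs are explicit errors, never NaN.
- **CCDFs** pool alter activities per ego group; grouping by dispersion
  quartiles (over egos with `k ≥ 10` and more than 10 events) or by fitted
  regime (`β ≷ 1`).
- **Connection kernel**: for each event, the risk set is every alter the
  ego contacts over the whole window at its pre-event activity; `π̂_a` is
  pooled successes over pooled opportunities, and the baseline `⟨1/k⟩` is
  the opportunity-weighted mean of `1/k` over the same events. Opportunity
  counts accumulate lazily (each activity level settles when its occupancy
  changes), so cost is O(1) per event. Bins backed by fewer than 30 egos
  (default; 50 for pooled-channel summaries) are suppressed. The activity
  axis is raw by default or `a/a_m`-normalized into 20 fixed-width bins for
  cross-ego pooling. For simulator logs, `baseline_events="auto"` skips
  each ego's leading `k·a0` baseline block so only urn dynamics are scored.
- **Persistence**: each ego's events split into consecutive halves with
  equal counts (odd event goes to the second half); `β` is fitted on the
  whole period and on each half re-aggregated with its own `a0` and `k`;
  `Δβ = β̂(I₂) − β̂(I₁)` is reported relative to the whole-period estimate.
  Alter turnover is the Jaccard similarity between interval alter sets.

## Problem sizes used in the validation suite

Simulation-theory agreement uses `k = 100`, `t = 10³`, 10³ realizations
with total-variation distance on log-spaced activity bins (per-integer TV
has a sampling-noise floor far above any meaningful tolerance when the
support spans thousands of integers). Null calibration uses 500 egos at
`k = 100` with 250 bootstrap replicates each; kernel checks pool 300 egos
of `k = 50` and 10³ events each; persistence checks use 100 egos of
`k = 10³` and 10⁴ events per turnover stratum. These sizes give standard
errors comfortably below the asserted tolerances.

## Known limitations

- The fitted family conditions on the observed minimum; for distributions
  with tiny `p_0` this induces the mild misspecification described above.
- `Δβ/β` is reported against the whole-period `β`, which is itself an
  estimate; egos with `β̂ ≈ 0` give unstable ratios (reported as NaN for
  exactly zero).
- The CvM-family statistics use one reasonable discrete convention; other
  window/weight conventions exist and would change absolute values (not the
  bootstrap p-values, which compare like with like).
- No confidence intervals for `β̂` are provided; the bootstrap machinery
  could support them but they are outside the package's scope.
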