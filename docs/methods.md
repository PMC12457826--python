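# Methods

This note records the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Quantile-threshold discretization

A continuous column is discretized against the CDF of a Gaussian-kernel
density estimate rather than against empirical quantiles. The kernel CDF
`F̂(x) = n⁻¹ Σ Φ((x − x_i)/h)` is smooth and strictly increasing for any
`h > 0`, so the threshold equations `F̂(Q_j) = j/(n+2)`, `j = i, …, i+n−1`,
have unique roots; we solve them by Brent's method bracketed on
`[min − 10h, max + 10h]`, where the kernel CDF is provably below/above any
interior target. The defaults are `n = i = 2` (three levels cut at the 50%
and 75% CDF fractions). The admissible parameterizations are those with all
target fractions in (0, 1), i.e. `i ≤ 2` for the largest threshold index
`i + n − 1 ≤ n + 1`; the generalized `(n, i)` pair is exposed in the
configuration.

Bandwidth default: `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`, the classical
rule-of-thumb for Gaussian kernels. When the IQR is zero (heavy ties) the
rule falls back to the standard deviation; a constant column is an error
unless an explicit bandwidth is supplied. The boundary convention is
`x ≤ Q` → lower level, making the map monotone and right-continuous
decisions unnecessary.

Degenerate data: under extreme point masses two solved thresholds can
coincide (within 1e−12); the empty level is collapsed with a warning and
the reduced level count recorded. For heavily tied columns the realized
occupancies legitimately deviate from the nominal fractions — the invariant
that always holds is the partition property (occupancies sum to one), and
the tests assert exactly that.

Grouping validation is a one-way ANOVA of the raw values across assigned
levels at α = 0.05, reported with per-group mean, sd and n; p-values are
kept at full precision and starred at 0.05/0.01/0.001. Baselines
(equal-width, equal-frequency with 'lower'-interpolated quantile edges so
ties are never split, seeded 1-D k-means relabeled by center order) share
the same output type for comparison studies.

## Latent Gaussian DAG model and the structural-EM fitter

Each ordinal variable is a thresholded view `X_k = l ⇔ Y_k ∈ [α(k,l),
α(k,l+1))` of a latent Gaussian `Y_k`; the latent vector follows a
linear-Gaussian SEM over a DAG. Ordinal data identify neither the location
nor the scale of the latents, so the model is normalized to zero means and
unit *marginal* variances (the conditional-variance alternative would make
thresholds depend on the graph); thresholds are then estimated once by the
marginal probit transform `α(k,l) = Φ⁻¹(P̂[X_k ≤ l−1])`, which is the
maximum-likelihood estimate under the marginal model and consistent
regardless of the graph. After every M-step the refit coefficients and
variances are rescaled back onto this unit-marginal scale.

**E-step.** Given the current implied covariance Σ, latent completions are
drawn by a systematic-scan Gibbs sampler: each full conditional
`Y_k | Y_−k` is univariate normal with precision `Ω_kk`, truncated to the
observed bin, and sampled exactly by inverse-CDF (`Φ⁻¹` of a uniform on the
bin's CDF image, clipped to ±1e−15 for tail stability and clamped into the
half-open bin). One chain is initialized from independent truncated
standard normals and advanced 5 sweeps per completion; K = 5 completions
per iteration by default.

**M-step.** The score is the completion-averaged Gaussian log-likelihood of
each node given its parents (least squares on the stacked completions via
cached sufficient statistics) minus `λ·(|pa| + 2)·log(n)/2`, i.e. a
BIC-type penalty with multiplier λ counting one slope per parent plus
intercept and variance; λ = 6 by default. The score decomposes over nodes,
so greedy hill climbing over single-edge additions, deletions and reversals
(acyclicity checked by reachability, ties broken by a fixed move order)
costs one or two node refits per move. A singular design triggers a ridge
(1e−8) fallback with a warning.

**Convergence.** The total penalized score is Monte-Carlo noisy, so a pure
score-change criterion never triggers at realistic tolerances; the loop
stops when the learned edge set is unchanged between consecutive iterations
*and* the score moved by less than max(tol, 0.1% relative), with tol = 1e−4
and a cap of 25 iterations. On non-convergence the best-scoring iterate is
returned flagged `converged=False` (with a warning), which keeps bootstrap
loops robust.

The fitted DAG is summarized by its Markov equivalence class: skeleton plus
v-structures, closed under the Meek orientation rules (R1–R3 suffice
without background knowledge). The implementation is verified in the tests
against brute-force enumeration of each equivalence class. Bootstrap edge
frequencies resample rows with replacement, refit, convert to a CPDAG, and
count a directed edge as 1 and an undirected edge as 0.5 per direction;
failed resamples are excluded with an adjusted denominator.

## Ordinal causal effects

`do(X_i = l)` is interpreted as graph mutilation plus interval truncation:
edges into `Y_i` are removed, `Y_i` keeps its standardized marginal
N(0, 1) truncated to the bin of level `l`. Because the intervened node is
exogenous in the mutilated graph, its mutilated and observational marginals
coincide, so the two candidate truncation semantics agree under the
unit-marginal normalization. The engine computes total effects through the
mutilated graph; no pathwise decomposition is attempted.

Under the mutilated joint `(Y_i, Y_o)` is bivariate normal, so

`P[Y_o ∈ bin k | do(Y_i ∈ bin l)] = E_{Y_i ~ TN(bin l)}[Φ((α_hi − cY_i)/s) − Φ((α_lo − cY_i)/s)]`

with `c = Σ_io/Σ_ii` and `s² = Σ_oo − Σ_io²/Σ_ii`. The expectation is
evaluated on the uniform scale `u = Φ(y/√Σ_ii)` — where the truncated
density is flat and semi-infinite bins become finite intervals — by
adaptive quadrature (absolute tolerance 1e−13). This is an exact reduction
of the bivariate-normal rectangle probability (the tests cross-check it
against scipy's bivariate CDF); its advantage is that the integrand sums to
one over outcome bins pointwise, so the computed probabilities are
normalized to quadrature accuracy and the OCE cells sum to zero over
outcome levels to ~1e−11. Antisymmetry `OCE(k, l→l′) = −OCE(k, l′→l)` is
exact by construction. Degenerate residual variance (|correlation| → 1) is
floored with a warning; an intervention bin with (near-)zero marginal mass
is an error naming the bin. The independent oracle forward-simulates the
mutilated SEM with the intervened latent drawn from its truncated marginal
and reports binomial standard errors.

## Synthetic data

Generators are pure functions of (config, seed). Random DAGs draw a
topological order and Bernoulli edges; coefficients avoid the near-null
band (|b| ∈ [0.3, 0.9]) so recovery studies are not dominated by barely
detectable edges. The chain generator sets conditional variances to
`1 − b²`, making `b` exactly the adjacent-latent correlation. The
training-log emulator reproduces the marginal shapes of a day-level running
log — a small ordinal session count, kilometre columns that are mostly zero
(rest days) with lognormal tails and increasing zero-inflation for higher
intensity zones, bounded self-ratings with a spike at zero, binary strength
and injury flags — with only a crude load-driven coupling between columns.
Passing tests on it therefore demonstrate pipeline correctness on
realistically shaped marginals, not recovery of any particular real-world
causal structure, and nothing about longitudinal (athlete-level)
correlation, which the generator deliberately omits.

## Problem sizes and defaults

Reference analysis settings: K = 5 completions, λ = 6, B = 500 bootstrap
resamples, three QTF levels at fractions (0.5, 0.75). The test suite
exercises the learner at n = 250–5000 records and m = 3–5 variables, the
recovery benchmark at n = 2000 over 20 seeds, oracle comparisons at 1e5
draws, and bootstrap loops at B = 3–25; these sizes were chosen so the full
suite documents the statistical claims while remaining quick to run.
Bootstrap defaults (B = 500) are intended for real analyses.

## Known limitations

- Structure learning assumes every column has ≥ 2 occupied levels;
  unoccupied interior levels are collapsed, so reported level indices can
  differ from the raw coding (the level-label map is retained).
- The score-based search finds a local optimum; no restarts are performed
  beyond the EM alternation itself (the bootstrap gives a stability view).
- Joint (multi-node) interventions and mixed continuous+ordinal learning
  are out of scope.
- The quadrature path evaluates one (intervention, outcome) pair at a time;
  effects through the full graph are total effects, labelled as such even
  where a "direct effect" reading is colloquially used for a single-edge
  pair.
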