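# ordcause

Causal analysis of mixed continuous/ordinal tables, built for
sports-epidemiology style data (daily training logs, self-ratings, injury
flags) where most variables are either inherently ordered or need a
principled ordered discretization before any graphical causal analysis is
possible.

The package chains three pieces:

1. **Quantile-threshold discretization (QTF).** A continuous variable
   `X = (x_1, …, x_n)` gets a Gaussian-kernel density fit
   `f̂(x) = (1/nh) Σ K((x − x_i)/h)` with the rule-of-thumb bandwidth
   `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`. Thresholds `Q_i, …, Q_{i+n−1}`
   solve `F̂(Q_j) = j/(n+2)` on the fitted CDF; with the default
   `n = i = 2` the cuts sit at the 50% and 75% points, giving three ordered
   levels with nominal occupancies 0.5 / 0.25 / 0.25 on tie-free data. A
   one-way ANOVA of the raw values across levels validates the grouping;
   equal-width, equal-frequency and 1-D k-means discretizers are included
   as baselines.
2. **Latent Gaussian DAG learning.** Each ordinal `X_k` is modelled as a
   discretization of a latent Gaussian `Y_k` at thresholds
   `α(k,0) = −∞ < α(k,1) < … < α(k,L_k) = +∞`, while `Y` follows a
   linear-Gaussian structural equation model
   `Y_k | y_pa(k) ~ N(μ_k + Σ_j b_jk (y_j − μ_j), v_k)` over a DAG. A
   structural-EM fitter alternates Gibbs sampling of latent completions
   restricted to the observed threshold bins (Monte-Carlo size `K`, default
   5) with penalized-score hill climbing (penalty `λ·#params·log(n)/2`,
   default `λ = 6`). The fitted DAG is reported through its Markov
   equivalence class (CPDAG), with bootstrap directed-edge frequencies over
   row resamples (default `B = 500`).
3. **Ordinal causal effects (OCE).** An intervention `do(X_i = l)` is read
   on the latent scale: `Y_i` is severed from its parents and drawn from its
   standardized marginal truncated to the bin `[α(i,l), α(i,l+1))`. The OCE
   of a shift `l → l′` on outcome level `k`,

   `OCE_io(k, l→l′) = P[Y_o ∈ bin k | do(Y_i ∈ bin l′)] − P[Y_o ∈ bin k | do(Y_i ∈ bin l)]`,

   is computed exactly from the bivariate normal law of `(Y_i, Y_o)` under
   the mutilated graph, and is antisymmetric in `(l, l′)` and sums to zero
   over outcome levels. A forward-simulation Monte-Carlo oracle provides an
   independent check, and a bootstrap variant exports the raincloud-plot
   distribution of each effect cell.

## Worked example

`examples/03_ordinal_effects.py` computes the OCE table of `X1` on `X3` for
a three-level chain `X1 → X2 → X3` with adjacent latent correlation 0.8:

```
intervention outcome  outcome_level  from_level  to_level   value
          X1      X3              0           0         1 -0.3296
          X1      X3              1           0         1  0.1256
          X1      X3              2           0         1  0.2041
          X1      X3              0           0         2 -0.5337
          X1      X3              1           0         2 -0.0000
          X1      X3              2           0         2  0.5337
          X1      X3              0           1         2 -0.2041
          X1      X3              1           1         2 -0.1256
          X1      X3              2           1         2  0.3296

top-level OCE for shift 0 -> 2: exact 0.5337, oracle 0.5361 +- 0.0013
```

Forcing `X1` from its bottom to its top level moves 53 percentage points of
probability mass out of the bottom outcome level and into the top one; each
shift block sums to zero because outcome probabilities are conserved, and
the quadrature value agrees with the forward-simulation oracle within
Monte-Carlo error. The other examples cover QTF discretization with ANOVA
validation (`01`), DAG learning with bootstrap CPDAG frequencies (`02`),
and the full pipeline on a synthetic training log (`04`).

The `ordcause` console script exposes the same stages as subcommands
(`discretize`, `anova`, `learn`, `bootstrap`, `oce`, `simulate`, `run`);
`ordcause run --data data.csv --config config.yaml` executes the whole
pipeline and writes provenance-stamped CSV artifacts per stage.

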