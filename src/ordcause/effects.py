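"""Ordinal causal effects on a latent Gaussian DAG.

An intervention do(X_i = level l) is interpreted on the latent scale: the
intervened latent variable Y_i is cut off from its parents (graph
mutilation) and drawn from its standardized marginal N(0, 1) truncated to
the threshold bin [a(i, l), a(i, l+1)) of the target level.  The ordinal
causal effect of shifting the intervention from level l to level l' on
outcome level k is the interventional probability contrast

    OCE_io(k, l -> l') = P[Y_o in bin k | do(Y_i in bin l')]
                       - P[Y_o in bin k | do(Y_i in bin l)],

which is antisymmetric in (l, l') and sums to zero over the outcome levels.
Probabilities are evaluated exactly by reducing the bivariate-normal
rectangle over (Y_i, Y_o) under the mutilated joint to a one-dimensional
integral over the truncated intervention variable, solved by adaptive
quadrature; a forward-simulation Monte-Carlo oracle is provided for
independent verification.

Levels are 0-based throughout, matching the integer coding of
:class:`~ordcause.dataset.OrdinalDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr, ndtri

from .dataset import OrdinalDataset
from .latent_dag import LatentGaussianDAG, osem_fit

__all__ = [
    "InterventionSpec",
    "mutilate",
    "interventional_bin_probability",
    "oce",
    "oce_matrix",
    "oce_bootstrap",
    "mc_interventional_bin_probability",
    "mc_oracle_oce",
]


@dataclass(frozen=True)
class InterventionSpec:
    """One OCE cell: shift intervention from_level -> to_level, watch outcome_level."""

    intervention: str
    outcome: str
    from_level: int
    to_level: int
    outcome_level: int

    def validate(self, model: LatentGaussianDAG) -> None:
        if self.intervention == self.outcome:
            raise ValueError("intervention and outcome must differ")
        if self.from_level == self.to_level:
            raise ValueError("from_level and to_level must differ")
        li = model.n_levels(self.intervention)
        lo = model.n_levels(self.outcome)
        for lvl, bound, what in (
            (self.from_level, li, "from_level"),
            (self.to_level, li, "to_level"),
            (self.outcome_level, lo, "outcome_level"),
        ):
            if not 0 <= lvl < bound:
                raise ValueError(f"{what}={lvl} outside 0..{bound - 1}")


def mutilate(model: LatentGaussianDAG, intervention: str | int) -> LatentGaussianDAG:
    """Graph surgery: delete edges into the intervention node (see model API)."""
    return model.mutilated(intervention)


def _pair_moments(model: LatentGaussianDAG, i: int, o: int) -> tuple[float, float, float]:
    sigma = model.implied_covariance()
    return float(sigma[i, i]), float(sigma[o, o]), float(sigma[i, o])


def interventional_bin_probability(
    model: LatentGaussianDAG,
    intervention: str | int,
    outcome: str | int,
    outcome_level: int,
    intervention_level: int,
) -> float:
    """P[Y_o in outcome bin | do(Y_i in intervention bin)].

    Under the mutilated joint the pair (Y_i, Y_o) is bivariate normal, so
    the conditional probability of the outcome bin given Y_i = y is a
    difference of normal CDFs; the do-probability is its expectation under
    Y_i truncated to the intervention bin.  That expectation is computed on
    the uniform scale u = Phi(y / s_i), where the truncated density is flat,
    with adaptive quadrature (abs. tolerance 1e-13).  Because the integrand
    sums to one over the outcome bins pointwise, the probabilities over
    outcome levels sum to one up to quadrature error.
    """
    i = model.index(intervention)
    o = model.index(outcome)
    if i == o:
        raise ValueError("intervention and outcome must differ")
    mut = model.mutilated(i)
    s_ii, s_oo, s_io = _pair_moments(mut, i, o)
    sd_i = np.sqrt(s_ii)

    a_i = model.thresholds[i]
    a_o = model.thresholds[o]
    lo_i, hi_i = a_i[intervention_level], a_i[intervention_level + 1]
    lo_o, hi_o = a_o[outcome_level], a_o[outcome_level + 1]

    u_lo, u_hi = ndtr(lo_i / sd_i), ndtr(hi_i / sd_i)
    mass = u_hi - u_lo
    if mass <= 1e-12:
        raise ValueError(
            f"intervention bin {intervention_level} of "
            f"{model.nodes[i]!r} has (near-)zero probability"
        )

    slope = s_io / s_ii  # regression of Y_o on Y_i under mutilation
    resid = s_oo - s_io**2 / s_ii
    if resid < 1e-20:
        warnings.warn("degenerate intervention-outcome correlation; perturbing",
                      stacklevel=2)
        resid = 1e-20
    sd_r = np.sqrt(resid)

    if slope == 0.0:  # no open path i -> o: marginal outcome probability
        sd_o = np.sqrt(s_oo)
        return float(ndtr(hi_o / sd_o) - ndtr(lo_o / sd_o))

    def integrand(u: float) -> float:
        y = sd_i * ndtri(u)
        return ndtr((hi_o - slope * y) / sd_r) - ndtr((lo_o - slope * y) / sd_r)

    val, _ = integrate.quad(
        integrand, u_lo, u_hi, epsabs=1e-13, epsrel=1e-13, limit=200
    )
    return float(np.clip(val / mass, 0.0, 1.0))


def oce(model: LatentGaussianDAG, spec: InterventionSpec) -> float:
    """Ordinal causal effect for one (outcome level, level shift) cell."""
    spec.validate(model)
    p_to = interventional_bin_probability(
        model, spec.intervention, spec.outcome, spec.outcome_level, spec.to_level
    )
    p_from = interventional_bin_probability(
        model, spec.intervention, spec.outcome, spec.outcome_level, spec.from_level
    )
    return p_to - p_from


def oce_matrix(
    model: LatentGaussianDAG,
    intervention: str,
    outcome: str,
) -> pd.DataFrame:
    """All OCE cells for one intervention-outcome pair, long format.

    Rows cover every outcome level k and every upward shift l < l'; the
    table has L_o * C(L_i, 2) rows.  Downward shifts follow by antisymmetry.
    """
    i = model.index(intervention)
    o = model.index(outcome)
    L_i, L_o = model.n_levels(i), model.n_levels(o)
    probs = {
        l: [
            interventional_bin_probability(model, intervention, outcome, k, l)
            for k in range(L_o)
        ]
        for l in range(L_i)
    }
    rows = []
    for l in range(L_i):
        for lp in range(l + 1, L_i):
            for k in range(L_o):
                rows.append({
                    "intervention": intervention,
                    "outcome": outcome,
                    "outcome_level": k,
                    "from_level": l,
                    "to_level": lp,
                    "value": probs[lp][k] - probs[l][k],
                })
    return pd.DataFrame(rows)


def oce_bootstrap(
    data: OrdinalDataset,
    intervention: str,
    outcome: str,
    B: int = 500,
    K: int = 5,
    lam: float = 6.0,
    seed: int = 0,
    **osem_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap distribution of the OCE table (raincloud-plot data).

    Each of the B row-resamples is refit with the structural-EM learner and
    its full OCE table computed.  Returns the long table with a
    ``bootstrap_rep`` column and the per-cell means (the diamond points of a
    raincloud display).
    """
    rng = np.random.default_rng(seed)
    tables = []
    for b in range(B):
        fit_seed = int(rng.integers(2**31))
        try:
            boot = data.resample(rng)
            fit = osem_fit(boot, K=K, lam=lam, seed=fit_seed, **osem_kwargs)
            tab = oce_matrix(fit, intervention, outcome)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"bootstrap resample {b} failed: {exc}", stacklevel=2)
            continue
        tab["bootstrap_rep"] = b
        tables.append(tab)
    if not tables:
        raise RuntimeError("all bootstrap resamples failed")
    long = pd.concat(tables, ignore_index=True)
    summary = (
        long.groupby(["intervention", "outcome", "outcome_level",
                      "from_level", "to_level"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean_oce"})
    )
    return long, summary


# ---------------------------------------------------------------------------
# forward-simulation oracle
# ---------------------------------------------------------------------------

def _forward_simulate_do(
    model: LatentGaussianDAG,
    i: int,
    intervention_level: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ancestral sampling of the mutilated SEM with Y_i truncated to its bin."""
    mut = model.mutilated(i)
    a_i = model.thresholds[i]
    lo, hi = a_i[intervention_level], a_i[intervention_level + 1]
    u = ndtr(lo) + rng.random(n_draws) * (ndtr(hi) - ndtr(lo))
    y_i = ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    Y = np.empty((n_draws, mut.m))
    for k in mut.topological_order():
        if k == i:
            Y[:, k] = y_i
            continue
        mean = np.zeros(n_draws)
        for j in mut.parents(k):
            mean += mut.coefficients[j, k] * Y[:, j]
        Y[:, k] = mean + np.sqrt(mut.cond_variances[k]) * rng.standard_normal(n_draws)
    return Y


def mc_interventional_bin_probability(
    model: LatentGaussianDAG,
    intervention: str | int,
    outcome: str | int,
    outcome_level: int,
    intervention_level: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and standard error) of the do-bin probability."""
    i = model.index(intervention)
    o = model.index(outcome)
    rng = np.random.default_rng(seed)
    Y = _forward_simulate_do(model, i, intervention_level, n_draws, rng)
    a_o = model.thresholds[o]
    hit = (Y[:, o] >= a_o[outcome_level]) & (Y[:, o] < a_o[outcome_level + 1])
    p = hit.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return float(p), float(se)


def mc_oracle_oce(
    model: LatentGaussianDAG,
    spec: InterventionSpec,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Forward-simulation estimate of one OCE cell with its standard error."""
    spec.validate(model)
    p_to, se_to = mc_interventional_bin_probability(
        model, spec.intervention, spec.outcome, spec.outcome_level,
        spec.to_level, n_draws, seed,
    )
    p_from, se_from = mc_interventional_bin_probability(
        model, spec.intervention, spec.outcome, spec.outcome_level,
        spec.from_level, n_draws, seed + 1,
    )
    return p_to - p_from, float(np.hypot(se_to, se_from))
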