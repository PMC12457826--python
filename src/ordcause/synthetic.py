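"""Seeded generators for every input the pipeline consumes.

Covers random DAG models with linear-Gaussian mechanisms, threshold
discretization into ordinal datasets, and continuous columns with the
zero-inflated spikes typical of daily training-load variables (a point mass
at zero for rest days plus a lognormal tail for active days).  All
generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .dataset import OrdinalDataset
from .latent_dag import LatentGaussianDAG

__all__ = [
    "random_dag",
    "random_model",
    "chain_model",
    "simulate_latent",
    "discretize_latent",
    "simulate_ordinal",
    "zero_inflated_lognormal",
    "make_training_log_like",
    "TRAINING_LOG_COLUMNS",
]

DEFAULT_COEF_RANGE = (0.3, 0.9)  # avoids near-null edges in recovery studies


def random_dag(m: int, edge_probability: float, seed: int = 0) -> np.ndarray:
    """Random DAG adjacency: random topological order + Bernoulli edges.

    ``edge_probability = 1`` gives the complete DAG with C(m, 2) edges.
    """
    if not 0 <= edge_probability <= 1:
        raise ValueError("edge_probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    adj = np.zeros((m, m), dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            if rng.random() < edge_probability:
                adj[order[a], order[b]] = True
    return adj


def equal_level_thresholds(n_levels: int) -> np.ndarray:
    """Standard-normal thresholds giving equal level occupancies."""
    cum = np.arange(1, n_levels) / n_levels
    return np.concatenate([[-np.inf], ndtri(cum), [np.inf]])


def random_model(
    m: int,
    edge_probability: float = 0.4,
    levels: int | list[int] = 3,
    seed: int = 0,
    coef_range: tuple[float, float] = DEFAULT_COEF_RANGE,
) -> LatentGaussianDAG:
    """Random standardized latent Gaussian DAG with discretization thresholds.

    Edge coefficients are drawn uniformly from +-[coef_range] with random
    sign; conditional variances start at 1 and the model is standardized to
    unit marginal variances.  Thresholds default to equal level occupancies.
    """
    rng = np.random.default_rng(seed)
    adj = random_dag(m, edge_probability, seed=int(rng.integers(2**31)))
    lo, hi = coef_range
    B = np.where(
        adj,
        rng.uniform(lo, hi, size=(m, m)) * rng.choice([-1.0, 1.0], size=(m, m)),
        0.0,
    )
    if isinstance(levels, int):
        levels = [levels] * m
    model = LatentGaussianDAG(
        nodes=[f"X{i + 1}" for i in range(m)],
        adjacency=adj,
        coefficients=B,
        means=np.zeros(m),
        cond_variances=np.ones(m),
        thresholds=[equal_level_thresholds(L) for L in levels],
    )
    return model.standardized()


def chain_model(
    m: int = 3,
    b: float = 0.8,
    levels: int = 3,
    level_fractions: np.ndarray | None = None,
) -> LatentGaussianDAG:
    """Standardized chain X1 -> X2 -> ... -> Xm with common edge strength b.

    Conditional variances are set to 1 - b**2 so every latent has unit
    marginal variance and ``b`` is exactly the correlation between adjacent
    latents.
    """
    if not -1 < b < 1:
        raise ValueError("chain coefficient must lie in (-1, 1)")
    adj = np.zeros((m, m), dtype=bool)
    B = np.zeros((m, m))
    v = np.ones(m)
    for j in range(m - 1):
        adj[j, j + 1] = True
        B[j, j + 1] = b
        v[j + 1] = 1 - b**2
    if level_fractions is None:
        thr = [equal_level_thresholds(levels) for _ in range(m)]
    else:
        cum = np.cumsum(level_fractions)[:-1]
        thr = [np.concatenate([[-np.inf], ndtri(cum), [np.inf]]) for _ in range(m)]
    model = LatentGaussianDAG(
        nodes=[f"X{i + 1}" for i in range(m)],
        adjacency=adj,
        coefficients=B,
        means=np.zeros(m),
        cond_variances=v,
        thresholds=thr,
    )
    return model.standardized()


def simulate_latent(model: LatentGaussianDAG, n: int, seed: int = 0) -> np.ndarray:
    """Ancestral sampling of the latent linear-Gaussian SEM (n x m matrix)."""
    rng = np.random.default_rng(seed)
    Y = np.empty((n, model.m))
    for k in model.topological_order():
        mean = np.full(n, model.means[k])
        for j in model.parents(k):
            mean += model.coefficients[j, k] * (Y[:, j] - model.means[j])
        Y[:, k] = mean + np.sqrt(model.cond_variances[k]) * rng.standard_normal(n)
    return Y


def discretize_latent(Y: np.ndarray, model: LatentGaussianDAG) -> OrdinalDataset:
    """Apply the threshold rule: level l iff Y in [a(k, l), a(k, l+1))."""
    cols = {}
    for k, name in enumerate(model.nodes):
        inner = model.thresholds[k][1:-1]
        cols[name] = np.searchsorted(inner, Y[:, k], side="right").astype(int)
    frame = pd.DataFrame(cols)
    return OrdinalDataset.from_frame(frame)


def simulate_ordinal(model: LatentGaussianDAG, n: int, seed: int = 0) -> OrdinalDataset:
    """Convenience: simulate latents and discretize them in one call."""
    return discretize_latent(simulate_latent(model, n, seed), model)


def zero_inflated_lognormal(
    n: int,
    zero_weight: float,
    mu: float = 1.5,
    sigma: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Point mass at zero (rest days) plus a lognormal tail (active days)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = rng.random(n) >= zero_weight
    out = np.zeros(n)
    out[active] = rng.lognormal(mu, sigma, size=int(active.sum()))
    return out


#: (name, kind) schema of the emulated daily training log: session count,
#: running-volume columns with rest-day spikes at zero, a strength-training
#: flag, bounded self-ratings in [0, 1], cross-training hours and an injury
#: flag.  Mirrors an 11-variable day-level running log.
TRAINING_LOG_COLUMNS: list[tuple[str, str]] = [
    ("Sessions", "ordinal"),
    ("Totalkm", "continuous"),
    ("Kmmiddle", "continuous"),
    ("Kmhigh", "continuous"),
    ("Kmsprinting", "continuous"),
    ("Strengthtraining", "ordinal"),
    ("PerceivedtrainingSuccess", "continuous"),
    ("Hoursalternative", "continuous"),
    ("Perceivedexertion", "continuous"),
    ("Perceivedrecovery", "continuous"),
    ("Injury", "ordinal"),
]


def make_training_log_like(
    n: int = 2000,
    seed: int = 0,
    injury_rate: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic day-level training log with realistic marginal shapes.

    Emulates the variable mix of a daily running log: a small ordinal
    session count, kilometre columns that are mostly zero with a lognormal
    tail on active days (increasingly zero-inflated for higher intensity
    zones), a binary strength-training flag, self-ratings in [0, 1] with a
    spike at zero on rest days, and a rare binary injury flag.  Marginals
    only - the inter-column dependence is a simple load-driven coupling, not
    a calibrated causal model.
    """
    rng = np.random.default_rng(seed)
    sessions = rng.choice([0, 1, 2], size=n, p=[0.35, 0.5, 0.15])
    rest = sessions == 0
    total = zero_inflated_lognormal(n, 0.0, mu=2.2, sigma=0.5, seed=rng)
    total[rest] = 0.0
    frac_mid = rng.beta(1.2, 8.0, size=n)
    frac_high = rng.beta(1.0, 12.0, size=n)
    frac_sprint = rng.beta(0.8, 30.0, size=n)
    km_mid = np.where(rng.random(n) < 0.35, total * frac_mid, 0.0)
    km_high = np.where(rng.random(n) < 0.25, total * frac_high, 0.0)
    km_sprint = np.where(rng.random(n) < 0.12, total * frac_sprint, 0.0)
    strength = (rng.random(n) < 0.2).astype(int)
    success = np.where(rest, 0.0, rng.beta(5, 2, size=n))
    hours_alt = zero_inflated_lognormal(n, 0.9, mu=0.3, sigma=0.4, seed=rng)
    exertion = np.where(rest, 0.0, rng.beta(3, 4, size=n))
    recovery = np.where(rest, 0.0, rng.beta(4, 5, size=n))
    load = (total - total.mean()) / (total.std() + 1e-9)
    injury = (
        rng.random(n) < np.clip(injury_rate + 0.05 * np.maximum(load, 0), 0, 1)
    ).astype(int)
    frame = pd.DataFrame({
        "Sessions": sessions,
        "Totalkm": total,
        "Kmmiddle": km_mid,
        "Kmhigh": km_high,
        "Kmsprinting": km_sprint,
        "Strengthtraining": strength,
        "PerceivedtrainingSuccess": success,
        "Hoursalternative": hours_alt,
        "Perceivedexertion": exertion,
        "Perceivedrecovery": recovery,
        "Injury": injury,
    })
    return frame, dict(TRAINING_LOG_COLUMNS)
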