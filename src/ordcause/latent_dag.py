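"""Latent Gaussian DAG learning from ordinal data.

Each observed ordinal variable X_k (levels 0 .. L_k - 1) is modelled as a
marginal discretization of a latent Gaussian variable Y_k at thresholds
-inf = a(k,0) < a(k,1) < ... < a(k,L_k) = +inf, while the latent vector Y
follows a linear-Gaussian structural equation model over a DAG:

    Y_k | y_pa(k) ~ N( mu_k + sum_j b_jk (y_j - mu_j), v_k ).

The structural-EM learner alternates a Monte-Carlo E-step (Gibbs sampling of
latent completions restricted to the observed threshold bins) with an M-step
(penalized-score hill-climbing over DAGs plus least-squares parameter
refits).  The latent scale is not identified by ordinal data, so after every
M-step the model is standardized to zero mean and unit marginal variance;
thresholds then live on the standard-normal scale and are estimated once by
the marginal probit transform of the observed level frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.special import ndtr, ndtri

from .dataset import OrdinalDataset

__all__ = [
    "LatentGaussianDAG",
    "CPDAG",
    "CPDAGSummary",
    "estimate_thresholds",
    "sample_latent_completion",
    "ScoreCache",
    "node_score",
    "structure_search",
    "osem_fit",
    "dag_to_cpdag",
    "bootstrap_cpdag",
]

_EPS_GAIN = 1e-9  # minimum score improvement accepted by the hill climber


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class LatentGaussianDAG:
    """Linear-Gaussian DAG over latent variables with discretization thresholds.

    ``adjacency[j, k]`` is True iff there is an edge j -> k, in which case
    ``coefficients[j, k]`` holds b_jk.  ``thresholds[k]`` has length
    L_k + 1 and includes the infinite endpoints.
    """

    nodes: list[str]
    adjacency: np.ndarray
    coefficients: np.ndarray
    means: np.ndarray
    cond_variances: np.ndarray
    thresholds: list[np.ndarray]
    converged: bool = True
    n_iter: int = 0
    score: float = field(default=np.nan)

    def __post_init__(self) -> None:
        m = len(self.nodes)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.cond_variances = np.asarray(self.cond_variances, dtype=float)
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency shape mismatch")
        if np.any(self.cond_variances <= 0):
            raise ValueError("conditional variances must be positive")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph has a directed cycle")
        for k, a in enumerate(self.thresholds):
            a = np.asarray(a, dtype=float)
            if not (np.isneginf(a[0]) and np.isposinf(a[-1])):
                raise ValueError(f"thresholds of {self.nodes[k]!r} lack +-inf endpoints")
            if np.any(np.diff(a) <= 0):
                raise ValueError(f"thresholds of {self.nodes[k]!r} not increasing")
            self.thresholds[k] = a

    # -- structure ---------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.nodes)

    def index(self, node: str | int) -> int:
        return node if isinstance(node, (int, np.integer)) else self.nodes.index(node)

    def n_levels(self, node: str | int) -> int:
        return len(self.thresholds[self.index(node)]) - 1

    def parents(self, k: str | int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[:, self.index(k)])

    def edges(self) -> list[tuple[str, str]]:
        return [(self.nodes[j], self.nodes[k])
                for j, k in zip(*np.nonzero(self.adjacency))]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def topological_order(self) -> list[int]:
        return [self.nodes.index(v) for v in nx.topological_sort(self.to_networkx())]

    def copy(self) -> "LatentGaussianDAG":
        return LatentGaussianDAG(
            nodes=list(self.nodes),
            adjacency=self.adjacency.copy(),
            coefficients=self.coefficients.copy(),
            means=self.means.copy(),
            cond_variances=self.cond_variances.copy(),
            thresholds=[a.copy() for a in self.thresholds],
            converged=self.converged,
            n_iter=self.n_iter,
            score=self.score,
        )

    # -- implied Gaussian --------------------------------------------------

    def implied_covariance(self) -> np.ndarray:
        """Sigma = (I - B^T)^{-1} V (I - B)^{-1} of the latent joint."""
        m = self.m
        B = np.where(self.adjacency, self.coefficients, 0.0)
        inv = np.linalg.inv(np.eye(m) - B.T)
        sigma = inv @ np.diag(self.cond_variances) @ inv.T
        return (sigma + sigma.T) / 2

    def implied_precision(self) -> np.ndarray:
        return np.linalg.inv(self.implied_covariance())

    def standardized(self) -> "LatentGaussianDAG":
        """Rescale to zero means and unit marginal variances (same DAG)."""
        d = np.sqrt(np.diag(self.implied_covariance()))
        out = self.copy()
        out.means = np.zeros(self.m)
        out.coefficients = self.coefficients * d[:, None] / d[None, :]
        out.cond_variances = self.cond_variances / d**2
        return out

    def mutilated(self, node: str | int) -> "LatentGaussianDAG":
        """Remove all edges into ``node`` (Pearl's graph surgery).

        The intervened node keeps its standardized marginal N(0, 1); every
        other conditional mechanism is untouched.
        """
        k = self.index(node)
        out = self.copy()
        out.adjacency[:, k] = False
        out.coefficients[:, k] = 0.0
        out.means[k] = 0.0
        out.cond_variances[k] = 1.0
        return out


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(counts: np.ndarray) -> np.ndarray:
    """Probit thresholds from level counts: a(k,l) = Phi^{-1}(P[X <= l-1]).

    Returns an array of length L+1 including the -inf / +inf endpoints.
    Interior zero-count levels are rejected (they should have been collapsed
    upstream); a single occupied level is an error because the latent scale
    would be unconstrained.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts > 0).sum() < 2:
        raise ValueError("threshold estimation needs >= 2 occupied levels")
    if np.any(counts == 0):
        raise ValueError("unoccupied level present; collapse levels first")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return np.concatenate([[-np.inf], ndtri(cum), [np.inf]])


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float | np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Vectorized truncated-normal draws by inverse-CDF on [lo, hi)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + rng.random(np.shape(mean)) * (b - a)
    y = mean + sd * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    # numerical tails can leak just outside the bin; clamp into [lo, hi)
    y = np.maximum(y, lo)
    finite_hi = np.isfinite(hi)
    y = np.where(finite_hi & (y >= hi), np.nextafter(hi, -np.inf), y)
    return y


def sample_latent_completion(
    data: OrdinalDataset,
    model: LatentGaussianDAG,
    K: int = 5,
    seed: int | np.random.Generator = 0,
    sweeps: int = 5,
    init: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Draw K latent completions consistent with the observed level bins.

    A single systematic-scan Gibbs chain runs over the nodes; each full
    conditional Y_k | Y_-k is univariate normal (from the implied joint)
    truncated to the observed bin [a(k, x), a(k, x+1)).  Each completion is
    the chain state after ``sweeps`` further sweeps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = data.as_matrix()
    n, m = X.shape
    omega = model.implied_precision()
    lows = np.empty((n, m))
    highs = np.empty((n, m))
    for k in range(m):
        a = model.thresholds[k]
        lows[:, k] = a[X[:, k]]
        highs[:, k] = a[X[:, k] + 1]

    if init is None:
        Y = np.empty((n, m))
        for k in range(m):  # independent truncated standard normals
            Y[:, k] = _truncated_normal(rng, np.zeros(n), 1.0, lows[:, k], highs[:, k])
    else:
        Y = init.copy()

    cond_sd = 1.0 / np.sqrt(np.diag(omega))
    completions = []
    for _ in range(K):
        for _ in range(sweeps):
            for k in range(m):
                w = -omega[:, k] / omega[k, k]
                w[k] = 0.0
                mean = Y @ w
                Y[:, k] = _truncated_normal(rng, mean, cond_sd[k],
                                            lows[:, k], highs[:, k])
        completions.append(Y.copy())
    return completions


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class ScoreCache:
    """Decomposable penalized Gaussian score over Monte-Carlo completions.

    Sufficient statistics (Gram matrix and column sums of the stacked
    completions) are precomputed once; each (node, parent-set) score is a
    small linear solve, cached for reuse during hill climbing.
    """

    def __init__(self, completions: list[np.ndarray], lam: float):
        Y = np.vstack(completions)
        self.N = Y.shape[0]                      # K * n stacked rows
        self.n = completions[0].shape[0]         # records
        self.m = Y.shape[1]
        self.lam = float(lam)
        self.gram = Y.T @ Y
        self.sums = Y.sum(axis=0)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def fit_node(self, k: int, parents: tuple[int, ...]) -> tuple[np.ndarray, float]:
        """Least-squares fit of Y_k on [1, Y_parents]; returns (beta, sigma2)."""
        p = list(parents)
        A = np.empty((len(p) + 1, len(p) + 1))
        A[0, 0] = self.N
        A[0, 1:] = self.sums[p]
        A[1:, 0] = self.sums[p]
        A[1:, 1:] = self.gram[np.ix_(p, p)]
        b = np.concatenate([[self.sums[k]], self.gram[p, k]])
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn("singular design in node fit; ridge fallback",
                          stacklevel=2)
            beta = np.linalg.solve(A + 1e-8 * np.eye(len(b)), b)
        rss = self.gram[k, k] - beta @ b
        sigma2 = max(rss / self.N, 1e-12)
        return beta, sigma2

    def node_score(self, k: int, parents: tuple[int, ...]) -> float:
        """Average log-likelihood of node k minus lam * |params| * log(n)/2."""
        key = (k, tuple(sorted(parents)))
        if key not in self._cache:
            _, sigma2 = self.fit_node(k, key[1])
            # average over completions == stacked loglik * n / N
            loglik = -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)
            penalty = self.lam * (len(key[1]) + 2) * np.log(self.n) / 2.0
            self._cache[key] = loglik - penalty
        return self._cache[key]

    def total_score(self, adjacency: np.ndarray) -> float:
        return sum(
            self.node_score(k, tuple(np.flatnonzero(adjacency[:, k])))
            for k in range(self.m)
        )


def node_score(
    completions: list[np.ndarray],
    k: int,
    parents: tuple[int, ...],
    lam: float = 6.0,
) -> float:
    """Standalone penalized node score (see :class:`ScoreCache`)."""
    return ScoreCache(completions, lam).node_score(k, tuple(parents))


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _has_path(adjacency: np.ndarray, src: int, dst: int) -> bool:
    """Directed reachability src ~> dst by DFS on the boolean adjacency."""
    if src == dst:
        return True
    stack = [src]
    seen = np.zeros(adjacency.shape[0], dtype=bool)
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(adjacency[u]):
            if v == dst:
                return True
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return False


def structure_search(
    completions: list[np.ndarray],
    lam: float = 6.0,
    init_adjacency: np.ndarray | None = None,
    cache: ScoreCache | None = None,
) -> tuple[np.ndarray, float]:
    """Greedy hill climbing over single-edge additions/deletions/reversals.

    Moves are scanned in a fixed order and ties broken by (gain, move order),
    so the search is deterministic for given completions.  Returns the local
    optimum adjacency and its total penalized score.
    """
    cache = cache or ScoreCache(completions, lam)
    m = cache.m
    adj = (np.zeros((m, m), dtype=bool) if init_adjacency is None
           else init_adjacency.copy())

    def pa(k):
        return tuple(np.flatnonzero(adj[:, k]))

    scores = [cache.node_score(k, pa(k)) for k in range(m)]
    while True:
        best = None  # (gain, order, move)
        order = 0
        for j in range(m):
            for k in range(m):
                if j == k:
                    continue
                order += 1
                if adj[j, k]:
                    # deletion
                    new_pa = tuple(x for x in pa(k) if x != j)
                    gain = cache.node_score(k, new_pa) - scores[k]
                    if gain > _EPS_GAIN and (best is None or gain > best[0]):
                        best = (gain, order, ("del", j, k))
                    # reversal j->k  =>  k->j
                    adj[j, k] = False
                    ok = not _has_path(adj, j, k)
                    adj[j, k] = True
                    if ok:
                        gain = (
                            cache.node_score(k, new_pa)
                            + cache.node_score(j, tuple(sorted(pa(j) + (k,))))
                            - scores[k] - scores[j]
                        )
                        if gain > _EPS_GAIN and (best is None or gain > best[0]):
                            best = (gain, order, ("rev", j, k))
                elif not adj[k, j]:
                    # addition
                    if _has_path(adj, k, j):
                        continue
                    gain = cache.node_score(k, tuple(sorted(pa(k) + (j,)))) - scores[k]
                    if gain > _EPS_GAIN and (best is None or gain > best[0]):
                        best = (gain, order, ("add", j, k))
        if best is None:
            break
        _, _, (kind, j, k) = best
        if kind == "add":
            adj[j, k] = True
        elif kind == "del":
            adj[j, k] = False
        else:
            adj[j, k] = False
            adj[k, j] = True
            scores[j] = cache.node_score(j, pa(j))
        scores[k] = cache.node_score(k, pa(k))
    return adj, float(sum(scores))


# ---------------------------------------------------------------------------
# structural EM
# ---------------------------------------------------------------------------

def _refit_model(
    nodes: list[str],
    adj: np.ndarray,
    cache: ScoreCache,
    thresholds: list[np.ndarray],
) -> LatentGaussianDAG:
    """Per-node least-squares refit, then standardize to unit marginals."""
    m = len(nodes)
    B = np.zeros((m, m))
    v = np.empty(m)
    for k in range(m):
        parents = tuple(np.flatnonzero(adj[:, k]))
        beta, sigma2 = cache.fit_node(k, parents)
        for c, j in enumerate(parents):
            B[j, k] = beta[1 + c]
        v[k] = sigma2
    model = LatentGaussianDAG(
        nodes=list(nodes),
        adjacency=adj.copy(),
        coefficients=B,
        means=np.zeros(m),
        cond_variances=v,
        thresholds=[a.copy() for a in thresholds],
    )
    return model.standardized()


def osem_fit(
    data: OrdinalDataset,
    K: int = 5,
    lam: float = 6.0,
    max_iter: int = 25,
    tol: float = 1e-4,
    seed: int = 0,
    sweeps: int = 5,
) -> LatentGaussianDAG:
    """Structural EM for the latent Gaussian DAG of an ordinal dataset.

    Parameters
    ----------
    data
        Ordinal table; every column must have >= 2 occupied levels.
    K
        Monte-Carlo completions per E-step.
    lam
        Penalty multiplier on the per-parameter BIC term log(n)/2.
    max_iter, tol
        The EM loop stops when the learned edge set is unchanged for two
        consecutive iterations and the penalized score moved by less than
        ``tol`` (the score is Monte-Carlo noisy, so structural stability is
        the primary criterion), or after ``max_iter`` iterations, in which
        case the best-scoring iterate is returned with ``converged=False``.
    seed
        Drives all E-step randomness.
    """
    rng = np.random.default_rng(seed)
    nodes = data.columns
    thresholds = [estimate_thresholds(data.counts(c)) for c in nodes]
    m = len(nodes)
    model = LatentGaussianDAG(
        nodes=nodes,
        adjacency=np.zeros((m, m), dtype=bool),
        coefficients=np.zeros((m, m)),
        means=np.zeros(m),
        cond_variances=np.ones(m),
        thresholds=thresholds,
    )
    prev_adj = model.adjacency.copy()
    prev_score = -np.inf
    stable = 0
    best = (-np.inf, model)
    for it in range(1, max_iter + 1):
        completions = sample_latent_completion(
            data, model, K=K, seed=rng, sweeps=sweeps
        )
        cache = ScoreCache(completions, lam)
        adj, score = structure_search(
            completions, lam, init_adjacency=model.adjacency, cache=cache
        )
        model = _refit_model(nodes, adj, cache, thresholds)
        model.n_iter = it
        model.score = score
        if score > best[0]:
            best = (score, model)
        if np.array_equal(adj, prev_adj) and abs(score - prev_score) < max(
            tol, 1e-3 * abs(score)
        ):
            stable += 1
            if stable >= 1:
                model.converged = True
                return model
        else:
            stable = 0
        prev_adj, prev_score = adj.copy(), score
    warnings.warn("structural EM did not stabilize; returning best iterate",
                  stacklevel=2)
    out = best[1]
    out.converged = False
    return out


# ---------------------------------------------------------------------------
# CPDAG
# ---------------------------------------------------------------------------

@dataclass
class CPDAG:
    """Partially directed representative of a Markov equivalence class."""

    nodes: list[str]
    directed: set[tuple[int, int]]
    undirected: set[frozenset[int]]

    def directed_edges(self) -> list[tuple[str, str]]:
        return sorted((self.nodes[j], self.nodes[k]) for j, k in self.directed)

    def undirected_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted((self.nodes[a], self.nodes[b])))
                      for a, b in map(sorted, self.undirected))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CPDAG)
            and self.nodes == other.nodes
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def adjacency_frame(self):
        """0/1 adjacency with undirected edges marked in both directions."""
        import pandas as pd

        m = len(self.nodes)
        a = np.zeros((m, m), dtype=int)
        for j, k in self.directed:
            a[j, k] = 1
        for e in self.undirected:
            j, k = tuple(e)
            a[j, k] = a[k, j] = 1
        return pd.DataFrame(a, index=self.nodes, columns=self.nodes)


def dag_to_cpdag(model_or_adj: LatentGaussianDAG | np.ndarray,
                 nodes: list[str] | None = None) -> CPDAG:
    """Markov-equivalence completion of a DAG.

    Keeps the skeleton, orients the v-structure edges, then closes under the
    Meek orientation rules; everything not compelled stays undirected.
    """
    if isinstance(model_or_adj, LatentGaussianDAG):
        adj = model_or_adj.adjacency
        nodes = model_or_adj.nodes
    else:
        adj = np.asarray(model_or_adj, dtype=bool)
        nodes = nodes or [f"X{i}" for i in range(adj.shape[0])]
    m = adj.shape[0]
    skel = adj | adj.T
    directed: set[tuple[int, int]] = set()
    for k in range(m):
        for j, l in combinations(np.flatnonzero(adj[:, k]), 2):
            if not skel[j, l]:  # unmarried parents -> compelled collider
                directed.add((j, k))
                directed.add((l, k))
    undirected = {
        frozenset((j, k))
        for j in range(m) for k in range(j + 1, m)
        if skel[j, k] and (j, k) not in directed and (k, j) not in directed
    }

    def orient(a: int, b: int) -> bool:
        e = frozenset((a, b))
        if e in undirected:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            b_, c_ = tuple(e)
            for b, c in ((b_, c_), (c_, b_)):
                # R1: a -> b, b - c, a and c nonadjacent  =>  b -> c
                if any((a, b) in directed and not skel[a, c]
                       for a in range(m) if a not in (b, c)):
                    changed |= orient(b, c)
                    break
                # R2: b -> a -> c with b - c  =>  b -> c  (else cycle)
                if any((b, a) in directed and (a, c) in directed
                       for a in range(m) if a not in (b, c)):
                    changed |= orient(b, c)
                    break
                # R3: b - a1, b - a2, a1 -> c, a2 -> c, a1,a2 nonadjacent
                colliders = [
                    a for a in range(m)
                    if a not in (b, c)
                    and frozenset((b, a)) in undirected
                    and (a, c) in directed
                ]
                if any(not skel[a1, a2]
                       for a1, a2 in combinations(colliders, 2)):
                    changed |= orient(b, c)
                    break
    return CPDAG(nodes=list(nodes), directed=directed, undirected=undirected)


@dataclass
class CPDAGSummary:
    """Point-estimate CPDAG plus bootstrap directed-edge frequencies."""

    cpdag: CPDAG
    edge_frequency: "object"  # pandas DataFrame (parent rows, child columns)
    n_success: int
    n_failed: int


def bootstrap_cpdag(
    data: OrdinalDataset,
    B: int = 500,
    K: int = 5,
    lam: float = 6.0,
    seed: int = 0,
    **osem_kwargs,
) -> CPDAGSummary:
    """Bootstrap edge-frequency matrix of the learned CPDAG.

    Rows are resampled with replacement B times; each resample is refit with
    :func:`osem_fit` and converted to a CPDAG.  A directed edge contributes 1
    to its cell, an undirected edge 0.5 to each direction.  Resamples whose
    fit fails are excluded and the denominator adjusted.
    """
    import pandas as pd

    if B < 1:
        raise ValueError("B >= 1 required")
    rng = np.random.default_rng(seed)
    nodes = data.columns
    m = len(nodes)
    point = osem_fit(data, K=K, lam=lam,
                     seed=int(rng.integers(2**31)), **osem_kwargs)
    counts = np.zeros((m, m))
    failed = 0
    for _ in range(B):
        fit_seed = int(rng.integers(2**31))
        try:
            boot = data.resample(rng)
            fit = osem_fit(boot, K=K, lam=lam, seed=fit_seed, **osem_kwargs)
            cp = dag_to_cpdag(fit)
        except Exception as exc:  # noqa: BLE001 - resample-level robustness
            warnings.warn(f"bootstrap resample failed: {exc}", stacklevel=2)
            failed += 1
            continue
        # column order can differ only if levels collapsed; map by name
        name_ix = [nodes.index(v) for v in fit.nodes]
        for j, k in cp.directed:
            counts[name_ix[j], name_ix[k]] += 1.0
        for e in cp.undirected:
            j, k = tuple(e)
            counts[name_ix[j], name_ix[k]] += 0.5
            counts[name_ix[k], name_ix[j]] += 0.5
    denom = max(B - failed, 1)
    freq = pd.DataFrame(counts / denom, index=nodes, columns=nodes)
    return CPDAGSummary(
        cpdag=dag_to_cpdag(point),
        edge_frequency=freq,
        n_success=B - failed,
        n_failed=failed,
    )
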