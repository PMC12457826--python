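"""Latent Gaussian DAG learning: thresholds, Gibbs E-step, scores, search, CPDAG."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from ordcause import (
    LatentGaussianDAG,
    OrdinalDataset,
    bootstrap_cpdag,
    chain_model,
    dag_to_cpdag,
    estimate_thresholds,
    osem_fit,
    sample_latent_completion,
    simulate_ordinal,
    structure_search,
)
from ordcause.latent_dag import ScoreCache
from ordcause.synthetic import equal_level_thresholds, random_dag, random_model


def _single_node_model(thresholds):
    return LatentGaussianDAG(
        nodes=["X"],
        adjacency=np.zeros((1, 1), dtype=bool),
        coefficients=np.zeros((1, 1)),
        means=np.zeros(1),
        cond_variances=np.ones(1),
        thresholds=[np.asarray(thresholds, dtype=float)],
    )


class TestThresholdEstimation:
    def test_balanced_binary_gives_zero_cut(self):
        a = estimate_thresholds(np.array([50, 50]))
        np.testing.assert_allclose(a, [-np.inf, 0.0, np.inf])

    def test_half_quarter_quarter_matches_probit_quantiles(self):
        a = estimate_thresholds(np.array([500, 250, 250]))
        assert a[1] == pytest.approx(0.0, abs=1e-12)
        assert a[2] == pytest.approx(ndtri(0.75))

    def test_single_occupied_level_rejected(self):
        with pytest.raises(ValueError, match="2 occupied"):
            estimate_thresholds(np.array([100, 0]))

    def test_consistency_on_simulated_no_edge_data(self):
        model = random_model(3, edge_probability=0.0, levels=4, seed=5)
        data = simulate_ordinal(model, 5000, seed=6)
        for k, col in enumerate(data.columns):
            est = estimate_thresholds(data.counts(col))
            np.testing.assert_allclose(
                est[1:-1], model.thresholds[k][1:-1], atol=0.1)


class TestLatentCompletion:
    def test_every_completion_respects_observed_bins(self, chain3):
        data = simulate_ordinal(chain3, 300, seed=0)
        comps = sample_latent_completion(data, chain3, K=5, seed=1)
        assert len(comps) == 5
        X = data.as_matrix()
        for Y in comps:
            for k in range(chain3.m):
                a = chain3.thresholds[k]
                assert np.all(Y[:, k] >= a[X[:, k]])
                assert np.all(Y[:, k] < a[X[:, k] + 1])

    def test_seeded_determinism(self, chain3):
        data = simulate_ordinal(chain3, 100, seed=2)
        a = sample_latent_completion(data, chain3, K=3, seed=7)
        b = sample_latent_completion(data, chain3, K=3, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_half_normal_mean_for_positive_bin(self):
        model = _single_node_model([-np.inf, 0.0, np.inf])
        frame = pd.DataFrame({"X": np.concatenate([np.zeros(1, int),
                                                   np.ones(4000, int)])})
        data = OrdinalDataset.from_frame(frame)
        comps = sample_latent_completion(data, model, K=5, seed=3)
        pos = np.concatenate([Y[1:, 0] for Y in comps])
        assert np.all(pos >= 0)
        # E[Y | Y > 0] for a standard normal
        assert pos.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.03)


class TestScore:
    def test_empty_parent_score_matches_closed_form(self, rng):
        y = rng.standard_normal(400)
        cache = ScoreCache([y[:, None]], lam=6.0)
        sigma2 = y.var()
        expected = (-0.5 * 400 * (np.log(2 * np.pi * sigma2) + 1)
                    - 6.0 * 2 * np.log(400) / 2)
        assert cache.node_score(0, ()) == pytest.approx(expected, rel=1e-9)

    def test_decomposability_under_edge_addition(self, rng):
        Y = rng.standard_normal((300, 3))
        cache = ScoreCache([Y], lam=6.0)
        before = [cache.node_score(k, ()) for k in range(3)]
        after_other = [cache.node_score(k, ()) for k in (0, 1)]
        cache.node_score(2, (0,))  # add 0 -> 2
        assert after_other == before[:2]

    def test_null_parent_usually_penalized(self, rng):
        # independent columns: adding the spurious parent should lose score
        losses = 0
        for rep in range(20):
            Y = np.random.default_rng(rep).standard_normal((500, 2))
            cache = ScoreCache([Y], lam=6.0)
            if cache.node_score(1, (0,)) < cache.node_score(1, ()):
                losses += 1
        assert losses >= 19


class TestStructureSearch:
    def test_strong_dependence_yields_single_edge(self, rng):
        y1 = rng.standard_normal(1000)
        y2 = 0.8 * y1 + 0.6 * rng.standard_normal(1000)
        adj, _ = structure_search([np.column_stack([y1, y2])], lam=6.0)
        assert adj.sum() == 1

    def test_independent_columns_yield_empty_graph(self, rng):
        Y = rng.standard_normal((1000, 4))
        adj, _ = structure_search([Y], lam=6.0)
        assert adj.sum() == 0

    def test_output_always_acyclic(self, rng):
        for rep in range(5):
            model = random_model(5, 0.5, seed=rep)
            Y = np.linalg.cholesky(model.implied_covariance()) @ \
                np.random.default_rng(rep).standard_normal((5, 800))
            adj, _ = structure_search([Y.T], lam=2.0)
            g = nx.DiGraph(zip(*np.nonzero(adj)))
            assert nx.is_directed_acyclic_graph(g)

    def test_total_score_is_sum_of_node_scores(self, rng):
        Y = rng.standard_normal((500, 3))
        Y[:, 2] += 0.9 * Y[:, 0]
        cache = ScoreCache([Y], lam=3.0)
        adj, total = structure_search([Y], lam=3.0, cache=cache)
        assert total == pytest.approx(cache.total_score(adj))


class TestOsemFit:
    def test_same_seed_identical_output(self, chain3):
        data = simulate_ordinal(chain3, 500, seed=4)
        a = osem_fit(data, seed=9)
        b = osem_fit(data, seed=9)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_allclose(a.coefficients, b.coefficients)

    def test_chain_cpdag_recovered_on_moderate_sample(self, chain3):
        hits = 0
        for s in range(5):
            data = simulate_ordinal(chain3, 2000, seed=200 + s)
            cp = dag_to_cpdag(osem_fit(data, seed=s))
            hits += cp == dag_to_cpdag(chain3)
        assert hits >= 4

    def test_implied_covariance_unit_diagonal_and_positive_definite(self, chain3):
        data = simulate_ordinal(chain3, 800, seed=11)
        fit = osem_fit(data, seed=12)
        sigma = fit.implied_covariance()
        np.testing.assert_allclose(np.diag(sigma), 1.0, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)

    def test_recovery_improves_with_sample_size(self):
        """Median structural Hamming distance shrinks as n grows."""
        model = random_model(4, 0.5, seed=21)
        true_cp = dag_to_cpdag(model)

        def shd(cp):
            a = cp.adjacency_frame().to_numpy()
            b = true_cp.adjacency_frame().to_numpy()
            return int((a != b).sum())

        med = []
        for n in (250, 1000, 4000):
            dists = []
            for s in range(3):
                data = simulate_ordinal(model, n, seed=1000 * n + s)
                dists.append(shd(dag_to_cpdag(osem_fit(data, seed=s))))
            med.append(np.median(dists))
        assert med[-1] <= med[0]


class TestCPDAG:
    def test_collider_edges_stay_directed(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 2] = adj[1, 2] = True
        cp = dag_to_cpdag(adj)
        assert cp.directed == {(0, 2), (1, 2)}
        assert not cp.undirected

    def test_chain_fully_undirected(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 2] = True
        cp = dag_to_cpdag(adj)
        assert not cp.directed
        assert cp.undirected == {frozenset((0, 1)), frozenset((1, 2))}

    def test_single_edge_undirected(self):
        adj = np.zeros((2, 2), dtype=bool)
        adj[0, 1] = True
        cp = dag_to_cpdag(adj)
        assert cp.undirected == {frozenset((0, 1))}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_equivalence_class_enumeration(self, seed):
        """Oracle: a skeleton edge is compelled iff every acyclic orientation
        of the skeleton with the same v-structures orients it the same way."""
        adj = random_dag(4, 0.5, seed=seed)
        m = adj.shape[0]

        def vstructs(a):
            out = set()
            skel = a | a.T
            for k in range(m):
                for j, l in combinations(np.flatnonzero(a[:, k]), 2):
                    if not skel[j, l]:
                        out.add((min(j, l), max(j, l), k))
            return out

        edges = [(j, k) for j in range(m) for k in range(j + 1, m)
                 if adj[j, k] or adj[k, j]]
        target_v = vstructs(adj)
        members = []
        for flips in product([False, True], repeat=len(edges)):
            cand = np.zeros_like(adj)
            for (j, k), flip in zip(edges, flips):
                if flip:
                    cand[k, j] = True
                else:
                    cand[j, k] = True
            g = nx.DiGraph(zip(*np.nonzero(cand))) if cand.any() else nx.DiGraph()
            if cand.any() and not nx.is_directed_acyclic_graph(g):
                continue
            if vstructs(cand) == target_v:
                members.append(cand)
        compelled = set()
        undirected = set()
        for j, k in edges:
            dirs = {(j, k) if mem[j, k] else (k, j) for mem in members}
            if len(dirs) == 1:
                compelled.add(next(iter(dirs)))
            else:
                undirected.add(frozenset((j, k)))
        cp = dag_to_cpdag(adj)
        assert cp.directed == compelled
        assert cp.undirected == undirected


class TestBootstrap:
    def test_frequencies_are_proper(self, collider3):
        data = simulate_ordinal(collider3, 400, seed=14)
        summary = bootstrap_cpdag(data, B=8, seed=15)
        f = summary.edge_frequency.to_numpy()
        assert np.all(f >= 0) and np.all(f <= 1)
        assert np.all(f + f.T <= 1 + 1e-12)
        assert summary.n_success + summary.n_failed == 8

    def test_strong_collider_edge_has_majority_frequency(self, collider3):
        data = simulate_ordinal(collider3, 2000, seed=16)
        summary = bootstrap_cpdag(data, B=20, seed=17)
        assert summary.edge_frequency.loc["A", "C"] > 0.5
        assert summary.edge_frequency.loc["B", "C"] > 0.5


class TestModelContainer:
    def test_cycle_rejected(self):
        adj = np.zeros((2, 2), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.raises(ValueError, match="cycle"):
            LatentGaussianDAG(
                nodes=["A", "B"], adjacency=adj, coefficients=adj * 0.5,
                means=np.zeros(2), cond_variances=np.ones(2),
                thresholds=[equal_level_thresholds(2)] * 2)

    def test_standardized_preserves_correlation(self):
        model = chain_model(m=2, b=0.8)
        sigma = model.implied_covariance()
        np.testing.assert_allclose(np.diag(sigma), 1.0)
        assert sigma[0, 1] == pytest.approx(0.8)
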