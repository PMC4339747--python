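"""CBN: down-set lattice, phase-type probabilities, likelihood, annealing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oncorestrict.cbn import (
    CBNEstimator,
    Poset,
    downset_lattice,
    fit_lambdas,
    genotype_probabilities,
    loglik,
    sample_genotypes,
)
from oncorestrict.graphs import ROOT
from oncorestrict.metrics import scores


def _brute_force_downsets(poset: Poset) -> set[frozenset]:
    rel = poset.relations()
    out = set()
    for r in range(len(poset.genes) + 1):
        for combo in itertools.combinations(poset.genes, r):
            s = set(combo)
            if all(u in s for (u, v) in rel if v in s):
                out.add(frozenset(s))
    return out


class TestLattice:
    def test_empty_poset_all_subsets(self):
        states, _ = downset_lattice(Poset.empty(("A", "B")))
        assert len(states) == 4

    def test_chain_prefixes_only(self):
        p = Poset.from_edges(("A", "B"), [("A", "B")])
        states, trans = downset_lattice(p)
        assert set(states.tolist()) == {0, 1, 3}  # {}, {A}, {A,B}
        assert len(trans) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            genes = tuple(f"g{i}" for i in range(int(rng.integers(2, 6))))
            edges = [
                (genes[i], genes[j])
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
                if rng.random() < 0.4
            ]
            p = Poset.from_edges(genes, edges)
            states, _ = downset_lattice(p)
            got = {
                frozenset(g for k, g in enumerate(genes) if s >> k & 1)
                for s in states.tolist()
            }
            assert got == _brute_force_downsets(p)

    def test_too_many_genes_refused(self):
        with pytest.raises(ValueError, match="limited"):
            downset_lattice(Poset.empty(tuple(f"g{i}" for i in range(15))))


class TestGenotypeProbabilities:
    def test_single_event_closed_form(self):
        # P(mutated) = lambda / (1 + lambda); lambda = 1 gives 1/2
        p = Poset.empty(("A",))
        for lam in (1.0, 3.0, 0.25):
            states, probs = genotype_probabilities(p, [lam])
            assert probs[list(states).index(1)] == pytest.approx(
                lam / (1 + lam)
            )

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            genes = tuple(f"g{i}" for i in range(4))
            edges = [("g0", "g2"), ("g1", "g2")] if rng.random() < 0.5 else []
            p = Poset.from_edges(genes, edges)
            _, probs = genotype_probabilities(p, rng.uniform(0.2, 3, 4))
            assert probs.sum() == pytest.approx(1.0)
            assert (probs >= 0).all()

    def test_incompatible_state_excluded(self):
        p = Poset.from_edges(("A", "B"), [("A", "B")])
        states, _ = genotype_probabilities(p, [1.0, 1.0])
        assert 2 not in states.tolist()  # {B} alone is not a down-set

    def test_matches_monte_carlo_clock_simulation(self):
        # independent oracle: forward simulation of the exponential clocks
        rng = np.random.default_rng(42)
        p = Poset.from_edges(
            ("A", "B", "C", "D"), [("A", "C"), ("B", "C"), ("C", "D")]
        )
        lam = np.array([1.5, 0.8, 2.0, 0.5])
        states, probs = genotype_probabilities(p, lam)
        n_draws = 100_000
        sim = sample_genotypes(p, lam, n_draws, rng)
        masks = sim.to_numpy() @ (1 << np.arange(4))
        for s, prob in zip(states.tolist(), probs):
            emp = (masks == s).mean()
            se = math.sqrt(max(emp * (1 - emp), 1e-9) / n_draws)
            assert abs(emp - prob) < 3 * se + 1e-4


class TestLogLikelihood:
    def test_zero_epsilon_equals_state_logprobs(self):
        p = Poset.from_edges(("A", "B"), [("A", "B")])
        lam = [1.2, 0.9]
        X = pd.DataFrame([[0, 0], [1, 0], [1, 1]], columns=["A", "B"])
        states, probs = genotype_probabilities(p, lam)
        lookup = dict(zip(states.tolist(), probs))
        expected = math.log(lookup[0]) + math.log(lookup[1]) + math.log(lookup[3])
        assert loglik(X, p, lam, epsilon=0.0) == pytest.approx(expected)

    def test_zero_epsilon_incompatible_row_is_minus_inf(self):
        p = Poset.from_edges(("A", "B"), [("A", "B")])
        X = pd.DataFrame([[0, 1]], columns=["A", "B"])
        assert loglik(X, p, [1.0, 1.0], epsilon=0.0) == -math.inf

    def test_positive_epsilon_tolerates_incompatible_rows(self):
        p = Poset.from_edges(("A", "B"), [("A", "B")])
        X = pd.DataFrame([[0, 1]], columns=["A", "B"])
        assert np.isfinite(loglik(X, p, [1.0, 1.0], epsilon=0.05))

    def test_single_gene_mle_closed_form(self):
        # with eps=0 the score equation gives lambda-hat = f / (1 - f)
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"A": (rng.random(1000) < 0.3).astype(int)})
        f = X["A"].mean()
        lam, _ = fit_lambdas(X, Poset.empty(("A",)), epsilon=0.0, n_restarts=2)
        assert lam[0] == pytest.approx(f / (1 - f), rel=1e-3)


class TestStructureSearch:
    def test_single_gene_poset(self):
        X = pd.DataFrame({"A": [1, 0, 1, 0]})
        est = CBNEstimator(random_state=0).fit(X)
        assert est.poset_.cover == frozenset()
        assert est.model_.edges == ((ROOT, "A"),)

    def test_chain_data_scores_at_least_empty_poset(self):
        genes = ("A", "B", "C")
        chain = Poset.from_edges(genes, [("A", "B"), ("B", "C")])
        X = sample_genotypes(chain, [2.0, 1.5, 1.0], 400,
                             np.random.default_rng(1))
        lam_c, ll_chain = fit_lambdas(X, chain, epsilon=0.05)
        _, ll_empty = fit_lambdas(X, Poset.empty(genes), epsilon=0.05)
        assert ll_chain >= ll_empty

    def test_same_seed_same_poset(self):
        p = Poset.from_edges(("A", "B", "C"), [("A", "B")])
        X = sample_genotypes(p, [2.0, 1.0, 0.7], 150,
                             np.random.default_rng(2), epsilon=0.05)
        m1 = CBNEstimator(random_state=3).fit(X).poset_
        m2 = CBNEstimator(random_state=3).fit(X).poset_
        assert m1.cover == m2.cover

    def test_rate_recovery_on_simulated_data(self):
        # observable (non-deep) events recover their rates well; the median
        # relative error over all genes stays moderate
        true = Poset.from_edges(
            ("A", "B", "C", "D", "E"), [("A", "C"), ("B", "C"), ("C", "D")]
        )
        true_lam = np.array([2.0, 1.2, 1.5, 0.6, 0.9])
        X = sample_genotypes(true, true_lam, 1000, np.random.default_rng(7),
                             epsilon=0.05)
        lam, _ = fit_lambdas(X, true, epsilon=0.05, n_restarts=3)
        rel = np.abs(lam - true_lam) / true_lam
        assert np.median(rel) < 0.25

    def test_pnd_decreases_with_sample_size(self):
        true = Poset.from_edges(
            ("A", "B", "C", "D", "E"), [("A", "C"), ("B", "C"), ("C", "D")]
        )
        true_lam = np.array([2.0, 1.2, 1.5, 0.6, 0.9])
        means = {}
        for n in (100, 500):
            pnds = []
            for seed in range(6):
                X = sample_genotypes(true, true_lam, n,
                                     np.random.default_rng(seed), epsilon=0.05)
                est = CBNEstimator(random_state=seed).fit(X)
                pnds.append(scores(true.to_restriction_graph(), est.model_).pnd)
            means[n] = np.mean(pnds)
        assert means[500] <= means[100]

    def test_poset_validation(self):
        with pytest.raises(ValueError, match="cycle"):
            Poset(("A", "B"), frozenset({("A", "B"), ("B", "A")}))
        with pytest.raises(ValueError, match="reduced"):
            Poset(("A", "B", "C"),
                  frozenset({("A", "B"), ("B", "C"), ("A", "C")}))
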