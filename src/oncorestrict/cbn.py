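"""Conjunctive Bayesian network (CBN) inference.

A CBN places a partial order (poset) on the genes: a gene can mutate only
once all its parents in the poset have mutated.  Once enabled, gene g
waits an Exp(lambda_g) time.  A patient is observed at an Exp(nu = 1)
sampling time, so the probability of observing true genotype x is the
phase-type quantity

    P(x) = nu * [ (nu I - Q)^(-1) ]_{empty, x}

where Q is the generator of the continuous-time Markov chain on the
lattice of down-sets (order ideals) of the poset, with rate lambda_g on
each transition x -> x + {g} for every g addable to x.  Observations carry
an independent per-gene flip error epsilon, so an observed row y has
probability sum_x P(x) eps^H(x,y) (1-eps)^(n-H(x,y)).

Structure search is simulated annealing over posets at temperature 1 with
number-of-nodes^2 steps, started from a linear poset ordered by decreasing
marginal frequency, with single cover-relation addition/removal moves;
rates are re-optimized (L-BFGS-B on log lambda) at every step.  This is a
faithful implementation of the published CBN model class, not a
bit-compatible port of any particular binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator

from .filtering import _as_frame
from .graphs import ROOT, RestrictionGraph

MAX_GENES = 14  # lattice and likelihood refuse beyond this

_POPCOUNT = np.array(
    [bin(i).count("1") for i in range(1 << MAX_GENES)], dtype=np.int8
)


@dataclass(frozen=True)
class Poset:
    """Partial order over genes, stored as its cover (reduced) relation."""

    genes: tuple[str, ...]
    cover: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        g = self._nx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("poset cover relation contains a cycle")
        if set(nx.transitive_reduction(g).edges) != set(self.cover):
            raise ValueError("cover relation is not transitively reduced")

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.cover)
        return g

    @property
    def n(self) -> int:
        return len(self.genes)

    def relations(self) -> frozenset[tuple[str, str]]:
        g = self._nx()
        return frozenset(
            (u, v) for u in self.genes for v in nx.descendants(g, u)
        )

    def parents_mask(self) -> list[int]:
        """Per-gene bitmask of cover parents (gene order = self.genes)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        masks = [0] * len(self.genes)
        for u, v in self.cover:
            masks[idx[v]] |= 1 << idx[u]
        return masks

    def to_restriction_graph(self, name: str = "CBN") -> RestrictionGraph:
        """Rooted form: minimal elements attach under Root."""
        return RestrictionGraph(self.cover, nodes=self.genes, name=name)

    @classmethod
    def linear(cls, genes: Sequence[str]) -> "Poset":
        cover = frozenset(zip(genes[:-1], genes[1:]))
        return cls(tuple(genes), cover)

    @classmethod
    def empty(cls, genes: Sequence[str]) -> "Poset":
        return cls(tuple(genes), frozenset())

    @classmethod
    def from_edges(
        cls, genes: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "Poset":
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        g.add_edges_from(edges)
        red = nx.transitive_reduction(g)
        return cls(tuple(genes), frozenset(red.edges))


def downset_lattice(poset: Poset):
    """All down-sets of the poset plus their addable-gene transitions.

    Returns (states, transitions): states is an int array of genotype
    bitmasks (state 0 is the empty set), transitions an int array of rows
    (from_state_index, to_state_index, gene_index).
    """
    if poset.n > MAX_GENES:
        raise ValueError(f"lattice limited to {MAX_GENES} genes")
    pmasks = poset.parents_mask()
    n = poset.n
    index = {0: 0}
    states = [0]
    transitions = []
    frontier = [0]
    while frontier:
        nxt = []
        for x in frontier:
            for g in range(n):
                bit = 1 << g
                if x & bit or (x & pmasks[g]) != pmasks[g]:
                    continue
                y = x | bit
                if y not in index:
                    index[y] = len(states)
                    states.append(y)
                    nxt.append(y)
                transitions.append((index[x], index[y], g))
        frontier = nxt
    order = np.argsort(states)  # canonical order for reproducibility
    states_arr = np.array(states)[order]
    remap = np.empty(len(states), dtype=int)
    remap[order] = np.arange(len(states))
    trans_arr = np.array(
        [(remap[a], remap[b], g) for a, b, g in transitions], dtype=int
    ).reshape(-1, 3)
    return states_arr, trans_arr


def genotype_probabilities(
    poset: Poset,
    lambdas: Sequence[float],
    nu: float = 1.0,
    lattice=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(states, probabilities) of the true genotype at an Exp(nu) time."""
    lam = np.asarray(lambdas, dtype=float)
    if (lam <= 0).any():
        raise ValueError("lambdas must be positive")
    states, trans = lattice if lattice is not None else downset_lattice(poset)
    m = len(states)
    probs = _solve_pi(states, trans, lam, nu, m)
    return states, probs


def _solve_pi(states, trans, lam, nu, m):
    # A = nu I - Q; solve pi = nu * e0^T A^{-1}  i.e.  A^T pi = nu e0
    rows = []
    cols = []
    vals = []
    diag = np.full(m, nu)
    if len(trans):
        src, dst, gene = trans[:, 0], trans[:, 1], trans[:, 2]
        rates = lam[gene]
        np.add.at(diag, src, rates)
        rows.extend(src)
        cols.extend(dst)
        vals.extend(-rates)
    if m <= 1024:
        A = np.zeros((m, m))
        A[np.arange(m), np.arange(m)] = diag
        if len(trans):
            np.add.at(A, (np.asarray(rows), np.asarray(cols)), np.asarray(vals))
        e0 = np.zeros(m)
        e0[0] = nu
        pi = np.linalg.solve(A.T, e0)
    else:
        rows = np.concatenate([np.asarray(rows, int), np.arange(m)])
        cols = np.concatenate([np.asarray(cols, int), np.arange(m)])
        vals = np.concatenate([np.asarray(vals, float), diag])
        A = sparse.csc_matrix((vals, (rows, cols)), shape=(m, m))
        e0 = np.zeros(m)
        e0[0] = nu
        pi = spsolve(A.T.tocsc(), e0)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    assert total > 0
    return pi / total


def _rows_as_masks(X: pd.DataFrame, genes: Sequence[str]):
    sub = X[list(genes)].to_numpy(dtype=np.int64)
    weights = 1 << np.arange(len(genes), dtype=np.int64)
    masks = sub @ weights
    uniq, counts = np.unique(masks, return_counts=True)
    return uniq, counts


def loglik(
    data,
    poset: Poset,
    lambdas: Sequence[float],
    epsilon: float = 0.05,
    nu: float = 1.0,
    lattice=None,
    _rows=None,
) -> float:
    """Log-likelihood of observed rows under the CBN + flip-error model."""
    X = _as_frame(data)
    n = poset.n
    states, trans = lattice if lattice is not None else downset_lattice(poset)
    uniq, counts = _rows if _rows is not None else _rows_as_masks(X, poset.genes)
    pi = _solve_pi(states, trans, np.asarray(lambdas, float), nu, len(states))
    if epsilon == 0.0:
        state_index = {int(s): i for i, s in enumerate(states)}
        total = 0.0
        for mask, cnt in zip(uniq, counts):
            i = state_index.get(int(mask))
            if i is None or pi[i] <= 0:
                return -math.inf
            total += cnt * math.log(pi[i])
        return total
    ham = _POPCOUNT[np.bitwise_xor.outer(states, uniq)]
    r = epsilon / (1.0 - epsilon)
    mix = pi @ (r ** ham.astype(float))
    logp = np.log(mix) + n * math.log1p(-epsilon)
    return float(counts @ logp)


def fit_lambdas(
    data,
    poset: Poset,
    epsilon: float = 0.05,
    n_restarts: int = 3,
    x0: np.ndarray | None = None,
    maxiter: int = 60,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Maximize the log-likelihood over per-gene rates (bounded
    quasi-Newton on log lambda, multi-start).  Returns (lambdas, loglik)."""
    X = _as_frame(data)
    lattice = downset_lattice(poset)
    rows = _rows_as_masks(X, poset.genes)
    n = poset.n

    def neg(loglam):
        return -loglik(
            X, poset, np.exp(loglam), epsilon, lattice=lattice, _rows=rows
        )

    rng = np.random.default_rng(seed)
    freqs = X[list(poset.genes)].mean(axis=0).to_numpy()
    # moment-style initializer: marginal odds of each event
    base = np.log(np.clip(freqs / np.clip(1 - freqs, 1e-3, None), 1e-3, 1e3))
    starts = [base if x0 is None else np.log(np.asarray(x0))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(base + rng.normal(0, 1.0, size=n))
    best = None
    for s in starts:
        res = optimize.minimize(
            neg,
            s,
            method="L-BFGS-B",
            bounds=[(-7.0, 7.0)] * n,
            options={"maxiter": maxiter, "ftol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -float(best.fun)


# ---------------------------------------------------------------------------
# Structure search
# ---------------------------------------------------------------------------


def _neighbor_moves(poset: Poset) -> list[Poset]:
    """Posets one cover-relation addition or removal away."""
    out = []
    # canonical move order (sorted) so the annealing chain is reproducible
    # across processes regardless of hash randomization
    for e in sorted(poset.cover):
        out.append(Poset.from_edges(poset.genes, poset.cover - {e}))
    closure = poset.relations()
    for u in poset.genes:
        for v in poset.genes:
            if u == v or (u, v) in closure or (v, u) in closure:
                continue
            out.append(
                Poset.from_edges(poset.genes, set(poset.cover) | {(u, v)})
            )
    return out


class CBNEstimator(BaseEstimator):
    """Fit a conjunctive Bayesian network by simulated annealing.

    Parameters
    ----------
    epsilon : float
        Per-gene observation flip probability (fixed during search).
    temperature : float
        Metropolis temperature (default 1, the standard setting).
    steps : int or None
        Annealing steps; None means number-of-genes squared (default).
    random_state : int
        Seed for the annealing chain and rate-fit restarts.
    search_maxiter, final_restarts : int
        Budget of the per-step rate refits and of the final polish.

    Attributes
    ----------
    poset_ : Poset
    model_ : RestrictionGraph (poset rooted at Root)
    lambdas_ : ndarray, fitted per-gene rates of the best poset
    loglik_ : float
    relations_ : frozenset of ordered gene pairs
    """

    def __init__(
        self,
        epsilon: float = 0.05,
        temperature: float = 1.0,
        steps: int | None = None,
        random_state: int = 0,
        search_maxiter: int = 12,
        final_restarts: int = 3,
    ):
        self.epsilon = epsilon
        self.temperature = temperature
        self.steps = steps
        self.random_state = random_state
        self.search_maxiter = search_maxiter
        self.final_restarts = final_restarts

    def fit(self, X, y=None):
        X = _as_frame(X)
        genes = list(X.columns)
        if not 1 <= len(genes) <= MAX_GENES:
            raise ValueError(f"CBN handles 1..{MAX_GENES} genes")
        rng = np.random.default_rng(self.random_state)
        freqs = X.mean(axis=0)
        order = sorted(genes, key=lambda g: (-freqs[g], g))
        current = Poset.linear(order)
        lam, ll = fit_lambdas(
            X,
            current,
            self.epsilon,
            n_restarts=1,
            maxiter=self.search_maxiter,
            seed=self.random_state,
        )
        lam_by_gene = dict(zip(current.genes, lam))
        best, best_ll = current, ll
        cache: dict[frozenset, tuple[float, dict]] = {
            current.cover: (ll, lam_by_gene)
        }
        n_steps = self.steps if self.steps is not None else len(genes) ** 2
        for _ in range(n_steps):
            moves = _neighbor_moves(current)
            if not moves:
                break
            cand = moves[int(rng.integers(len(moves)))]
            if cand.cover in cache:
                cand_ll, cand_lam = cache[cand.cover]
            else:
                x0 = np.array(
                    [lam_by_gene.get(g, 1.0) for g in cand.genes]
                )
                lam_c, cand_ll = fit_lambdas(
                    X,
                    cand,
                    self.epsilon,
                    n_restarts=1,
                    x0=x0,
                    maxiter=self.search_maxiter,
                    seed=self.random_state,
                )
                cand_lam = dict(zip(cand.genes, lam_c))
                cache[cand.cover] = (cand_ll, cand_lam)
            delta = cand_ll - ll
            if delta >= 0 or rng.random() < math.exp(
                delta / self.temperature
            ):
                current, ll, lam_by_gene = cand, cand_ll, cand_lam
                if ll > best_ll:
                    best, best_ll = current, ll
        lam, ll = fit_lambdas(
            X,
            best,
            self.epsilon,
            n_restarts=self.final_restarts,
            x0=np.array([cache[best.cover][1][g] for g in best.genes]),
            seed=self.random_state,
        )
        self.poset_ = best
        self.lambdas_ = lam
        self.loglik_ = ll
        self.epsilon_ = self.epsilon
        self.model_ = best.to_restriction_graph()
        self.relations_ = self.model_.relations()
        self.n_features_in_ = len(genes)
        return self


def fit_cbn(data, seed: int = 0, **kwargs) -> RestrictionGraph:
    """Thin wrapper: fit a CBN and return the rooted inferred poset."""
    return CBNEstimator(random_state=seed, **kwargs).fit(data).model_


def sample_genotypes(
    poset: Poset,
    lambdas: Sequence[float],
    n_subjects: int,
    rng: np.random.Generator,
    epsilon: float = 0.0,
    nu: float = 1.0,
) -> pd.DataFrame:
    """Draw observed genotypes from the CBN generative model.

    Runs the exponential-clock process forward (an independent route from
    the lattice linear algebra, usable as a Monte-Carlo oracle), stops at
    an Exp(nu) sampling time, then applies per-gene flips.
    """
    lam = np.asarray(lambdas, float)
    pmasks = poset.parents_mask()
    n = poset.n
    out = np.zeros((n_subjects, n), dtype=np.int8)
    for row in range(n_subjects):
        t_obs = rng.exponential(1.0 / nu)
        t = 0.0
        x = 0
        while True:
            addable = [
                g
                for g in range(n)
                if not x & (1 << g) and (x & pmasks[g]) == pmasks[g]
            ]
            if not addable:
                break
            rates = lam[addable]
            total = rates.sum()
            t_next = t + rng.exponential(1.0 / total)
            if t_next > t_obs:
                break
            t = t_next
            g = addable[
                int(rng.choice(len(addable), p=rates / total))
            ]
            x |= 1 << g
        bits = np.array([(x >> g) & 1 for g in range(n)], dtype=np.int8)
        if epsilon > 0:
            flips = rng.random(n) < epsilon
            bits = np.where(flips, 1 - bits, bits)
        out[row] = bits
    return pd.DataFrame(out, columns=list(poset.genes))
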