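"""Oncogenetic tree (OT) inference by maximum-weight branching.

The classical OT estimator builds a complete directed graph over Root plus
the observed genes, weights each candidate edge i -> j by a score that
rewards co-occurrence and the correct marginal ordering,

    w(i -> j) = log(p_ij / (p_i + p_j)) + log(p_ij / (p_i * p_j)),

with p_Root = 1 and p_Root,j = p_j, and returns the maximum-weight
spanning arborescence rooted at Root (Chu-Liu/Edmonds).  Pairs that never
co-occur get weight minus infinity and are excluded.  Genes observed at
frequency one make every ratio degenerate; they are set aside and
re-attached as childless direct children of Root, which mirrors the
behavior of the standard implementation and is the degeneracy the
zero-row-augmented "-A" variants are designed to remove.

Being trees, OTs cannot represent conjunctions: every inferred node has a
single parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .filtering import _as_frame
from .graphs import ROOT, RestrictionGraph, relations as graph_relations
from .sampling import Dataset


@dataclass
class FrequencyTable:
    """Marginal (p_i) and pairwise joint (p_ij) mutation frequencies."""

    genes: list[str]
    p: pd.Series
    p_joint: pd.DataFrame

    def __post_init__(self) -> None:
        pv = self.p.to_numpy()
        jv = self.p_joint.to_numpy()
        if ((jv - np.minimum.outer(pv, pv)) > 1e-12).any():
            raise ValueError("joint frequency exceeds a marginal frequency")


def estimate_frequencies(data) -> FrequencyTable:
    X = _as_frame(data)
    vals = X.to_numpy(dtype=float)
    n = len(X)
    p = X.mean(axis=0)
    joint = pd.DataFrame(
        vals.T @ vals / n, index=X.columns, columns=X.columns
    )
    return FrequencyTable(list(X.columns), p, joint)


def _edge_weight(p_i: float, p_j: float, p_ij: float) -> float:
    if p_ij <= 0:
        return -math.inf
    return math.log(p_ij / (p_i + p_j)) + math.log(p_ij / (p_i * p_j))


class OncotreeEstimator(BaseEstimator):
    """Fit an oncogenetic tree to a binary subjects-by-genes matrix.

    Attributes
    ----------
    tree_ : RestrictionGraph
        The inferred rooted tree (cover edges only).
    relations_ : frozenset of (str, str)
        Transitive closure of the tree's cover relations, Root excluded.
    dropped_genes_ : list of str
        Genes at observed frequency zero, excluded from the tree.
    saturated_genes_ : list of str
        Genes at observed frequency one, attached childless under Root.
    edge_probabilities_ : dict
        Conditional child-given-parent frequencies p_ij / p_i per tree
        edge (stored for reference; topology is the deliverable).
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        freqs = estimate_frequencies(X)
        p = freqs.p
        active = [g for g in X.columns if 0 < p[g] < 1]
        self.dropped_genes_ = [g for g in X.columns if p[g] == 0]
        self.saturated_genes_ = [g for g in X.columns if p[g] == 1]
        edges = self._branching(freqs, active)
        for g in self.saturated_genes_:
            edges.append((ROOT, g))
        self.tree_ = RestrictionGraph(
            edges, nodes=active + self.saturated_genes_, name="OT"
        )
        self.relations_ = self.tree_.relations()
        self.edge_probabilities_ = {
            (u, v): (p[v] if u == ROOT else freqs.p_joint.loc[u, v] / p[u])
            for u, v in self.tree_.edges
        }
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _branching(freqs: FrequencyTable, active: list[str]) -> list:
        if not active:
            return []
        p = freqs.p
        g = nx.DiGraph()
        g.add_node(ROOT)
        rank = {gene: i for i, gene in enumerate(sorted(active))}
        for j in active:
            w = _edge_weight(1.0, p[j], p[j])
            g.add_edge(ROOT, j, weight=w + _tiebreak(1.0, 0))
            for i in active:
                if i == j:
                    continue
                w = _edge_weight(p[i], p[j], freqs.p_joint.loc[i, j])
                if math.isinf(w):
                    continue
                g.add_edge(i, j, weight=w + _tiebreak(p[i], rank[i] + 1))
        branching = nx.maximum_spanning_arborescence(g, attr="weight")
        return list(branching.edges)

    def predict_relations(self):
        return self.relations_


def _tiebreak(parent_freq: float, parent_rank: int) -> float:
    # deterministic preference on exactly tied weights: higher parent
    # frequency first, then lexicographic parent order
    return 1e-9 * parent_freq - 1e-12 * parent_rank


def fit_ot(data) -> RestrictionGraph:
    """Thin functional wrapper: fit an OT and return the inferred tree."""
    return OncotreeEstimator().fit(data).tree_


def ot_relations(model: RestrictionGraph) -> frozenset:
    """Relations (transitive closure of cover relations, Root excluded)."""
    return graph_relations(model)
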