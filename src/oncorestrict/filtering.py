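"""Driver-candidate selection for the Drivers-Unknown scenario.

Four filters are used.  The S family keeps any gene whose marginal
mutation frequency is strictly larger than the threshold (S1: 1%, S5: 5%).
The J family keeps the largest gene set such that every unordered pair
within it is jointly mutated in at least threshold of the subjects (J1,
J5); this is a maximum clique of the qualifying-pair graph and is solved
exactly.  Whenever more than 12 genes qualify, the 12 most frequent are
kept.  Zero-row augmentation (the -A method variants) appends 10% all-zero
pseudosamples and, in the Drivers-Unknown pipeline, always runs after
filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sampling import Dataset

GENE_CAP = 12

FILTER_NAMES = ("S1", "S5", "J1", "J5")


@dataclass(frozen=True)
class FilterSpec:
    family: Literal["S", "J"]
    threshold: float
    cap: int = GENE_CAP

    def __post_init__(self) -> None:
        if self.family not in ("S", "J"):
            raise ValueError("family must be 'S' or 'J'")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_name(cls, name: str) -> "FilterSpec":
        if name not in FILTER_NAMES:
            raise ValueError(f"unknown filter {name!r}; valid: {FILTER_NAMES}")
        return cls(family=name[0], threshold={"1": 0.01, "5": 0.05}[name[1]])


class FrequencyFilter(BaseEstimator, TransformerMixin):
    """Column selector implementing the S/J driver filters.

    Parameters
    ----------
    method : str
        One of "S1", "S5", "J1", "J5".
    cap : int
        Maximal number of genes kept (the 12 most frequent when exceeded).

    Attributes
    ----------
    selected_genes_ : list of str
        Gene labels retained, in original column order.
    support_ : ndarray of bool
        Mask over input columns.
    """

    def __init__(self, method: str = "S1", cap: int = GENE_CAP):
        self.method = method
        self.cap = cap

    def fit(self, X, y=None):
        X = _as_frame(X)
        spec = FilterSpec.from_name(self.method)
        freqs = X.mean(axis=0)
        if spec.family == "S":
            selected = [g for g in X.columns if freqs[g] > spec.threshold]
        else:
            selected = _max_joint_set(X, spec.threshold)
        if len(selected) > self.cap:
            # keep the most common; ties broken lexicographically
            selected = sorted(selected, key=lambda g: (-freqs[g], g))[: self.cap]
        order = {g: i for i, g in enumerate(X.columns)}
        self.selected_genes_ = sorted(selected, key=order.get)
        self.support_ = np.array(
            [g in set(self.selected_genes_) for g in X.columns]
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X[self.selected_genes_]

    def get_support(self):
        return self.support_


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, Dataset):
        return X.matrix
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])


def _max_joint_set(X: pd.DataFrame, threshold: float) -> list[str]:
    """Largest gene set with every pairwise joint frequency >= threshold.

    Exact maximum clique of the qualifying-pair graph; ties among maximum
    cliques are broken by highest summed marginal frequency, then
    lexicographically.
    """
    genes = list(X.columns)
    vals = X.to_numpy(dtype=float)
    n = len(X)
    joint = vals.T @ vals / n
    g = nx.Graph()
    g.add_nodes_from(genes)
    for (i, a), (jx, b) in combinations(enumerate(genes), 2):
        if joint[i, jx] >= threshold:
            g.add_edge(a, b)
    best_size = 0
    cliques = []
    for clique in nx.find_cliques(g):
        if len(clique) > best_size:
            best_size = len(clique)
            cliques = [clique]
        elif len(clique) == best_size:
            cliques.append(clique)
    freqs = X.mean(axis=0)

    def keyfun(c):
        return (-sum(freqs[x] for x in c), tuple(sorted(c)))

    return sorted(min(cliques, key=keyfun))


def filter_genes(
    dataset: Dataset, spec: FilterSpec | str
) -> tuple[list[str], Dataset]:
    """Apply a filter to a dataset, returning (selected genes, filtered
    dataset with all rows and only the selected columns)."""
    name = spec if isinstance(spec, str) else f"{spec.family}{'1' if spec.threshold == 0.01 else '5'}"
    filt = FrequencyFilter(method=name).fit(dataset.matrix)
    sub = dataset.matrix[filt.selected_genes_]
    meta = dict(dataset.metadata, filter=name, selected_genes=filt.selected_genes_)
    return filt.selected_genes_, Dataset(sub, meta)


def augment(dataset: Dataset, fraction: float = 0.10) -> Dataset:
    """Append round-half-up(fraction * n) all-zero pseudosample rows.

    Augmentation encodes no order information; it only rescues genes at
    observed frequency one, which inference otherwise degenerates on.
    """
    n = dataset.n_subjects
    extra = int(math.floor(fraction * n + 0.5))
    zeros = pd.DataFrame(
        np.zeros((extra, len(dataset.gene_labels)), dtype=np.int8),
        columns=dataset.gene_labels,
    )
    matrix = pd.concat([dataset.matrix, zeros], ignore_index=True)
    meta = dict(dataset.metadata, augmented_rows=extra)
    return Dataset(matrix, meta)
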