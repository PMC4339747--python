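"""Restriction graphs: rooted DAGs encoding order restrictions among drivers.

A restriction graph is a rooted DAG whose nodes are driver genes plus a
distinguished ``Root``.  An edge u -> v means "mutation u must be present
before mutation v can confer a fitness advantage"; when a node has two or
more parents the semantics are conjunctive (*all* parents required), which
is the AND semantics shared by oncogenetic trees and conjunctive Bayesian
networks.  The stored edge set is always the cover (transitively reduced)
relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import json

import networkx as nx

ROOT = "Root"


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered driver and passenger gene labels of a simulated genome.

    By default passengers are added at a 4:1 passenger:driver ratio, the
    ratio used throughout the Drivers-Unknown scenario.
    """

    driver_labels: tuple[str, ...]
    passenger_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.driver_labels:
            raise ValueError("at least one driver gene is required")
        drivers = set(self.driver_labels)
        passengers = set(self.passenger_labels)
        if len(drivers) != len(self.driver_labels) or len(passengers) != len(
            self.passenger_labels
        ):
            raise ValueError("gene labels must be unique")
        if drivers & passengers:
            raise ValueError("driver and passenger labels must be disjoint")
        if ROOT in drivers or ROOT in passengers:
            raise ValueError(f"{ROOT!r} is a reserved label")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.driver_labels + self.passenger_labels

    @property
    def n_genes(self) -> int:
        return len(self.driver_labels) + len(self.passenger_labels)

    @classmethod
    def with_passengers(
        cls, driver_labels: Sequence[str], ratio: int = 4
    ) -> "GenomeSpec":
        """Driver labels plus ``ratio`` neutral passengers per driver."""
        n = len(driver_labels) * ratio
        passengers = tuple(f"P{i + 1}" for i in range(n))
        return cls(tuple(driver_labels), passengers)


class RestrictionGraph:
    """Rooted DAG of conjunctive order restrictions over driver genes.

    Parameters
    ----------
    edges
        Parent -> child pairs over driver labels; parents may be ``"Root"``.
        Drivers with no listed parent are attached to Root implicitly.
    nodes
        Optional full driver label list (to include isolated drivers).
    name
        Identifier such as ``"11-A"``.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> None:
        g = nx.DiGraph()
        g.add_node(ROOT)
        for node in nodes:
            g.add_node(node)
        for parent, child in edges:
            if child == ROOT:
                raise ValueError("Root cannot be a child")
            g.add_edge(parent, child)
        # implicit Root attachment for parentless drivers
        for node in list(g.nodes):
            if node != ROOT and g.in_degree(node) == 0:
                g.add_edge(ROOT, node)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("restriction graph must be acyclic")
        for node in g.nodes:
            if node != ROOT and not nx.has_path(g, ROOT, node):
                raise ValueError(f"driver {node!r} not reachable from Root")
        reduced = nx.transitive_reduction(g)
        if set(reduced.edges) != set(g.edges):
            raise ValueError("edge list must be the cover (reduced) relation")
        self._g = g
        self.name = name

    # -- basic structure ---------------------------------------------------

    @property
    def drivers(self) -> tuple[str, ...]:
        return tuple(sorted(n for n in self._g.nodes if n != ROOT))

    @property
    def n_drivers(self) -> int:
        return len(self._g.nodes) - 1

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._g.edges))

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._g.predecessors(node)))

    @property
    def has_conjunction(self) -> bool:
        """True iff some driver requires two or more parent mutations."""
        return any(
            self._g.in_degree(n) >= 2 for n in self._g.nodes if n != ROOT
        )

    def as_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RestrictionGraph):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and set(
            self._g.edges
        ) == set(other._g.edges)

    def __hash__(self) -> int:
        return hash((frozenset(self._g.nodes), frozenset(self._g.edges)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RestrictionGraph(name={self.name!r}, n_drivers={self.n_drivers}, "
            f"edges={list(self.edges)!r})"
        )

    # -- dependency evaluation ---------------------------------------------

    def count_driver_status(self, genotype: Iterable[str]) -> tuple[int, int]:
        """Split mutated drivers into (dependencies met, dependencies unmet).

        Returns ``(j, p)`` where ``j`` counts mutated drivers all of whose
        parents are mutated (Root counting as always mutated) and ``p``
        counts mutated drivers with at least one unmutated parent.
        Passenger labels in the genotype are ignored only if they are not
        driver labels of this graph; unknown labels are rejected elsewhere.
        """
        present = set(genotype)
        unknown = present - set(self._g.nodes)
        if unknown:
            raise ValueError(
                f"genotype labels {sorted(unknown)} not drivers of graph "
                f"{self.name!r}; strip passengers before calling"
            )
        j = p = 0
        for gene in present:
            if all(
                par == ROOT or par in present
                for par in self._g.predecessors(gene)
            ):
                j += 1
            else:
                p += 1
        return j, p

    def is_compatible(self, genotype: Iterable[str]) -> bool:
        """True iff the mutated drivers form a down-set of the graph order."""
        _, p = self.count_driver_status(genotype)
        return p == 0

    def relations(self) -> frozenset[tuple[str, str]]:
        """Transitive closure of the cover relations, Root excluded.

        These ordered pairs are the "relations" scored by the performance
        measures: (x, y) is a relation iff y is reachable from x, with the
        root node left out on both sides.
        """
        return relations(self._g)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": list(self.drivers),
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RestrictionGraph":
        return cls(
            edges=[tuple(e) for e in d.get("edges", [])],
            nodes=d.get("nodes", []),
            name=d.get("name", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RestrictionGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dot(self) -> str:
        lines = [f'digraph "{self.name or "restriction_graph"}" {{']
        for u, v in self.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self._g, path)


def relations(graph: nx.DiGraph | RestrictionGraph) -> frozenset[tuple[str, str]]:
    """Ordered pairs (x, y), neither Root, with y reachable from x."""
    g = graph.as_networkx() if isinstance(graph, RestrictionGraph) else graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("relations are defined for acyclic graphs only")
    out = set()
    for x in g.nodes:
        if x == ROOT:
            continue
        for y in nx.descendants(g, x):
            if y != ROOT:
                out.add((x, y))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Fixture graphs
# ---------------------------------------------------------------------------
#
# The study design uses six true graphs named 11-A, 11-B, 9-A, 9-B, 7-A and
# 7-B: 7, 9 and 11 driver nodes, the A variant of each size containing at
# least one conjunction and the B variant derived from A by deleting, at each
# multi-parent node, all but one incoming edge.  The exact published
# topologies are not available; the graphs below are RECONSTRUCTIONS that
# satisfy every stated structural constraint (node counts, conjunction
# status, B-from-A derivation, maximal paths spanning two to six drivers).

_FIXTURE_EDGES: dict[str, list[tuple[str, str]]] = {
    "7-A": [
        (ROOT, "A"), (ROOT, "B"), ("A", "C"), ("B", "C"),
        ("C", "D"), ("D", "G"), (ROOT, "E"), ("E", "F"),
    ],
    "9-A": [
        (ROOT, "A"), (ROOT, "B"), ("A", "C"), ("B", "C"),
        ("C", "D"), ("D", "E"), ("E", "I"), ("G", "I"),
        (ROOT, "F"), ("F", "G"), ("C", "H"),
    ],
    "11-A": [
        (ROOT, "A"), (ROOT, "B"), ("A", "C"), ("B", "C"),
        ("C", "D"), ("D", "E"), ("E", "F"), ("F", "G"),
        (ROOT, "H"), ("H", "I"), ("I", "K"), ("E", "K"),
        ("C", "J"),
    ],
}

# edges deleted from each A variant to obtain the conjunction-free B variant
_B_DELETIONS: dict[str, list[tuple[str, str]]] = {
    "7-B": [("B", "C")],
    "9-B": [("B", "C"), ("G", "I")],
    "11-B": [("B", "C"), ("E", "K")],
}

FIXTURE_NAMES = ("11-A", "11-B", "9-A", "9-B", "7-A", "7-B")


def fixture_graph(name: str) -> RestrictionGraph:
    """One of the six study graphs (reconstructed topologies; see module)."""
    if name in _FIXTURE_EDGES:
        return RestrictionGraph(_FIXTURE_EDGES[name], name=name)
    if name in _B_DELETIONS:
        a_name = name.replace("B", "A")
        removed = set(_B_DELETIONS[name])
        edges = [e for e in _FIXTURE_EDGES[a_name] if e not in removed]
        return RestrictionGraph(edges, name=name)
    raise KeyError(f"unknown fixture graph {name!r}; valid: {FIXTURE_NAMES}")


def fixture_graphs() -> dict[str, RestrictionGraph]:
    """All six named true graphs keyed by name."""
    return {name: fixture_graph(name) for name in FIXTURE_NAMES}


def random_graph(
    n_drivers: int, conjunction: bool, seed: int
) -> RestrictionGraph:
    """Random valid restriction graph on ``n_drivers`` genes.

    With ``conjunction=True`` (requires n_drivers >= 3) the result contains
    at least one node with two parents.  Deterministic given ``seed``.
    """
    import numpy as np

    if n_drivers < 1:
        raise ValueError("n_drivers must be >= 1")
    if conjunction and n_drivers < 3:
        raise ValueError("a conjunction needs at least 3 drivers")
    rng = np.random.default_rng(seed)
    labels = [f"G{i + 1}" for i in range(n_drivers)]
    edges: list[tuple[str, str]] = []
    if not conjunction:
        for i, lab in enumerate(labels):
            if i == 0:
                edges.append((ROOT, lab))
            else:
                edges.append((str(rng.choice([ROOT] + labels[:i])), lab))
        return RestrictionGraph(edges, nodes=labels, name=f"rand-{n_drivers}")
    # conjunction variant: two independent branch heads under Root, random
    # single-parent attachment for the middle, and a final node drawing two
    # parents with no ancestor relation between them (so both edges are
    # cover edges and the node is a genuine conjunction).
    head_a, head_b, *middle, last = labels if n_drivers > 3 else (
        labels[0], labels[1], labels[2]
    )
    if n_drivers == 3:
        middle = []
    edges = [(ROOT, head_a), (ROOT, head_b)]
    for i, lab in enumerate(middle):
        cands = [ROOT, head_a, head_b] + middle[:i]
        edges.append((str(rng.choice(cands)), lab))
    g = nx.DiGraph(edges)
    non_last = [head_a, head_b] + middle
    pairs = [
        (u, v)
        for i, u in enumerate(non_last)
        for v in non_last[i + 1 :]
        if not (nx.has_path(g, u, v) or nx.has_path(g, v, u))
    ]
    p1, p2 = pairs[int(rng.integers(len(pairs)))]
    edges += [(p1, last), (p2, last)]
    graph = RestrictionGraph(edges, nodes=labels, name=f"rand-{n_drivers}-conj")
    assert graph.has_conjunction
    return graph
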