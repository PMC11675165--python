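"""Causal DAGs: d-separation, implied conditional independencies, adjustment
sets, and single-edge graph revision.

The package ships two named graphs for the allostatic self-efficacy (ASE)
model of fatigue and depression over the variables

    A (age), G (gender), M (metacognition of allostatic control),
    F (fatigue), S (general self-efficacy), D (depression):

``J0``
    the original ASE graph: A and G feed every questionnaire score,
    M -> F, and F -> D <- S.
``J1``
    the revised graph, J0 plus a directed edge M -> S.

d-separation is decided by reachability on the moralized ancestral subgraph;
an exhaustive path-enumeration oracle in the test suite is the contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Dag",
    "CiStatement",
    "J0",
    "J1",
    "is_d_separated",
    "implied_ci_statements",
    "is_valid_adjustment_set",
    "reconcile_single_edge",
]


class GraphError(ValueError):
    """Invalid graph input (unknown node, cycle, malformed statement)."""


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes
        Ordered variable names. Order fixes canonical output ordering.
    edges
        Set of ``(parent, child)`` pairs. Must be acyclic, without
        self-loops, and with both endpoints in ``nodes``.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]]):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise GraphError("duplicate node names")
        edges = frozenset((str(p), str(c)) for p, c in edges)
        node_set = set(nodes)
        for p, c in edges:
            if p == c:
                raise GraphError(f"self-loop on {p!r}")
            if p not in node_set or c not in node_set:
                raise GraphError(f"edge ({p!r}, {c!r}) has endpoint outside nodes")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a directed cycle")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    # -- basic structure -------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> set[str]:
        self._check_nodes([node])
        return {p for p, c in self.edges if c == node}

    def children(self, node: str) -> set[str]:
        self._check_nodes([node])
        return {c for p, c in self.edges if p == node}

    def ancestors(self, nodes: Iterable[str]) -> set[str]:
        """All nodes with a directed path into ``nodes``, including them."""
        nodes = list(nodes)
        self._check_nodes(nodes)
        out: set[str] = set(nodes)
        frontier = list(nodes)
        while frontier:
            v = frontier.pop()
            for p in self.parents(v):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    def descendants(self, node: str) -> set[str]:
        """Strict descendants of ``node``."""
        g = self.to_networkx()
        return set(nx.descendants(g, node))

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(
            self.to_networkx(), key=self.nodes.index))
        return order

    def add_edge(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, set(self.edges) | {(parent, child)})

    def _check_nodes(self, names: Iterable[str]) -> None:
        unknown = set(names) - set(self.nodes)
        if unknown:
            raise GraphError(f"unknown variable name(s): {sorted(unknown)}")

    # -- serialization ----------------------------------------------------

    def to_edge_list(self) -> str:
        """One ``parent child`` pair per line, canonically ordered."""
        return "\n".join(f"{p} {c}" for p, c in sorted(self.edges)) + "\n"

    @classmethod
    def from_edge_list(cls, text: str, nodes: Sequence[str] | None = None) -> "Dag":
        edges = []
        seen: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p, c = line.split()
            edges.append((p, c))
            for v in (p, c):
                if v not in seen:
                    seen.append(v)
        return cls(nodes if nodes is not None else seen, edges)

    def to_dot(self, name: str = "G") -> str:
        lines = [f"digraph {name} {{"]
        lines += [f"  {v};" for v in self.nodes]
        lines += [f"  {p} -> {c};" for p, c in sorted(self.edges)]
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CiStatement:
    """A conditional-independence statement ``x _||_ y | z``."""

    x: str
    y: str
    z: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, x: str, y: str, z: Iterable[str] = ()):
        z = frozenset(z)
        if x == y:
            raise GraphError("x and y must differ")
        if x in z or y in z:
            raise GraphError("x and y must not appear in the conditioning set")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def validate(self, dag: Dag) -> None:
        dag._check_nodes({self.x, self.y, *self.z})

    def __str__(self) -> str:  # e.g. "M _||_ S | A,G"
        cond = ",".join(sorted(self.z))
        return f"{self.x} _||_ {self.y}" + (f" | {cond}" if cond else "")


# The ASE variable set and the two named graphs.
ASE_NODES = ("A", "G", "M", "F", "S", "D")

J0 = Dag(
    ASE_NODES,
    [
        ("A", "M"), ("G", "M"),
        ("M", "F"), ("A", "F"), ("G", "F"),
        ("A", "S"), ("G", "S"),
        ("F", "D"), ("S", "D"), ("A", "D"), ("G", "D"),
    ],
)

J1 = J0.add_edge("M", "S")


def is_d_separated(dag: Dag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Decide whether ``z`` d-separates ``x`` and ``y`` in ``dag``.

    Uses undirected reachability on the moralized ancestral subgraph: restrict
    to ancestors of ``{x, y} | z``, marry co-parents, drop ``z``, and test
    connectivity.  Symmetric in ``x`` and ``y``.
    """
    stmt = CiStatement(x, y, z)
    stmt.validate(dag)
    z = set(stmt.z)

    relevant = dag.ancestors({x, y, *z})
    und: dict[str, set[str]] = {v: set() for v in relevant}
    for p, c in dag.edges:
        if p in relevant and c in relevant:
            und[p].add(c)
            und[c].add(p)
    # marry parents of every common child within the ancestral subgraph
    for v in relevant:
        ps = [p for p in dag.parents(v) if p in relevant]
        for a, b in itertools.combinations(ps, 2):
            und[a].add(b)
            und[b].add(a)
    # remove conditioned nodes, then search x -> y
    frontier = [x]
    seen = {x}
    while frontier:
        v = frontier.pop()
        for w in und[v]:
            if w in z or w in seen:
                continue
            if w == y:
                return False
            seen.add(w)
            frontier.append(w)
    return True


def implied_ci_statements(dag: Dag, max_cond_size: int) -> list[CiStatement]:
    """Every CI statement with ``|z| <= max_cond_size`` implied by ``dag``.

    Returns statements in canonical order: lexicographic by ``x`` then ``y``
    (each unordered pair appears once with ``x < y``), then by sorted ``z``.
    """
    if max_cond_size < 0:
        raise GraphError("max_cond_size must be nonnegative")
    if max_cond_size > len(dag.nodes) - 2:
        raise GraphError("max_cond_size exceeds |nodes| - 2")
    out: list[CiStatement] = []
    for x, y in itertools.combinations(sorted(dag.nodes), 2):
        rest = sorted(set(dag.nodes) - {x, y})
        for k in range(max_cond_size + 1):
            for z in itertools.combinations(rest, k):
                if is_d_separated(dag, x, y, z):
                    out.append(CiStatement(x, y, z))
    return out


def is_valid_adjustment_set(
    dag: Dag, treatments: Iterable[str], outcome: str, z: Iterable[str] = ()
) -> bool:
    """Backdoor criterion for ``z`` relative to ``(treatments, outcome)``.

    ``z`` is valid when it contains no descendant of any treatment and blocks
    every backdoor path (paths entering a treatment through an incoming edge).
    """
    treatments = set(treatments)
    z = set(z)
    dag._check_nodes(treatments | z | {outcome})
    if treatments & z:
        raise GraphError("treatments and adjustment set overlap")
    if outcome in treatments or outcome in z:
        raise GraphError("outcome must not be a treatment or in z")
    for t in treatments:
        if dag.descendants(t) & z:
            return False
    # Block backdoor paths: remove edges out of the treatments, then require
    # d-separation of treatments and outcome given z in the surgered graph.
    surgered = Dag(
        dag.nodes, {(p, c) for p, c in dag.edges if p not in treatments}
    )
    return all(
        is_d_separated(surgered, t, outcome, z - {t})
        for t in treatments
        if t != outcome
    )


def reconcile_single_edge(
    dag: Dag,
    decisions: Sequence[tuple[CiStatement, bool]],
    candidate_nodes: Iterable[str] | None = ("M", "F", "S", "D"),
) -> list[tuple[Dag, tuple[str, str] | None, int]]:
    """Score single-edge additions against observed CI test decisions.

    Each decision pairs a tested statement with ``rejected`` (True when the
    test rejected conditional independence).  A candidate graph predicts
    "not rejected" exactly when it d-separates the statement; the mismatch
    count is the number of decisions the candidate gets wrong.

    Parameters
    ----------
    candidate_nodes
        Endpoints allowed for the new edge.  Defaults to the questionnaire
        scores {M, F, S, D}: age and gender are exogenous demographics and
        not plausible targets of revision.  Pass ``None`` to allow any pair.

    Returns
    -------
    list of (candidate dag, added edge or None, mismatch count), sorted by
    ascending mismatch then lexicographically by edge; the unmodified input
    graph (edge ``None``) is always included as baseline and sorts before
    any edge at equal mismatch.
    """
    if not decisions:
        raise GraphError("decisions must be nonempty")
    for stmt, _ in decisions:
        stmt.validate(dag)

    if candidate_nodes is None:
        pool = dag.nodes
    else:
        pool = tuple(candidate_nodes)
        dag._check_nodes(pool)

    def mismatches(g: Dag) -> int:
        return sum(
            is_d_separated(g, s.x, s.y, s.z) == rejected for s, rejected in decisions
        )

    scored: list[tuple[Dag, tuple[str, str] | None, int]] = [
        (dag, None, mismatches(dag))
    ]
    for p, c in itertools.permutations(pool, 2):
        if (p, c) in dag.edges:
            continue
        try:
            cand = dag.add_edge(p, c)
        except GraphError:  # cycle
            continue
        scored.append((cand, (p, c), mismatches(cand)))
    # baseline (edge None) sorts before any concrete edge at equal mismatch
    scored.sort(key=lambda t: (t[2], t[1] is not None, t[1] or ("", "")))
    return scored
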