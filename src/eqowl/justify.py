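"""Justification of hasPheno links over instance graphs.

An annotation links a phenotype bearer (typically an organism) to a *pheno*
— the quality or relator complex it exhibits — via the encapsulating
``hasPheno`` relation.  That link is an interpretive overlay, not a basic
fact: it must be *justified* by a chain of basic relations (inheres-in,
part-of, has-function, participates-in, role/player links, …) connecting
the pheno to the bearer.  This module checks that requirement on explicit
instance graphs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx

from .errors import UnknownNodeError
from .model import Term

__all__ = [
    "HASPHENO_LABEL", "DEFAULT_ALLOWED", "DEFAULT_MAX_DEPTH",
    "InstanceGraph", "ChainStep", "JustificationResult",
    "justify_haspheno", "audit_graph",
]

HASPHENO_LABEL = "hasPheno"

#: Basic relations accepted in justification chains by default.  The set is
#: open-ended by design; callers may pass their own.
DEFAULT_ALLOWED: FrozenSet[str] = frozenset(
    {
        "inheres-in", "part-of", "has-function", "participates-in",
        "has-role", "role-of", "plays", "played-by",
    }
)

#: Guard against pathological graphs; realistic chains are length <= 4.
DEFAULT_MAX_DEPTH = 10


class InstanceGraph:
    """A directed multigraph of typed individuals.

    Nodes are (id, type term) pairs; edges carry free-string relation
    labels, several edges may connect the same pair of nodes.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    def add_node(self, node_id: str, node_type: Term) -> None:
        self._g.add_node(node_id, type=node_type)

    def add_edge(self, source: str, relation: str, target: str) -> None:
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise UnknownNodeError(f"edge endpoint {endpoint!r} not declared")
        self._g.add_edge(source, target, relation=relation)

    @property
    def nodes(self) -> Dict[str, Term]:
        return {n: d["type"] for n, d in self._g.nodes(data=True)}

    @property
    def edges(self) -> List[Tuple[str, str, str]]:
        return [(u, d["relation"], v) for u, v, d in self._g.edges(data=True)]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def haspheno_edges(self) -> List[Tuple[str, str]]:
        """(bearer, pheno) pairs of hasPheno edges, sorted by endpoints."""
        return sorted(
            (u, v)
            for u, v, d in self._g.edges(data=True)
            if d["relation"] == HASPHENO_LABEL
        )

    def _neighbors(self, node: str, allowed: FrozenSet[str]):
        """Allowed edges incident to ``node``, traversable both ways."""
        for _, v, d in self._g.out_edges(node, data=True):
            if d["relation"] in allowed:
                yield v, d["relation"], "forward"
        for u, _, d in self._g.in_edges(node, data=True):
            if d["relation"] in allowed:
                yield u, d["relation"], "reverse"


@dataclass(frozen=True)
class ChainStep:
    """One hop of a justification chain, read from pheno towards bearer.

    ``direction`` records how the underlying directed edge was traversed:
    ``forward`` follows the edge from ``source`` to ``target`` as stored,
    ``reverse`` walks a stored ``target → source`` edge backwards.
    """

    source: str
    relation: str
    direction: str
    target: str


@dataclass(frozen=True)
class JustificationResult:
    justified: bool
    chain: Optional[Tuple[ChainStep, ...]] = None
    failure_reason: Optional[str] = None  # no-path | depth-exceeded


def justify_haspheno(
    g: InstanceGraph,
    bearer: str,
    pheno: str,
    allowed: FrozenSet[str] = DEFAULT_ALLOWED,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> JustificationResult:
    """Search for a shortest chain of allowed basic relations from ``pheno``
    to ``bearer``.

    Edges are traversable in both directions (the chain must *connect* the
    two individuals; inverse dialects like part-of/has-part should not
    matter).  ``hasPheno`` itself must not be in ``allowed`` — a hasPheno
    link cannot justify itself.
    """
    allowed = frozenset(allowed)
    if HASPHENO_LABEL in allowed:
        raise ValueError(f"{HASPHENO_LABEL} cannot appear in the allowed set")
    for node in (bearer, pheno):
        if node not in g:
            raise UnknownNodeError(f"unknown node {node!r}")
    # breadth-first search from the pheno; BFS guarantees chain minimality
    parent: Dict[str, Optional[ChainStep]] = {pheno: None}
    queue = deque([(pheno, 0)])
    found_depth = None
    while queue:
        node, depth = queue.popleft()
        if node == bearer:
            found_depth = depth
            break
        for nxt, relation, direction in g._neighbors(node, allowed):
            if nxt not in parent:
                parent[nxt] = ChainStep(node, relation, direction, nxt)
                queue.append((nxt, depth + 1))
    if found_depth is None:
        return JustificationResult(justified=False, failure_reason="no-path")
    if found_depth > max_depth:
        return JustificationResult(justified=False, failure_reason="depth-exceeded")
    chain: List[ChainStep] = []
    node = bearer
    while parent[node] is not None:
        step = parent[node]
        chain.append(step)
        node = step.source
    chain.reverse()
    return JustificationResult(justified=True, chain=tuple(chain))


def audit_graph(
    g: InstanceGraph,
    allowed: FrozenSet[str] = DEFAULT_ALLOWED,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> List[Tuple[Tuple[str, str], JustificationResult]]:
    """Justify every hasPheno edge in the graph.

    Returns one ((bearer, pheno), result) pair per hasPheno edge, in
    deterministic endpoint-sorted order.
    """
    return [
        ((bearer, pheno), justify_haspheno(g, bearer, pheno, allowed, max_depth))
        for bearer, pheno in g.haspheno_edges()
    ]
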