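"""Minimum spanning arborescence (Chu-Liu/Edmonds).

Given a weighted directed graph and a root, find the minimum-total-weight
directed spanning tree with all edges pointing away from the root. The
classic cycle-contraction algorithm is implemented here directly so that
tie-breaking is fully deterministic: when two candidate incoming edges have
equal (possibly contraction-adjusted) weight, the edge with the smaller
caller-supplied tie key wins. This makes map construction reproducible
bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count
from typing import Hashable, Iterable, Mapping

__all__ = ["minimum_arborescence", "UnreachableNodeError"]


class UnreachableNodeError(ValueError):
    """Some node has no incoming path from the root."""

    def __init__(self, nodes: list):
        self.nodes = list(nodes)
        super().__init__(f"unreachable from root: {self.nodes}")


@dataclass(eq=False)  # identity hashing: each edge object is unique
class _Edge:
    u: Hashable
    v: Hashable
    w: float
    key: tuple
    orig: "_Edge | None" = None  # edge at the previous contraction level


def _best_incoming(nodes, edges, root):
    best: dict = {}
    for e in edges:
        if e.v == root or e.u == e.v:
            continue
        cur = best.get(e.v)
        if cur is None or (e.w, e.key) < (cur.w, cur.key):
            best[e.v] = e
    missing = [v for v in nodes if v != root and v not in best]
    if missing:
        raise UnreachableNodeError(missing)
    return best


def _find_cycle(nodes, best, root):
    color: dict = {}
    for start in nodes:
        if start == root or color.get(start) == 2:
            continue
        path = []
        v = start
        while v != root and color.get(v) is None:
            color[v] = 1
            path.append(v)
            v = best[v].u
        if color.get(v) == 1:  # closed a new cycle
            return path[path.index(v):]
        for p in path:
            color[p] = 2
    return None


def _solve(nodes: set, edges: list[_Edge], root, fresh) -> set[_Edge]:
    best = _best_incoming(nodes, edges, root)
    cycle = _find_cycle(nodes, best, root)
    if cycle is None:
        return set(best.values())

    C = set(cycle)
    cnode = ("__contracted__", next(fresh))
    new_nodes = (nodes - C) | {cnode}
    new_edges: list[_Edge] = []
    for e in edges:
        if e.u in C and e.v in C:
            continue
        if e.v in C:
            new_edges.append(_Edge(e.u, cnode, e.w - best[e.v].w, e.key, orig=e))
        elif e.u in C:
            new_edges.append(_Edge(cnode, e.v, e.w, e.key, orig=e))
        else:
            new_edges.append(_Edge(e.u, e.v, e.w, e.key, orig=e))

    sub = _solve(new_nodes, new_edges, root, fresh)

    chosen: set[_Edge] = set()
    entering: _Edge | None = None
    for e in sub:
        if e.v == cnode:
            entering = e
        chosen.add(e.orig)  # type: ignore[arg-type]
    if entering is None:  # pragma: no cover - root can never be contracted
        raise AssertionError("contracted cycle has no entering edge")
    vstar = entering.orig.v  # cycle node actually entered
    for v in C:
        if v != vstar:
            chosen.add(best[v])
    return chosen


def minimum_arborescence(
    nodes: Iterable[Hashable],
    weights: Mapping[tuple, float],
    root: Hashable,
    tie_keys: Mapping[tuple, tuple] | None = None,
) -> set[tuple]:
    """Minimum-weight spanning arborescence rooted at ``root``.

    Parameters
    ----------
    nodes : iterable
        All nodes to span (must include the root).
    weights : mapping (u, v) -> float
        Directed edge weights; absent pairs are absent edges.
    root : node
        Every other node must be reachable from it, else
        :class:`UnreachableNodeError`.
    tie_keys : mapping (u, v) -> sortable, optional
        Secondary comparison used when adjusted weights tie; defaults to the
        edge pair itself (lexicographic).

    Returns
    -------
    set of (u, v) edges of the optimal arborescence.
    """
    node_set = set(nodes)
    if root not in node_set:
        raise ValueError(f"root {root!r} not among nodes")
    edges = [
        _Edge(u, v, float(w), tuple(tie_keys[(u, v)]) if tie_keys else (u, v))
        for (u, v), w in weights.items()
        if u in node_set and v in node_set
    ]
    if len(node_set) == 1:
        return set()
    chosen = _solve(node_set, edges, root, count())
    return {(e.u, e.v) for e in chosen}
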