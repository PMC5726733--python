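"""Path-existence search between two residues in a contact (sub)graph.

Three routes answer "is the active site reachable from the allosteric site?"

* :func:`find_path_astar` -- best-first search on f = g + h, where g is the
  accumulated straight-line step length between representative coordinates
  and h the straight-line distance to the end node.  Complete on finite
  graphs whatever the heuristic, so the existence answer never depends on h.
* :func:`find_path_dfs` -- exhaustive depth-first search with an explicit
  stack (no recursion, so MutS-scale subgraphs with deep paths are safe);
  children are explored nearest-the-end first.
* :func:`connected_oracle` -- plain breadth-first connectivity with no
  heuristic at all, kept as the independent reference.

:func:`shortest_path` (fewest hops, BFS) exists only for reporting worked
examples; the null model consumes path existence, not path length.

All tie-breaks are by node index, so fixed seeds give bit-identical runs.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np

from .contacts import ContactGraph
from .errors import InputError

__all__ = [
    "PathResult",
    "find_path_astar",
    "find_path_dfs",
    "connected_oracle",
    "shortest_path",
    "validate_path",
    "format_path",
]


@dataclass(frozen=True)
class PathResult:
    """Outcome of a path search.

    ``path`` is the ordered node-index list from start to end (empty when no
    path exists); ``nodes_expanded`` counts nodes taken off the frontier.
    """

    found: bool
    path: tuple[int, ...]
    nodes_expanded: int


def _check_endpoints(graph: ContactGraph, start: int, end: int) -> None:
    if start == end:
        raise InputError("start and end must be distinct nodes")
    for node in (start, end):
        if not graph.has_node(node):
            raise InputError(f"node {node} is not in the graph")


def _heuristic_vector(
    graph: ContactGraph, coords: np.ndarray | None, end: int,
    heuristic: np.ndarray | None,
) -> np.ndarray:
    if heuristic is not None:
        return np.asarray(heuristic, dtype=np.float64)
    if coords is None:
        raise InputError("either coords or an explicit heuristic vector is required")
    coords = np.asarray(coords, dtype=np.float64)
    return np.linalg.norm(coords - coords[end], axis=1)


def find_path_astar(
    graph: ContactGraph,
    coords: np.ndarray | None,
    start: int,
    end: int,
    heuristic: np.ndarray | None = None,
) -> PathResult:
    """A* search; found iff ``end`` is reachable from ``start``.

    ``coords`` is the per-node representative coordinate array indexed by
    original node index; ``heuristic`` may instead supply h directly (e.g.
    the distance-matrix row of the end residue).  Path cost g accumulates
    straight-line step lengths, in the same A units as h.
    """
    _check_endpoints(graph, start, end)
    h = _heuristic_vector(graph, coords, end, heuristic)
    if coords is not None:
        coords = np.asarray(coords, dtype=np.float64)

    def step(i: int, j: int) -> float:
        if coords is None:
            return 1.0  # hop cost; existence and completeness are unaffected
        return float(np.linalg.norm(coords[i] - coords[j]))

    open_heap: list[tuple[float, int, int]] = [(float(h[start]), start, start)]
    g_score = {start: 0.0}
    came_from: dict[int, int] = {}
    closed: set[int] = set()
    expanded = 0
    while open_heap:
        f, node, _ = heapq.heappop(open_heap)
        if node in closed:
            continue
        closed.add(node)
        expanded += 1
        if node == end:
            return PathResult(True, _reconstruct(came_from, start, end), expanded)
        g = g_score[node]
        for nb in graph.adjacency[node]:
            nb = int(nb)
            if nb in closed:
                continue
            tentative = g + step(node, nb)
            if tentative < g_score.get(nb, np.inf):
                g_score[nb] = tentative
                came_from[nb] = node
                heapq.heappush(open_heap, (tentative + float(h[nb]), nb, node))
    return PathResult(False, (), expanded)


def find_path_dfs(
    graph: ContactGraph,
    coords: np.ndarray | None,
    start: int,
    end: int,
    heuristic: np.ndarray | None = None,
) -> PathResult:
    """Exhaustive depth-first search with an explicit stack.

    Children are explored in increasing distance to the end node (ties by
    node index); a visited set prevents revisits.
    """
    _check_endpoints(graph, start, end)
    h = _heuristic_vector(graph, coords, end, heuristic)
    visited = {start}
    parent: dict[int, int] = {}
    stack: list[int] = [start]
    expanded = 0
    while stack:
        node = stack.pop()
        expanded += 1
        if node == end:
            return PathResult(True, _reconstruct(parent, start, end), expanded)
        children = [int(nb) for nb in graph.adjacency[node] if int(nb) not in visited]
        # Nearest-the-end explored first = pushed last (LIFO).
        children.sort(key=lambda j: (float(h[j]), j), reverse=True)
        for nb in children:
            visited.add(nb)
            parent[nb] = node
            stack.append(nb)
    return PathResult(False, (), expanded)


def connected_oracle(graph: ContactGraph, start: int, end: int) -> bool:
    """True iff start and end lie in the same connected component (plain BFS)."""
    _check_endpoints(graph, start, end)
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node == end:
            return True
        for nb in graph.adjacency[node]:
            nb = int(nb)
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return False


def shortest_path(graph: ContactGraph, start: int, end: int) -> PathResult:
    """Fewest-hop path by breadth-first search.

    Neighbours are enqueued in increasing node-index order, so among equal-
    length paths the one through the smallest node index at each layer is
    returned, deterministically.
    """
    _check_endpoints(graph, start, end)
    parent: dict[int, int] = {}
    seen = {start}
    queue = deque([start])
    expanded = 0
    while queue:
        node = queue.popleft()
        expanded += 1
        if node == end:
            return PathResult(True, _reconstruct(parent, start, end), expanded)
        for nb in graph.adjacency[node]:  # adjacency arrays are sorted
            nb = int(nb)
            if nb not in seen:
                seen.add(nb)
                parent[nb] = node
                queue.append(nb)
    return PathResult(False, (), expanded)


def _reconstruct(parent: dict[int, int], start: int, end: int) -> tuple[int, ...]:
    path = [end]
    while path[-1] != start:
        path.append(parent[path[-1]])
    return tuple(reversed(path))


def validate_path(result: PathResult, graph: ContactGraph, start: int, end: int) -> bool:
    """Check PathResult invariants against the graph it was found in."""
    if not result.found:
        return result.path == ()
    path = result.path
    if not path or path[0] != start or path[-1] != end:
        return False
    if len(set(path)) != len(path):
        return False
    for i, j in zip(path[:-1], path[1:]):
        if not graph.has_node(i) or j not in set(int(x) for x in graph.adjacency[i]):
            return False
    return True


def format_path(result: PathResult, labels) -> str:
    """Render a path in author numbering, e.g. ``376 -> 367 -> 388 -> 313``."""
    if not result.found:
        return "(no path)"
    return " -> ".join(str(labels[i][1]) for i in result.path)
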