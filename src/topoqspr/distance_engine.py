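"""All-pairs shortest-path and detour (longest simple path) matrices.

The shortest-path matrix comes from breadth-first search on the unweighted
graph.  The detour matrix — the length of the longest *simple* path between
each vertex pair — is NP-hard in general, but molecular graphs are sparse
with small biconnected blocks, so we decompose the graph into its block-cut
tree and solve each block exactly:

* a simple path between u and v crosses each block on the unique block path
  between them at most once, entering and leaving through cut vertices;
* the detour distance is therefore the sum of within-block detour distances
  along that block path;
* within one block (at molecular scale: a fused-ring system of <= ~20
  vertices and cyclomatic number <= ~6) exact depth-first enumeration of
  simple paths is cheap.

Everything here is deterministic: iteration order is fixed by vertex index.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chem_graph import MolecularGraph

__all__ = [
    "DistanceMatrix",
    "DetourMatrix",
    "DetourBudgetError",
    "shortest_path_matrix",
    "detour_matrix",
    "brute_force_detour",
]

# Hard ceiling on DFS steps per block; molecular blocks use a tiny fraction
# of this.  Exceeding it raises instead of silently approximating.
_BLOCK_DFS_BUDGET = 50_000_000


class DetourBudgetError(RuntimeError):
    """Raised when exact detour computation would exceed its step budget."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of unweighted shortest-path lengths (edge counts)."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", v)
        if v.shape != (self.n, self.n):
            raise ValueError(f"distance matrix shape {v.shape} != ({self.n},{self.n})")


@dataclass(frozen=True)
class DetourMatrix:
    """Symmetric matrix of longest-simple-path lengths (edge counts)."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", v)
        if v.shape != (self.n, self.n):
            raise ValueError(f"detour matrix shape {v.shape} != ({self.n},{self.n})")


def shortest_path_matrix(g: MolecularGraph) -> DistanceMatrix:
    """Exact all-pairs shortest-path lengths via BFS from every source."""
    G = g.to_networkx()
    n = g.n_vertices
    out = np.zeros((n, n), dtype=np.int64)
    for src in range(n):
        lengths = nx.single_source_shortest_path_length(G, src)
        if len(lengths) != n:
            raise ValueError(f"{g.name}: graph is disconnected")  # pragma: no cover
        for dst, d in lengths.items():
            out[src, dst] = d
    return DistanceMatrix(n=n, values=out)


def _block_detour_table(G: nx.Graph, block: tuple[int, ...]) -> dict[tuple[int, int], int]:
    """Exact all-pairs detour distances within one biconnected block.

    DFS over simple paths from each source, recording the longest arrival
    at every other block vertex.
    """
    sub = {v: sorted(set(G[v]) & set(block)) for v in block}
    table: dict[tuple[int, int], int] = {}
    budget = _BLOCK_DFS_BUDGET
    for src in block:
        best = {v: -1 for v in block}
        # iterative DFS; each stack frame is (vertex, depth); visited is a
        # mutable path set maintained by sentinel pops
        stack: list[tuple[int, int]] = [(src, 0)]
        visited: set[int] = set()
        while stack:
            budget -= 1
            if budget <= 0:
                raise DetourBudgetError(
                    f"detour enumeration exceeded {_BLOCK_DFS_BUDGET} steps "
                    f"in a block of {len(block)} vertices"
                )
            v, depth = stack.pop()
            if v < 0:
                visited.discard(~v)
                continue
            visited.add(v)
            stack.append((~v, depth))  # sentinel: unmark on the way back
            if depth > best[v]:
                best[v] = depth
            for w in sub[v]:
                if w not in visited:
                    stack.append((w, depth + 1))
        for dst in block:
            if dst != src:
                table[(src, dst)] = best[dst]
    return table


def detour_matrix(g: MolecularGraph) -> DetourMatrix:
    """Exact detour matrix via block-cut-tree decomposition.

    For vertices u, v the unique path in the block-cut tree visits a sequence
    of blocks joined at cut vertices; the detour distance is the sum of exact
    within-block detours between consecutive anchors u, c1, ..., ck, v.
    """
    G = g.to_networkx()
    n = g.n_vertices
    if n == 1:
        return DetourMatrix(n=1, values=np.zeros((1, 1), dtype=np.int64))

    blocks = [tuple(sorted(c)) for c in nx.biconnected_components(G)]
    cut_vertices = set(nx.articulation_points(G))
    tables = [_block_detour_table(G, blk) for blk in blocks]

    # Block-cut tree: one node per block, one per cut vertex.
    bc = nx.Graph()
    home_block: dict[int, int] = {}
    for i, blk in enumerate(blocks):
        bc.add_node(("B", i))
        for v in blk:
            if v in cut_vertices:
                bc.add_edge(("B", i), ("C", v))
            else:
                home_block[v] = i

    def node_of(v: int):
        return ("C", v) if v in cut_vertices else ("B", home_block[v])

    out = np.zeros((n, n), dtype=np.int64)
    # Cache tree paths per source for determinism and speed.
    for u in range(n):
        paths = nx.single_source_shortest_path(bc, node_of(u))
        for v in range(u + 1, n):
            path = paths[node_of(v)]
            total = 0
            anchor = u
            for node in path:
                if node[0] != "B":
                    continue
                i = node[1]
                # the next cut vertex after this block on the path, or v
                pos = path.index(node)
                nxt = v
                for later in path[pos + 1:]:
                    if later[0] == "C":
                        nxt = later[1]
                        break
                if anchor != nxt:
                    total += tables[i][(anchor, nxt)]
                    anchor = nxt
            out[u, v] = out[v, u] = total
    return DetourMatrix(n=n, values=out)


def brute_force_detour(g: MolecularGraph, a: int, b: int) -> int:
    """Test oracle: longest simple a-b path by whole-graph DFS enumeration.

    Exponential in the worst case; refuses graphs with more than 12 vertices.
    """
    if g.n_vertices > 12:
        raise ValueError(
            f"brute-force detour oracle refuses n={g.n_vertices} > 12 vertices"
        )
    if not (0 <= a < g.n_vertices and 0 <= b < g.n_vertices):
        raise ValueError(f"vertex out of range: {a}, {b}")
    if a == b:
        return 0
    adj: dict[int, list[int]] = {v: [] for v in range(g.n_vertices)}
    for x, y in g.sorted_edges():
        adj[x].append(y)
        adj[y].append(x)
    best = -1
    stack = [(a, frozenset([a]), 0)]
    while stack:
        v, vis, ln = stack.pop()
        if v == b:
            best = max(best, ln)
            continue
        for w in adj[v]:
            if w not in vis:
                stack.append((w, vis | {w}, ln + 1))
    return best
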