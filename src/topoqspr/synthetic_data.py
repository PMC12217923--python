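"""Synthetic inputs: random molecular-scale graphs and QSPR datasets.

The graph generator emulates hydrogen-depleted drug skeletons: a uniform
random labeled tree (drawn via a Pruefer sequence, so tree shapes are
unbiased) plus a chosen number of extra non-tree edges, giving a connected
simple graph whose cyclomatic number equals ``extra_edges``.  The study
drugs span 19-28 heavy atoms with 1-4 rings; the defaults bracket that range
(trees through cyclomatic 6, up to 30 vertices).

The QSPR generator draws property values from the same linear model the
analysis assumes, P = A* + b* TI + eps with Gaussian noise, so parameter
recovery can be checked against known truth.  All randomness flows from a
single integer seed; nothing uses global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chem_graph import MolecularGraph
from .topo_indices import INDEX_FIELDS, compute_index_set

__all__ = [
    "SyntheticQsprSpec",
    "random_connected_graph",
    "generate_qspr_dataset",
]


@dataclass(frozen=True)
class SyntheticQsprSpec:
    """Ground-truth configuration for one synthetic QSPR dataset."""

    n_molecules: int
    true_intercept: float
    true_slope: float
    noise_sd: float
    seed: int
    index: str = "wiener"
    n_vertices_range: tuple[int, int] = (12, 30)
    max_extra_edges: int = 6

    def __post_init__(self) -> None:
        if self.n_molecules < 3:
            raise ValueError(f"n_molecules must be >= 3, got {self.n_molecules}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.index not in INDEX_FIELDS:
            raise ValueError(f"unknown index {self.index!r}")


def random_connected_graph(n: int, extra_edges: int, seed: int) -> MolecularGraph:
    """Uniform random tree on n vertices plus extra_edges distinct chords.

    The result is connected and simple by construction with cyclomatic
    number exactly ``extra_edges``; identical seeds give identical graphs.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 vertices, got {n}")
    max_extra = n * (n - 1) // 2 - (n - 1)
    if not 0 <= extra_edges <= max_extra:
        raise ValueError(
            f"extra_edges={extra_edges} infeasible for n={n} "
            f"(must be in 0..{max_extra})"
        )
    rng = np.random.default_rng(seed)
    if n == 2:
        tree_edges = {(0, 1)}
    else:
        pruefer = [int(x) for x in rng.integers(0, n, size=n - 2)]
        tree = nx.from_prufer_sequence(pruefer)
        tree_edges = {(min(a, b), max(a, b)) for a, b in tree.edges()}
    edges = set(tree_edges)
    if extra_edges:
        non_edges = sorted(
            (a, b)
            for a in range(n)
            for b in range(a + 1, n)
            if (a, b) not in edges
        )
        picks = rng.choice(len(non_edges), size=extra_edges, replace=False)
        edges.update(non_edges[i] for i in picks)
    return MolecularGraph(
        name=f"synthetic(n={n},chords={extra_edges},seed={seed})",
        n_vertices=n,
        edges=frozenset(edges),
    )


def generate_qspr_dataset(
    spec: SyntheticQsprSpec,
    max_attempts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw graphs, compute the chosen index, and emit noisy properties.

    Returns ``(ti, p)`` with ``p_i = A* + b* ti_i + eps_i``,
    ``eps_i ~ N(0, noise_sd^2)`` i.i.d.  If every generated graph happens to
    share the same index value (degenerate design), the batch is redrawn with
    a diagnostic, up to ``max_attempts`` times.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_vertices_range
    for attempt in range(max_attempts):
        ti = np.empty(spec.n_molecules, dtype=float)
        for i in range(spec.n_molecules):
            n = int(rng.integers(lo, hi + 1))
            max_extra = n * (n - 1) // 2 - (n - 1)
            extra = int(rng.integers(0, min(spec.max_extra_edges, max_extra) + 1))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            g = random_connected_graph(n, extra, seed=sub_seed)
            ti[i] = compute_index_set(g)[spec.index]
        if np.ptp(ti) > 0:
            break
    else:
        raise RuntimeError(
            f"degenerate index variance after {max_attempts} attempts "
            f"(all {spec.n_molecules} graphs share {spec.index}={ti[0]})"
        )
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n_molecules)
    p = spec.true_intercept + spec.true_slope * ti + eps
    return ti, p
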