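"""The five distance-based topological indices.

For a connected simple graph G with shortest-path distances d(u,v) and detour
distances D(u,v) (longest simple path), summing over unordered pairs u < v:

* Wiener index          W(G)  = sum d(u,v)
* Hyper-Wiener index    WW(G) = sum (d(u,v) + d(u,v)^2) / 2
* Harary index          H(G)  = sum 1 / d(u,v)
* Detour index          D(G)  = sum D(u,v)
* Detour-Harary index   DH(G) = sum 1 / D(u,v)

W, WW and D are exact integers (each hyper-Wiener summand d(d+1)/2 is a
triangular number); H and DH are accumulated in floating point at full
precision and only rounded at output time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_graph import MolecularGraph
from .distance_engine import (
    DetourMatrix,
    DistanceMatrix,
    detour_matrix,
    shortest_path_matrix,
)

__all__ = [
    "IndexSet",
    "INDEX_FIELDS",
    "wiener",
    "hyper_wiener",
    "harary",
    "detour_index",
    "detour_harary",
    "compute_index_set",
]

#: Field order used by every table in this package.
INDEX_FIELDS = ("wiener", "hyper_wiener", "harary", "detour", "detour_harary")


@dataclass(frozen=True)
class IndexSet:
    """The five index values of one molecule."""

    wiener: int
    hyper_wiener: int
    harary: float
    detour: int
    detour_harary: float

    def as_tuple(self) -> tuple:
        return (self.wiener, self.hyper_wiener, self.harary,
                self.detour, self.detour_harary)

    def as_dict(self) -> dict:
        return dict(zip(INDEX_FIELDS, self.as_tuple()))

    def __getitem__(self, key: str):
        return getattr(self, key)


def _upper(values: np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries: one value per unordered pair."""
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    return values[iu]


def wiener(dm: DistanceMatrix) -> int:
    """Sum of shortest-path distances over unordered pairs."""
    return int(_upper(dm.values).sum())


def hyper_wiener(dm: DistanceMatrix) -> int:
    """Sum of (d + d^2)/2 over unordered pairs; exact integer."""
    d = _upper(dm.values)
    return int(((d + d * d) // 2).sum())


def harary(dm: DistanceMatrix) -> float:
    """Sum of reciprocal shortest-path distances over unordered pairs."""
    d = _upper(dm.values)
    return float((1.0 / d).sum())


def detour_index(dtm: DetourMatrix) -> int:
    """Sum of detour distances over unordered pairs."""
    return int(_upper(dtm.values).sum())


def detour_harary(dtm: DetourMatrix) -> float:
    """Sum of reciprocal detour distances over unordered pairs."""
    d = _upper(dtm.values)
    return float((1.0 / d).sum())


def compute_index_set(g: MolecularGraph) -> IndexSet:
    """Compute both matrices once and all five indices from them."""
    dm = shortest_path_matrix(g)
    dtm = detour_matrix(g)
    return IndexSet(
        wiener=wiener(dm),
        hyper_wiener=hyper_wiener(dm),
        harary=harary(dm),
        detour=detour_index(dtm),
        detour_harary=detour_harary(dtm),
    )
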