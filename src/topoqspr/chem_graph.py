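"""Hydrogen-depleted molecular graphs and the packaged drug fixtures.

A molecule is reduced to its heavy-atom skeleton: one vertex per non-hydrogen
atom, one edge per bond regardless of bond order (double, triple and aromatic
bonds all collapse to a single unweighted edge).  All distance-based indices
in this package are defined on that unlabeled simple connected graph, so the
reduction loses nothing they can see.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = [
    "MolecularGraph",
    "DrugFixture",
    "SmilesParseError",
    "GraphValidationError",
    "parse_smiles",
    "parse_adjacency",
    "load_drug_fixtures",
    "DRUG_ORDER",
]

#: Canonical fixture order (alphabetical, as in the shipped property table).
DRUG_ORDER = (
    "Alprazolam", "Amitriptyline", "Amoxapine", "Buspirone", "Clomipramine",
    "Desipramine", "Desvenlafaxine", "Diazepam", "Fluoxetine", "Imipramine",
    "Lorazepam", "Nortriptyline", "Oxazepam", "Protriptyline", "Trimipramine",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when input violates the simple-connected-graph contract."""


@dataclass(frozen=True)
class MolecularGraph:
    """An unweighted, undirected, simple, connected heavy-atom graph.

    Parameters
    ----------
    name:
        Text label (molecule name or input identifier).
    n_vertices:
        Number of heavy atoms.
    edges:
        Unordered vertex-index pairs, stored canonically as ``(min, max)``.
    elements:
        Optional element symbol per vertex, for provenance only; no index
        computed here depends on it.
    """

    name: str
    n_vertices: int
    edges: frozenset[tuple[int, int]]
    elements: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise GraphValidationError(f"{self.name}: empty graph")
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise GraphValidationError(f"{self.name}: self-loop at vertex {a}")
            if not (0 <= a < self.n_vertices and 0 <= b < self.n_vertices):
                raise GraphValidationError(
                    f"{self.name}: edge ({a},{b}) out of range 0..{self.n_vertices - 1}"
                )
            canon.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", frozenset(canon))
        if self.elements is not None and len(self.elements) != self.n_vertices:
            raise GraphValidationError(
                f"{self.name}: {len(self.elements)} element symbols for "
                f"{self.n_vertices} vertices"
            )
        g = self.to_networkx()
        if self.n_vertices > 1 and not nx.is_connected(g):
            frags = sorted(nx.connected_components(g), key=len, reverse=True)
            raise GraphValidationError(
                f"{self.name}: graph is disconnected "
                f"({len(frags)} fragments of sizes {[len(f) for f in frags]})"
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def cyclomatic_number(self) -> int:
        """|E| - |V| + 1: the number of independent cycles (ring count)."""
        return self.n_edges - self.n_vertices + 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def to_adjacency_text(self) -> str:
        """Serialise as one '<i> <j>' line per edge (re-parsable)."""
        lines = [f"# {self.name}: {self.n_vertices} vertices"]
        lines += [f"{a} {b}" for a, b in self.sorted_edges()]
        return "\n".join(lines) + "\n"

    def relabel(self, permutation: Sequence[int]) -> "MolecularGraph":
        """Return the graph with vertex i renamed permutation[i]."""
        if sorted(permutation) != list(range(self.n_vertices)):
            raise GraphValidationError(f"{self.name}: not a permutation")
        edges = frozenset(
            (permutation[a], permutation[b]) for a, b in self.edges
        )
        elements = None
        if self.elements is not None:
            inv = [0] * self.n_vertices
            for i, p in enumerate(permutation):
                inv[p] = i
            elements = tuple(self.elements[inv[i]] for i in range(self.n_vertices))
        return MolecularGraph(self.name, self.n_vertices, edges, elements)


def parse_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Build the hydrogen-depleted graph of a SMILES string.

    Bond order is discarded; the result is the simple graph of heavy atoms.
    Multi-fragment SMILES (dot-disconnected salts, mixtures) are rejected
    because every index here is undefined on a disconnected graph.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"{name or smiles!r}: invalid SMILES")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise GraphValidationError(
            f"{name or smiles!r}: {len(frags)} disconnected fragments "
            f"of sizes {[len(f) for f in frags]}"
        )
    edges = frozenset(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    return MolecularGraph(
        name=name or smiles,
        n_vertices=mol.GetNumAtoms(),
        edges=edges,
        elements=elements,
    )


def parse_adjacency(text_lines: Iterable[str] | str, name: str = "adjacency") -> MolecularGraph:
    """Parse a plain-text edge list: one '<i> <j>' (0-based) per line.

    Blank lines and lines starting with '#' are ignored.  Self-loops and
    duplicate edges are hard errors, as is a disconnected result.
    """
    if isinstance(text_lines, str):
        text_lines = text_lines.splitlines()
    edges: set[tuple[int, int]] = set()
    max_idx = -1
    for lineno, raw in enumerate(text_lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphValidationError(f"{name} line {lineno}: expected 'i j', got {line!r}")
        try:
            a, b = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise GraphValidationError(f"{name} line {lineno}: non-integer index in {line!r}") from exc
        if a < 0 or b < 0:
            raise GraphValidationError(f"{name} line {lineno}: negative vertex index")
        if a == b:
            raise GraphValidationError(f"{name} line {lineno}: self-loop '{a} {a}' forbidden")
        key = (min(a, b), max(a, b))
        if key in edges:
            raise GraphValidationError(f"{name} line {lineno}: duplicate edge {key}")
        edges.add(key)
        max_idx = max(max_idx, a, b)
    if not edges:
        raise GraphValidationError(f"{name}: no edges found")
    return MolecularGraph(name=name, n_vertices=max_idx + 1, edges=frozenset(edges))


@dataclass(frozen=True)
class DrugFixture:
    """One drug of the study set: structure, measured properties, and the
    published index values it is expected to reproduce."""

    name: str
    structure: str  # SMILES
    heavy_atom_count: int
    properties: "PropertyRecord"
    expected_indices: Optional["IndexSet"] = None
    _graph_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def to_graph(self) -> MolecularGraph:
        if "g" not in self._graph_cache:
            g = parse_smiles(self.structure, self.name)
            if g.n_vertices != self.heavy_atom_count:
                raise GraphValidationError(
                    f"{self.name}: SMILES yields {g.n_vertices} heavy atoms, "
                    f"fixture declares {self.heavy_atom_count}"
                )
            self._graph_cache["g"] = g
        return self._graph_cache["g"]


def _data_text(filename: str) -> str:
    try:
        return resources.files("topoqspr.data").joinpath(filename).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise IOError(f"packaged fixture file {filename!r} missing") from exc


def load_drug_fixtures() -> list[DrugFixture]:
    """Load the 15-drug study set in canonical (alphabetical) order.

    Each fixture carries the published physicochemical property row and the
    published index row.  Two published Harary entries and one Detour-Harary
    entry are known misprints (they cannot be produced by any structure
    consistent with the remaining indices); they are shipped as published and
    the discrepancy is surfaced by the analysis, not silently patched.
    """
    from .qspr_stats import PropertyRecord, PROPERTY_FIELDS
    from .topo_indices import IndexSet

    smiles: dict[str, str] = {}
    for line in _data_text("drugs.smi").splitlines():
        if not line.strip():
            continue
        smi, drug = line.split("\t")
        smiles[drug] = smi

    props: dict[str, PropertyRecord] = {}
    for row in csv.DictReader(_data_text("properties.csv").splitlines()):
        props[row["drug"]] = PropertyRecord(
            **{f: float(row[f]) for f in PROPERTY_FIELDS}
        )

    expected: dict[str, IndexSet] = {}
    for row in csv.DictReader(_data_text("expected_indices.csv").splitlines()):
        expected[row["drug"]] = IndexSet(
            wiener=int(row["wiener"]),
            hyper_wiener=int(row["hyper_wiener"]),
            harary=float(row["harary"]),
            detour=int(row["detour"]),
            detour_harary=float(row["detour_harary"]),
        )

    missing = [d for d in DRUG_ORDER if d not in smiles or d not in props or d not in expected]
    if missing:
        raise IOError(f"fixture data incomplete for drugs: {missing}")

    fixtures = []
    for drug in DRUG_ORDER:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles[drug])
        if mol is None:
            raise IOError(f"fixture SMILES for {drug} is corrupt")
        fixtures.append(
            DrugFixture(
                name=drug,
                structure=smiles[drug],
                heavy_atom_count=mol.GetNumAtoms(),
                properties=props[drug],
                expected_indices=expected[drug],
            )
        )
    return fixtures
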