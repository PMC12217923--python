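# topoqspr

Distance-based topological indices and QSPR regression for drug molecular
graphs, built around a 15-drug tricyclic-antidepressant study set.

## The problem

A topological index is a single number computed from a molecule's
hydrogen-depleted graph — heavy atoms as vertices, bonds as edges, bond
order ignored — that is invariant under atom relabeling. Because such
indices correlate with bulk physicochemical behaviour, they are used in
quantitative structure–property relationship (QSPR) modelling to screen
candidate molecules without laboratory measurement.

This package computes five distance-based indices. With `d(u,v)` the
shortest-path distance and `D(u,v)` the *detour* distance (the length of the
longest simple path) between vertices `u` and `v`, summing over unordered
pairs:

| index | definition |
|---|---|
| Wiener `W(G)` | Σ `d(u,v)` |
| hyper-Wiener `WW(G)` | Σ `(d(u,v) + d(u,v)²)/2` |
| Harary `H(G)` | Σ `1/d(u,v)` |
| detour `D(G)` | Σ `D(u,v)` |
| detour-Harary `DH(G)` | Σ `1/D(u,v)` |

The detour matrix is NP-hard in general; here it is computed *exactly* by
decomposing the molecular graph into its biconnected blocks (block-cut
tree) and enumerating simple paths only inside each small block — see
`docs/methods.md`.

Each index is then linked to eight measured properties (boiling point,
melting point, enthalpy of vaporisation, flash point, molar refractivity,
polarizability, surface tension, molar volume) of 15 tricyclic
antidepressants by simple linear regression `P = A + b·TI`, with Pearson r,
R², Fisher's F, its p-value and the standard error of estimate per model.

## Worked example

```python
>>> from topoqspr import parse_smiles, compute_index_set
>>> g = parse_smiles("CNCCCN1c2ccccc2CCc2ccccc21", "desipramine")
>>> g.n_vertices, g.n_edges, g.cyclomatic_number
(20, 22, 3)
>>> compute_index_set(g).as_tuple()
(759, 2282, 68.04837773837773, 2328, 22.578743034993028)
```

Desipramine's 20 heavy atoms form a graph with three rings; its Wiener
index is 759 (total pairwise bond-count separation), its detour index 2328
(the same sum over longest simple paths), and the reciprocal-distance
Harary index is 68.0484 — a compactness measure that grows when atoms sit
close together.

The full study pipeline is driven by the numbered scripts:

```bash
python analysis/01_compute_indices.py    # indices for all 15 drugs + errata scan
python analysis/02_fit_qspr.py           # 40 regression models and summary grids
python analysis/03_validate_synthetic.py # engine/oracle and recovery checks
```

`02_fit_qspr.py` ends with (actual output):

```
21 of 40 models significant at p < 0.05.
Strongest model: molar_refractivity = 61.1895 + 0.0106 * detour  (R^2 = 0.7935, F = 49.9422, SEE = 3.6495)
```

i.e. the detour index explains ~79% of the variance in molar refractivity
across the panel, while melting point and surface tension have no strong
predictor among these indices (max |r| < 0.52).

The same functionality is exposed as a CLI for arbitrary input files:

```bash
topoqspr indices --in drugs.smi --out out/
topoqspr qspr --structures drugs.smi --properties props.csv --out out/
```

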