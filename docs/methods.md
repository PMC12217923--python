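# Methods

## Molecular graphs

A molecule is modelled as its hydrogen-depleted graph: one vertex per heavy
atom, one edge per bond. Bond order, element identity, charge and
stereochemistry are discarded — every index implemented here is a function
of the unlabeled simple connected graph only, and the study drugs that share
a heavy-atom skeleton (amitriptyline/imipramine; desipramine/nortriptyline/
protriptyline, which differ chemically only in where a nitrogen sits or
whether a bond is double) must and do receive identical index values. SMILES
parsing is delegated to RDKit; a plain adjacency-list format (`i j` per
line, `#` comments) is accepted as a structure-free entry point. Disconnected
inputs are rejected: every index below is undefined across fragments.

The 15-drug study set ships as package data: a SMILES file, a property
table (eight properties per drug, units: °C for boiling/melting/flash
point, kJ/mol enthalpy, cm³ molar refractivity and molar volume, 10⁻²⁴ cm³
polarizability, dyne/cm surface tension), and the published index table the
analysis is compared against. The published property table prints one drug
twice and runs its numeric columns together; the shipped CSV resolves the
duplicate (one Alprazolam row kept, the second published index row —
identical to Imipramine's, as the skeleton isomorphism requires —
relabelled Amitriptyline) and the run-on Desipramine row as boiling 407.4 /
melting 25 / enthalpy 65.9 / flash 160.5, the only reading under which the
published regression tables reproduce.

## Distance and detour matrices

Shortest-path distances come from breadth-first search from every source
(unweighted edges), cross-checked in the tests against an independent
Floyd–Warshall oracle.

The detour distance `D(u,v)` — the length of the longest *simple* path —
is NP-hard on arbitrary graphs, but molecular graphs are sparse and their
biconnected blocks are small (a fused-ring system forms one block; chains
and isolated rings are trivial). The engine therefore:

1. decomposes the graph into biconnected components and articulation
   points (block-cut tree);
2. computes, per block, exact all-pairs longest simple paths by
   depth-first enumeration with a visited set (iterative, sentinel-popped);
3. sums within-block detours along the unique block path between the two
   endpoints — a simple path can enter and leave each block only through
   its cut vertices, so detour distances add along the block-cut tree.

For the study drugs (19–28 heavy atoms, ring count ≤ 4, largest block 17
vertices) this is milliseconds per molecule. Enumeration carries a hard
step budget (5×10⁷ per graph) and raises rather than approximate if an
input's blocks are too entangled; nothing in the intended scale
(≤ ~40 vertices, cyclomatic number ≤ ~6) comes near it. A whole-graph
exhaustive DFS oracle (refusing n > 12) provides the independent check in
the tests: on 100 random connected graphs (n ≤ 10, up to 4 chords) the
engine and oracle agree on every entry, and on 200 random trees the detour
matrix equals the distance matrix exactly, as it must when every pair has a
unique simple path.

Both matrices are integer-valued and deterministic; iteration order is
fixed by vertex index.

## Indices

W, WW and D are exact integer sums over the strict upper triangle (each
hyper-Wiener summand `d(d+1)/2` is a triangular number, so integer division
is exact). H and DH are IEEE-double sums of reciprocals, reported at full
precision and formatted to 4 decimals only at output time; comparisons
against 4-decimal published values use |Δ| ≤ 5×10⁻⁵.

## QSPR regression

Each property is regressed on each index by ordinary least squares,
`P = A + b·TI`, with the closed form `b = cov(TI,P)/var(TI)`,
`A = mean(P) − b·mean(TI)`; Pearson r; `R² = r²`;
`F = R²(n−2)/(1−R²)` on (1, n−2) degrees of freedom; the p-value from the
upper F tail (scipy's regularized-incomplete-beta implementation); and
`SEE = sqrt(RSS/(n−2))`. Significance is declared at p < 0.05 with no
multiple-testing correction — each of the 40 models is reported as its own
univariate screen, the convention of small-panel QSPR work; readers should
treat the family-wide error rate accordingly. Normality of the responses is
assumed, not tested. Fits on panels with fewer than 8 molecules carry a
low-power warning; fewer than 3 is an error. A zero-variance predictor
raises a degenerate-fit error for that cell without aborting the rest of
the report.

The reproduction pipeline regresses on the *published* index table
(`index_source="table"`), because the published fits were computed from
that table and inherit its errata (below). For fresh input the CLI and
`index_source="computed"` recompute all predictors from structure, which is
the scientifically preferred route.

## Errata in the published tables

Reproduction surfaced two classes of defect, handled openly rather than
patched:

1. **Index-table cells no structure can produce.** The Harary entries of
   the two isomorphic-skeleton rows (printed 70.1254 and 70.1256 — two
   different values for isomorphic graphs, already impossible) and of
   trimipramine (78.4616), and buspirone's detour-Harary (57.3298).
   Exhaustive search over every side-chain tree and attachment point on the
   tricyclic core shows the unique graph reproducing each row's other four
   indices forces H = 72.7087 (resp. 78.4611) and DH = 57.3198. The
   acceptance tests assert the published values as printed and these four
   cells fail, by design; `analysis/01_compute_indices.py` writes the
   computed corrections.
2. **Regression cells contradicted by their own neighbours.** Four cells
   disagree with values the same publication prints elsewhere for the same
   model: a correlation of 0.5805 beside an R² of 0.3475 (⇒ r = 0.5895), an
   F of 49.8686 beside R² = 0.7899 (⇒ F = 48.8686 by the F–R² identity), a
   slope of 1.9971 in a grid whose model equation prints 1.9791, a p of
   0.1101 beside F = 3.1166 on (1,13) df (⇒ p = 0.1010), and one p printed
   as 1.1989 (impossible; read 0.1989, which matches). The tests assert the
   self-consistent member of each pair, which the pipeline reproduces.

All other published cells — 71/75 index values and every remaining
regression statistic — reproduce to printed precision.

## Synthetic data

The generator emulates drug-like skeletons: a uniform random labeled tree
(Prüfer sequence, so tree shapes are unbiased) on n vertices plus k extra
chords, giving a connected simple graph with cyclomatic number exactly k.
Defaults (n ∈ [12, 30], k ≤ 6) bracket the study drugs (19–28 heavy atoms,
1–4 rings). Property values are drawn from the same linear model the
analysis assumes, `P = A* + b*·TI + ε`, ε ~ N(0, σ²) i.i.d. All randomness
descends from one integer seed via `numpy.random.default_rng`; no global
state.

What the generator does *not* emulate: chemical valence constraints (a
random vertex may exceed degree 4), element labels, and correlated noise
between properties. Passing tests therefore demonstrate correctness of the
graph algorithms and estimator calibration under the assumed linear model —
not that real properties follow that model, which is exactly what the
empirical R² values quantify.

Validation sizes (chosen to keep the default suite under a few minutes on
one core): 200 random trees for the detour≡distance identity, 100 random
cyclic graphs against the exhaustive oracle, closed-form checks on paths
and cycles, OLS against both scipy's linregress and a Nelder–Mead RSS
minimiser, and 1000-replicate parameter recovery on a fixed 50-molecule
design (slope bias within 4 Monte-Carlo standard errors of zero).

## Known limitations

* Detour computation is exact but exponential per block; inputs far outside
  molecular scale fail loudly rather than degrade.
* The regression layer is deliberately univariate simple OLS to mirror the
  study design; no cross-validation, multivariate models or applicability
  domain are provided.
* Element symbols are carried for provenance but unused; heteroatom- or
  bond-order-weighted index variants are out of scope.
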