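# reactnet

Graph-theoretic prediction of reaction paths: enumerate reaction
intermediates as atom-connectivity matrices, prune chemically implausible
species, weigh candidate elementary reactions by chemical distance, and
extract the minimal subnetwork of shortest reactant→product paths.

## Who this is for

Computational chemists who want a *first screening* of possible reaction
mechanisms before spending quantum-chemical effort.  Instead of exploring a
potential energy surface, the method works in a discrete chemical space:

* A state of the system is a symmetric binary **atom-connectivity (AC)
  matrix** `A` over a fixed, ordered atom list; a multi-molecule state is
  block-diagonal, and each block is one molecule.
* One elementary reaction is a symmetric **conversion matrix**
  `C ∈ {−1,0,1}` added to a state: `+1` forms a bond, `−1` breaks one.
  Per step at most 2 formations and 2 dissociations are allowed and at
  most two molecules may react; bonds broken in earlier cycles never
  re-form and newly formed bonds never re-break, which prevents cycling.
* Candidate intermediates are generated breadth-first from the reactant
  matrix **R** until no new state appears.  Permutational isomers are
  collapsed with a spectral canonical key (eigenvalues of a Z-weighted
  Coulomb-like matrix, backed by an exact isomorphism check), and states
  are screened by a bond-order/valence/formal-charge model and a per-molecule
  ring-count bound.  For large molecules, enumeration runs on a designated
  subset of **active atoms** (the reaction centers); all other bonds are
  frozen.
* The **chemical distance** between two states,
  `CD(A,B) = ½ min_P Σ |A − PᵀBP|`, is the minimum number of bond changes
  over all element-preserving atom permutations, solved exactly as a
  mixed-integer linear program.  States far from both reactant **R** and
  product **P** are discarded by the ellipse criterion
  `CD(R,I) + CD(I,P) ≤ CD(R,P) + Δ` with digression factor Δ.
* Surviving states become vertices of a **reaction network** whose edges
  are cap-respecting elementary reactions weighted by CD (in catalytic
  runs, edges must involve a catalyst atom).  Following the principle of
  minimum structure change, for every vertex all equidistant shortest
  R→v→P paths are sampled (Dijkstra + tie enumeration), the top fraction
  by total CD is kept, and the connected R/P-component of the kept edges
  is the **minimal subnetwork** — the small set of mechanisms worth
  refining with electronic-structure methods.

Electronic structure itself is out of scope: a pluggable evaluator contract
accepts energies from any backend, and a crude additive bond-increment
surrogate ships for testing the energy-dependent filters (energy screen
`E ≤ E(R) + E_tol`, endothermicity filter).

## Worked example

The six-atom halogen exchange 2 ICl + H₂ → 2 HCl + I₂ ships as the fixture
`halogen_exchange` (all atoms active):

```sh
$ reactnet run --fixture halogen_exchange
atoms: 6
active_atoms: 6
cycles: 2
intermediates: 4
after_energy: 4
cd_rp: 6
after_ellipse: 4
network_vertices: 4
network_edges: 4
sampled_paths: 2
kept_paths: 2
minimal_vertices: 4
minimal_edges: 4
```

Four states survive the screens (the reactants, I₂+Cl₂+H₂, HI+HCl+ICl, and
the product 2 HCl+I₂), the reactant–product chemical distance is 6 bond
changes, and two four-vertex paths of total CD length 8 tie for rank 1:

```
1  8  ClI.ClI.[H][H] -> II.ClCl.[H][H] -> II.Cl.Cl
2  8  ClI.ClI.[H][H] -> I.Cl.ClI    -> II.Cl.Cl
```

The second is the textbook corridor through HI + HCl + ICl.  (SMILES are
canonical, so HCl prints as `Cl` and HI as `I`.)

The same run is available from Python:

```python
from reactnet import RunConfig, run_pipeline

result = run_pipeline(RunConfig(fixture="halogen_exchange"))
print(result.counts["cd_rp"])          # 6
print(result.ranked_paths[0].length)   # 8
```

Arbitrary systems are given as SMILES (dot-separated molecules) or
SDF/MOL/XYZ files, with 0-based active/catalyst atom indices over the
concatenated reactant atom order:

```sh
reactnet run --reactant "ICl.ICl.[H][H]" --product "Cl.Cl.II" --out results/
```

Two larger fixtures reproduce the study conditions of the published case
studies: `claisen` (ester condensation under ethoxide, charge −1, 7 active
atoms) and `hydroformylation` (HCo(CO)₃ + ethylene + CO + H₂, 8 active
atoms, Co flagged as catalyst).  See `docs/methods.md` for the model
details and the known differences from the published stage counts.

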