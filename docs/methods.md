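# Methods

This note records the model choices behind `reactnet`, the parameters that
matter, and what the shipped fixtures and tests do and do not demonstrate.

## State model and enumeration

A system state is a symmetric 0/1 atom-connectivity (AC) matrix over an
ordered atom list that is fixed for the whole run; molecules are the
connected components.  An elementary step adds a symmetric {−1,0,1}
conversion matrix.  Admissible entries depend on the current state `I` and
the reactant matrix `R`:

| `I_ij` | `R_ij` | allowed `C_ij` | reading                          |
|-------:|-------:|----------------|----------------------------------|
| 0      | 0      | 0 or +1        | a new bond may form              |
| 0      | 1      | 0              | a broken reactant bond stays broken |
| 1      | 1      | 0 or −1        | a surviving reactant bond may break |
| 1      | 0      | 0              | a newly formed bond stays        |

plus two global caps per step: at most `max_form` formations and
`max_break` dissociations (default 2/2), and the changed bonds may touch at
most `molecularity` molecules (default 2) of the state being converted.

These rules are *monotone*: along any trajectory the set of broken reactant
bonds only grows and the set of new bonds only grows.  Two consequences are
worth knowing.  First, enumeration terminates at a finite fixed point
without any cycle bookkeeping.  Second, a designated product whose
mechanism re-breaks a bond formed en route (the halogen-exchange example
does exactly this) may be unreachable by enumeration under strict
plausibility screens; the pipeline therefore always installs the designated
product as a network vertex — it is an input, not a discovery.

Enumeration is breadth-first over exact matrices (byte-level deduplication)
with permutational isomers collapsed by a canonical key: the sorted
eigenvalue spectrum of a Coulomb-like matrix (diagonal `0.5·Z^2.4`,
off-diagonal `A_ij·Z_i·Z_j`, rounded to 1e-6) refined by a neighborhood
invariant, with an exact VF2 isomorphism check on residual collisions.  For
small systems (≤10⁴ within-element permutations) an exact brute-force
canonical form replaces the spectral route outright.  Each species records
the cycle at which it was first reached.

With active atoms flagged, enumeration operates on the active sub-matrix;
bonds touching inactive atoms are frozen and re-inserted on expansion.
Formations that would push an atom beyond its maximum valence (metal:
coordination cap) are pruned during generation — such states could never
pass the valence screen, so this is purely an optimization.

## Plausibility screens

A state survives if an integer bond-order assignment exists:

* per-atom allowed (valence, formal charge) pairs for main-group elements
  (closed shell; e.g. C: 4/0 or 3/±1, O: 2/0, 1/−1, 3/+1, H: 1/0, 0/±1);
* per-atom |charge| ≤ `charge_bound` (default 1);
* total |charge| over the system ≤ |system charge| + 2·`max_extra_ion_pairs`
  (default 0: charge separation beyond the net charge is rejected — no
  spontaneous zwitterions or ion pairs);
* carbon monoxide is recognized as a dative molecule ([C−]≡[O+]) and counts
  as zero charge separation;
* metals bypass the octet model: the metal is capped by
  `metal_max_coordination` (default 6), metal bonds count as single bonds
  toward ligand valences, coordination-sphere atoms may carry any tabulated
  formal charge at no budget cost (metal–ligand bonding is ill-defined),
  and remote atoms obey the normal rules;
* every molecule's cyclomatic number (bonds − atoms + 1) must lie within
  `ring_bounds`.  The reference reactions are ring-free, so the fixtures
  use (0, 0); hydroformylation uses (0, 1) to admit the three-membered
  metal–olefin coordination motif.

The search maximizes satisfied octets, then minimizes total |charge|, with
lexicographic bond orders as the tie-break, and is cached per molecule.
Accepted states are emitted as canonical SMILES via RDKit; molecules whose
bonding defies SMILES are flagged (`!` + formula) and keep their graph
identity.

## Energies

All energy filters speak to one contract: a deterministic callable mapping
a state to a total energy in kcal/mol, additive over molecules.  External
backends attach as subprocess plug-ins (XYZ payload in, one-line energy
out).  The built-in surrogate is an additive bond-increment model: each
bonded element pair contributes a fixed stabilization (e.g. H–H 104,
C–H 99, C–O 95, Co–C 35 kcal/mol), so bond breaking costs and bond making
pays.  It is order-, strain- and electronics-blind; it exists to exercise
the energy screen (`E ≤ E(R) + E_tol`, inclusive, default
`E_tol = 20 kcal/mol`, reactant and product always retained) and the
endothermicity filter, not to rank isomers accurately.  Expect the
surrogate to keep near-isoenergetic bond-shuffle states that a
semiempirical backend would separate.

## Chemical distance

`cd_fixed` counts differing bonds under a fixed atom order; `cd_min`
minimizes over element-preserving permutations via an assignment MILP
(binary p_uv, doubly stochastic constraints, linearized edge-match
variables, HiGHS backend, per-pair time limit 10 s with a flagged
best-feasible fallback).  Identity is exact: CD = 0 iff the states are
permutationally isomorphic.  An edge-type counting bound gives a cheap
certificate; most pairs resolve without the solver.

Within the pipeline, distances default to the **active-atom basis**: all
bond changes live there by construction, the small basis keeps the MILP
exact and instantaneous, and permuting frozen spectator atoms cannot
change which bonds react.  The all-atom minimization — never larger than the
active-basis value, since it optimizes over a superset of permutations —
is available with `cd_basis="all"`; with ~20 interchangeable hydrogens it
routinely needs seconds per pair or hits the time limit, which is why it
is not the default.

The ellipse criterion keeps states with `CD(R,I) + CD(I,P) ≤ CD(R,P) + Δ`
(inclusive; Δ ≥ 0, default 6; both foci always kept).  It can optionally
run during enumeration (`inflight_ellipse`).

## Network and paths

Vertices are the surviving states; an edge joins two states when the
CD-optimal mapping changes ≤ `max_form` formations and ≤ `max_break`
dissociations (equivalently, matched bonds ≥ max(|E_u|,|E_v|) − 2), the
changed bonds touch ≤ 2 molecules of at least one endpoint, and — when
catalyst atoms are flagged — some changed bond touches a catalyst atom.
Edge weight = minimized CD.

For every vertex v, all equidistant shortest loopless R→v→P paths are
collected by composing the two shortest-path DAGs depth-first with a
visited-set check.  When every composition clashes, the exact minimal
loopless length through v comes from a min-cost flow (node-split graph,
two internally disjoint legs), and ties at that length from a bounded
best-first search.  Tie classes in highly degenerate networks are
truncated deterministically at `max_ties_per_vertex` (default 1000) with a
warning; all reported path counts are then a deterministic sample.  A
`yen_k > 1` option extends sampling to the k shortest distinct lengths per
vertex via Yen's algorithm.

Distinct sampled paths are ranked by total CD (ties lexicographic); the
shortest ⌈q·n⌉ are kept (`top_q`, default 0.5), with ties at the cutoff
retained and tied lengths sharing a percentile.  The minimal subnetwork is
the R/P-containing component of the kept-path edges.  Downstream hooks for
refinement: edge-frequency prioritization (most-traversed edges first),
`remove_edge_and_paths` for edges whose computed barriers disqualify them,
and `kinetic_filter` (drop vertices above `E(R) + E_tol`, drop edges whose
uphill ΔE away from R — by hop distance, higher-energy endpoint when
equidistant — exceeds `endo_threshold`, then drop isolated vertices,
keeping R and P).

## Fixtures and what the tests show

`halogen_exchange` (2 ICl + H₂ → 2 HCl + I₂, 6 atoms) is small enough that
every operation is validated against brute-force oracles: exhaustive
conversion enumeration, exhaustive reachability, exhaustive permutation CD,
and exhaustive simple-path enumeration.

`claisen` encodes two ethyl acetate molecules plus ethoxide (charge −1).
The active set is the package's reconstruction of the reaction centers —
the seven atoms that change bonds or carry charge in the accepted
mechanism (α-H, α-C and carbonyl O of the enolized ester; carbonyl C,
carbonyl O and ester O of the attacked ester; ethoxide O).  At the
literature settings it yields 84 intermediates and the textbook
deprotonation → C–C attack → ethoxide expulsion sequence is sampled at the
minimal CD length (rank-1 tie class, percentile < 1%).

`hydroformylation` encodes HCo(CO)₃ + C₂H₄ + CO + H₂ with eight active
atoms (hydride, Co, both olefin carbons, the incoming CO, both H₂ atoms)
and Co as the catalyst atom; it yields 292 intermediates, and the
Heck–Breslow cycle's CD length sits at the ~20th percentile of all sampled
paths.

The published stage counts for these two systems (113/239 intermediates,
and the energy-chained network/path sizes) are stored on the fixtures as
advisory regression numbers (enforced only under `--strict`).  They are
not reproduced exactly here: the original active-atom assignments are
figure-only information, the published energy screens used PM6/CPCM and
DFTB rather than the surrogate, and this implementation's screens are its
own concretization of "inappropriate valence/formal charge/ring count".
Matching the printed counts therefore shows agreement of scale, not
identity; everything downstream of a *fixed* state list (distances,
admissibility, sampling, ranking, extraction) is exact and
oracle-validated.

## Numerical and determinism notes

Spectra are rounded to 1e-6 before keying; collisions fall back to exact
isomorphism.  All iteration orders are sorted (atom order, lexicographic
bond pairs, canonical-key order), so runs are byte-identical without
seeds.  The MILP time limit and the tie cap are the only truncation
points; both are flagged in results (`status="fallback"/"time_limit"`,
truncation warnings).  Degenerate inputs: empty atom lists, non-square or
non-binary matrices, element-multiset mismatches, missing endpoints, and
missing energies all raise with named causes rather than propagating.

## Known limitations

* No conformers, stereoisomers, or electronic states: one AC matrix is one
  vertex.
* The monotone conversion rules bound how far enumeration can wander; with
  tight screens some literature mechanisms' own products are reachable
  only as designated inputs (see above).
* The surrogate energy model is qualitative; quantitative screening needs
  an attached backend.
* Tie truncation makes path *counts* on highly degenerate networks
  cap-dependent, though path lengths, ranking and the mechanism corridors
  are unaffected.
* Termolecular steps and bond-order-resolved states (bond-electron
  matrices) are intentionally out of scope.
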