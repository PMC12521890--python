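# Methods

## The problem

Generative models for 3D molecules are routinely scored by whether their raw
output respects elementary chemistry: does every atom have a plausible
valency, is the molecule one connected piece, and does its geometry sit near
a minimum of the potential that produced the training data?  Two widespread
defects corrupt these scores.  First, valency bookkeeping around aromatic
bonds: a historical implementation counted every aromatic bond as
contributing 1 to valency (instead of 1.5), and — worse — the same buggy
count was used to *build* the reference lookup table, baking chemically
impossible entries (neutral carbon with valency 3, neutral nitrogen with
valency 2) into the definition of "stable".  Second, geometry benchmarks
scored with a classical force field (MMFF94) when the reference conformers
were produced with a semi-empirical method (GFN2-xTB); the two potentials
disagree by more than the differences between models.  This package
implements the corrected evaluation stack.

## Valency model

Valency is the sum of bond orders of an atom's covalent bonds; hydrogens
are explicit atoms and contribute 1 each.  Three counting modes exist:

- **kekulized** (the exact definition): aromatic bonds are resolved into an
  alternating single/double assignment and integer orders are summed.  The
  per-atom sum is invariant to which kekulé structure is chosen (tested
  against an exhaustive enumerator); a molecule with no valid assignment is
  *non-kekulizable* and counts as fully unstable and invalid — skipping it
  would inflate scores.
- **1.5-aromatic**: each aromatic bond contributes 3/2.  Correct on isolated
  rings, wrong at ring fusions (a triphenylene fusion carbon gets 9/2).
  Values are exact rationals and are compared to table entries without
  rounding: 9/2 never passes as 4.
- **legacy 1.0-aromatic**: the historical bug, shipped only to reproduce
  published numbers, and gated behind an explicit `--legacy` flag in the
  CLI.

The aromatic tuple `(n_arom, v_other)` — the count of incident aromatic
bonds and the total order of the remaining bonds — describes an atom's
environment without kekulizing and without a per-bond weight; it is the
basis of the aromatic-aware reference table.

Kekulization is delegated to RDKit; when RDKit declines for bookkeeping
reasons, a backtracking assigner over the aromatic subgraph is the fallback
for systems of ≤ 16 aromatic atoms.  The fallback requires every aromatic
atom to carry at least two aromatic bonds: a lone "aromatic" bond dangling
off an atom (seen in malformed raw output) is not a kekulizable motif even
when a bond-order assignment would satisfy valences on paper.

## Reference tables

Three references ship with the package (`load_shipped_table`):

- **corrected** — allowed valencies by (element, formal charge), from the
  curated dataset; e.g. (C, 0) → {4}, (S, 0) → {2, 3, 6}.
- **legacy** — the historical table verbatim, implausible entries included
  (e.g. (C, 0) → {3, 4}, (H, ±1) → {0}) and entries missing from historical
  tables excluded.  Needed to reproduce previously published stability
  values, and for nothing else.
- **aromatic** — allowed `v_other` by (element, n_arom, formal charge);
  e.g. (C, 2, 0) → {1, 2} and (C, 3, 0) → {0}, which classifies both the rim
  and fusion carbons of polycyclic aromatics correctly.

The aromatic table restricted to `n_arom = 0` agrees with the corrected
simple table on every shared key; the one discrepancy — (O, −1) appears
only in the simple table — ships verbatim and is surfaced by
`aromatic_consistency_report` rather than silently reconciled.

Tables are plain JSON (`"element|charge"` or `"element|n_arom|charge"` keys,
sorted integer arrays), so diffs between any two references are reviewable
line by line.  `build_simple_table` / `build_aromatic_table` construct the
same structures from any dataset: an entry is exactly an observed
configuration, with no frequency weighting (stability is set membership).
Tables store integers by contract.  A consequence worth stating: under the
1.5-aromatic mode a dataset containing ring fusions cannot be
self-consistent against its own table, because fusion atoms observe the
non-integer valency 9/2 — this is precisely the failure of the 1.5
approximation, not a table defect.  Under kekulized counting and under the
aromatic-tuple representation, self-consistency holds universally (tested).

## Metrics

- **Atom stability (AS)**: fraction of atoms whose valency (or aromatic
  tuple) appears in the reference table.  Missing key ⇒ unstable.
- **Molecule stability (MS)**: fraction of molecules with all atoms stable;
  MS ≤ AS by construction.
- **V&C (valid & connected)**: fraction of molecules that sanitize *without
  modification* and form a single connected component.  The toolkit will
  happily "fix" a three-bond neutral carbon by granting it an implicit
  hydrogen; any such adjustment counts as failure here, because the object
  under evaluation is the raw generated molecule.

Uncertainty uses the split protocol: the collection is permuted with a
seeded generator and chunked into disjoint splits (default 5 × 1000 out of
5000 — the published evaluation size), and the metric's mean ± sample
standard deviation (ddof = 1) across splits is reported.  Whether published
± values are std or stderr is not stated anywhere authoritative; this
package reports std and labels it as such.  The seed defaults to 0 and is
echoed into every report.

## Curation pipeline

`curate` = fragment filter → kekulize → flag, in that order (the fragment
filter must run first because fragmented records are what corrupt the
valency table).  Fragmented molecules — the signature of a failed
semi-empirical geometry optimization — are removed outright, never repaired
by largest-fragment selection.  Flags mark the known failure signatures:
hydrogen with no covalent bonds, neutral carbon with valency 2, and any
configuration absent from the corrected reference.  The pipeline preserves
atom/bond content exactly except aromatic → kekulé orders, is idempotent,
and reports counts so the removed fraction is auditable.  The removal
fraction a given corpus produces is a property of that corpus; on the
original full dataset it was reported as 0.18%, which requires the external
download to reproduce.

## Geometry/energy benchmark

For each molecule, an optimizer backend produces a conformer pair (initial
and relaxed coordinates plus energies, kcal/mol).  Deviations are measured
over the topology's internal coordinates:

    Δr    = |r_init − r_opt|                      bonds, Å
    Δθ    = min(|Δ|, 180° − |Δ|)                  angles, degrees, ∈ [0, 90]
    Δφ    = min(|Δ|, 360° − |Δ|)                  torsions, degrees, ∈ [0, 180]
    ΔE_relax = E_init − E_opt                     kcal/mol, signed

Aggregation pools each deviation class over all internal coordinates of all
molecules in a split, then averages; per-molecule values are retained for
transparency.  ΔE_relax is reported as mean and median; negative values
(the optimizer ended uphill) are convergence anomalies — counted and
flagged, never clipped.  Degenerate internal coordinates (coincident atoms,
collinear arms) are excluded from averages and counted.  More than 10%
backend failures voids a benchmark run.  The `valid_only` filter is the
V&C criterion above.

Backends: GFN2-xTB via the external `xtb` executable (XYZ interchange,
net charge from formal charges, singlet multiplicity, normal optimization
level; Hartree × 627.509474 → kcal/mol at the boundary — the only place the
constant appears); MMFF94 via RDKit, suitable only as a coarse filter; an
identity backend for dry runs; and a harmonic backend
(E = ½k Σ‖x − x_ref‖², default k = 1 kcal/mol/Å²) that returns its
reference coordinates exactly, used for closed-form tests.

## Synthetic fixtures

The generator produces everything the tests need, offline and bit-stable
under a fixed spec+seed:

- a toy library (benzene, pyridine, pyrrole, imidazole, naphthalene,
  triphenylene — each in aromatic-typed and kekulized representations —
  plus methane, ethane, water, ammonia) with idealized planar/tetrahedral
  geometries from an embedded builder;
- the five failure-mode molecules (three-single-bond C, two-single-bond N,
  N⁺ with triple+aromatic bonds, a fragmented record with isolated H⁺, a
  valency-2 carbene);
- fragmented-but-well-valenced records (two waters; benzene + methane);
- H–Sₙ–H zigzag chains whose interior atoms all have degree 2, so injected
  perturbations are exactly recoverable;
- mixed corpora with exact category counts and ground-truth labels in
  provenance (defaults: 5000 molecules — the published evaluation size —
  with 10% valency-defect and 2% fragmented records, the order of failure
  rates contemporary models exhibit).

Perturbed conformer pairs stretch every non-ring bond (rigid-branch
translation along the bond axis), bend every degree-2-centered angle
(in-plane branch rotation), and twist every rotatable central bond (branch
rotation about the bond axis).  On acyclic topologies each class is exactly
independent; torsion twists leave bonds and angles untouched, bond
stretches leave everything else untouched.  Angle bends and torsion twists
interact when combined on non-planar chains, so the exact-recovery tests
inject one class at a time (on the planar default chains the interaction
vanishes anyway).  Ring bonds and crowded centers are skipped and recorded
in provenance.

What the fixtures do *not* emulate: drug-like scale and element diversity,
conformer-ensemble energetics, or the geometric noise distribution of a
trained model.  Passing tests therefore demonstrate the correctness of the
metric machinery — counting, lookup, aggregation, recovery of known signals
— not model-quality conclusions about real generated sets.

## Numerical choices and limitations

- Valencies are `fractions.Fraction`; all table comparisons are exact.
- Coordinates are Å throughout; angle math uses atan2-based dihedrals with
  a 1e-6 degeneracy guard.
- Kekulé backtracking is capped at 16 aromatic atoms per system (fallback
  only; RDKit handles larger systems).
- SDF I/O is V2000 (V3000 automatically above 999 atoms), coordinates
  round-trip to 4 decimals, aromatic bonds as type 4, charges via `M  CHG`.
- Stereochemistry, tautomers, radicals and 2D depiction are out of scope;
  an atom whose configuration is absent from the reference table is
  unstable, with no explicit radical model.
- The full-scale numbers that require the original dataset and an xtb
  installation (the 0.18% removal fraction, the MMFF→GFN2-xTB baseline
  deviations) are reachable through the same entry points (`curate`,
  `benchmark` with `XTBBackend`) but are not reproduced by the offline test
  suite.
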