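# moleval

Chemically exact evaluation for 3D molecular generative models: stability
metrics with aromatic-aware valency tables, a dataset-curation pipeline, and
a geometry/energy benchmark consistent with the reference level of theory.

## Why

The standard way to score a 3D molecule generator is to check, on its *raw*
output, that every atom's valency — the sum of its bond orders, explicit
hydrogens included — appears in a lookup table of configurations observed in
the training data (atom stability AS / molecule stability MS), that the
molecule sanitizes and is one connected component (V&C), and that its
geometry sits near a minimum of the training potential.  In practice these
scores have been inflated by three defects:

1. a counting bug that let each aromatic bond contribute 1 (instead of 1.5)
   to valency, and a lookup table *built with the same bug*, which admits
   impossible entries such as neutral carbon with valency 3;
2. the 1.5-per-aromatic-bond approximation itself, which breaks at ring
   fusions — a triphenylene fusion carbon has three aromatic bonds and
   would get valency 4.5;
3. geometry scoring with MMFF94 when the reference conformers were
   optimized with GFN2-xTB, a disagreement larger than the differences
   between models.

`moleval` implements the corrections: exact kekulized valency counting with
rational arithmetic (4.5 never rounds to 4); the aromatic-tuple descriptor
`(n_arom, v_other)` — number of aromatic bonds, total order of the other
bonds — with its aromatic-aware reference table, under which both the
`(2, 1)` rim and `(3, 0)` fusion carbons of polycyclic aromatics classify
correctly; shipped corrected/legacy/aromatic reference tables; a curation
pipeline that removes fragmented records before tables are built; and an
internal-coordinate deviation benchmark (Δr = |r_init − r_opt|,
Δθ = min(|Δ|, 180°−|Δ|), Δφ = min(|Δ|, 360°−|Δ|), ΔE_relax = E_init − E_opt)
against pluggable optimizer backends (GFN2-xTB via the `xtb` executable,
MMFF94, analytic test backends).

## Worked example

```python
from moleval import (ValencyMode, atom_valency, aromatic_tuple,
                     classify_atom, load_shipped_table,
                     molecule_aromatic_tuples, toy_molecule_set)

mols = toy_molecule_set()
benzene = next(m for m in mols if m.name == "benzene/aromatic")
tri = next(m for m in mols if m.name == "triphenylene/aromatic")

print(atom_valency(benzene, 0, ValencyMode.AROM_1_5).value)   # 4
print(aromatic_tuple(benzene, 0))                   # AromaticTuple(n_arom=2, v_other=1)

fusion = next(i for i, t in enumerate(molecule_aromatic_tuples(tri))
              if t.n_arom == 3)
corrected = load_shipped_table("corrected")
aromatic = load_shipped_table("aromatic")
print(classify_atom(tri, fusion, corrected, ValencyMode.AROM_1_5)[0])  # False
print(classify_atom(tri, fusion, aromatic)[0])                         # True
```

A benzene carbon gets valency 4 under the 1.5 rule and tuple `(2, 1)`; a
triphenylene fusion carbon is *misclassified* by the 1.5 rule against the
simple table (valency 9/2) but stable under the aromatic-tuple table
(`(C, 3, 0) → {0}`).

Running `python examples/stability_metrics.py` on a 5000-molecule synthetic
corpus with 8% injected valency defects and 2% fragmented records prints:

```
corrected table, kekulized valency:
  MS = 0.920 ± 0.009
aromatic-tuple table:
  MS = 0.920 ± 0.009
legacy table, legacy 1.0-aromatic counting (historical bug):
  MS = 0.984 ± 0.005

V&C = 0.900 ± 0.010
```

The corrected metrics recover exactly the injected defect rate (1 − 0.08),
the legacy pairing overstates stability, and V&C additionally penalizes the
fragmented records.  The other scripts in `examples/` walk through table
construction and curation (`curate_dataset.py`), the triphenylene argument
(`aromatic_tuples.py`), and the geometry benchmark with exact
injected-deviation recovery (`geometry_benchmark.py`).

## Command line

```sh
moleval curate       --input raw.sdf --output curated.sdf --report report.json
moleval build-tables --input curated.sdf --out-simple t.json --out-aromatic a.json
moleval stability    --input generated.sdf --table corrected --splits 5 --split-size 1000
moleval geometry     --input generated.sdf --backend gfn2-xtb --valid-only
```

Exit codes: 0 success, 1 metric undefined (empty input), 2 I/O or
configuration error.  The flawed legacy table/mode exists to reproduce
historical numbers and demands an explicit `--legacy` acknowledgment.

## Layout

- `src/moleval/` — `graph` (molecular graph, kekulization, sanitization
  verdict), `io` (SDF/SMILES/XYZ), `valency`, `tables`, `metrics`,
  `curation`, `geometry`, `backends`, `fixtures` (synthetic data),
  `cli`/`reports`.
- `docs/methods.md` — the model, conventions, numerical choices and
  limitations.
- `examples/` — one narrative script per capability.
- `tests/` — pytest suite, including an independent exhaustive kekulé
  enumerator used as the oracle for valency invariance.
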