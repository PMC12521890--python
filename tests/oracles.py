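"""Independent test oracles, deliberately naive.

The kekulé enumerator here exhaustively tries every single/double
assignment over a molecule's aromatic bonds against a tiny hand-written
valence map.  It shares no code with the package's kekulization (which goes
through the cheminformatics toolkit with a backtracking fallback), so the
two can disagree only if one of them is wrong.
"""

from __future__ import annotations

import itertools

from moleval.graph import BondOrder, MoleculeGraph

# default valences for the elements appearing in the oracle corpus
ORACLE_VALENCES = {
    ("H", 0): {1},
    ("C", 0): {4},
    ("C", -1): {3},
    ("C", 1): {3},
    ("N", 0): {3},
    ("N", 1): {4},
    ("N", -1): {2},
    ("O", 0): {2},
    ("O", 1): {3},
    ("S", 0): {2},
}


def enumerate_kekule_assignments(mol: MoleculeGraph) -> list[dict[int, int]]:
    """Every assignment {aromatic bond index -> 1 or 2} under which all
    atoms touching an aromatic bond reach an allowed total valency."""
    arom = [k for k, b in enumerate(mol.bonds)
            if b.order is BondOrder.AROMATIC]
    touched = sorted({x for k in arom
                      for x in (mol.bonds[k].i, mol.bonds[k].j)})
    base = {}
    for a in touched:
        total = 0
        for b in mol.incident_bonds(a):
            if b.order is not BondOrder.AROMATIC:
                total += b.order.numeric
        base[a] = total
    out = []
    for combo in itertools.product((1, 2), repeat=len(arom)):
        sums = dict(base)
        for k, order in zip(arom, combo):
            sums[mol.bonds[k].i] += order
            sums[mol.bonds[k].j] += order
        ok = all(
            sums[a] in ORACLE_VALENCES[
                (mol.atoms[a].element, mol.atoms[a].formal_charge)]
            for a in touched)
        if ok:
            out.append(dict(zip(arom, combo)))
    return out


def atom_order_sums(mol: MoleculeGraph, assignment: dict[int, int]) -> list[int]:
    """Per-atom total bond order under one enumerated assignment."""
    sums = [0] * mol.n_atoms
    for k, b in enumerate(mol.bonds):
        order = assignment[k] if k in assignment else b.order.numeric
        sums[b.i] += order
        sums[b.j] += order
    return sums
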