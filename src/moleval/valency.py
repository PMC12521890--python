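"""Per-atom valency under the three counting modes, and the aromatic tuple.

Valency is the sum of bond orders of an atom's covalent bonds (explicit
hydrogens each contribute 1).  For molecules without aromatic bonds all
modes agree.  With aromatic bonds:

``KEKULIZED``
    Integer bond orders taken from the molecule's kekulized form — the
    chemically exact definition.  Requires kekulization to succeed.
``AROM_1_5``
    Each aromatic bond contributes 3/2.  Correct for isolated rings
    (benzene carbon → 4) but wrong at ring fusions (a triphenylene fusion
    carbon gets 9/2), so values are kept as exact rationals and never
    rounded: 9/2 must not compare equal to 4.
``AROM_1_LEGACY``
    Each aromatic bond contributes 1 — a historical implementation bug,
    shipped solely to reproduce published numbers.

The aromatic tuple ``(n_arom, v_other)`` sidesteps the ambiguity entirely:
count the aromatic bonds, sum the rest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .graph import BondOrder, KekulizationError, MoleculeGraph, kekulize

__all__ = [
    "ValencyMode",
    "AtomValency",
    "AromaticTuple",
    "atom_valency",
    "molecule_valencies",
    "aromatic_tuple",
    "molecule_aromatic_tuples",
]


class ValencyMode(enum.Enum):
    KEKULIZED = "kekulized"
    AROM_1_5 = "arom_1_5"
    AROM_1_LEGACY = "arom_1_legacy"


_AROMATIC_CONTRIB = {
    ValencyMode.AROM_1_5: Fraction(3, 2),
    ValencyMode.AROM_1_LEGACY: Fraction(1),
}


@dataclass(frozen=True)
class AtomValency:
    atom_index: int
    value: Fraction

    @property
    def is_integer(self) -> bool:
        return self.value.denominator == 1


@dataclass(frozen=True)
class AromaticTuple:
    """(number of incident aromatic bonds, total non-aromatic bond order)."""

    n_arom: int
    v_other: int


def _sum_orders(mol: MoleculeGraph, atom_index: int,
                aromatic_contrib: Optional[Fraction]) -> Fraction:
    total = Fraction(0)
    for b in mol.incident_bonds(atom_index):
        if b.order is BondOrder.AROMATIC:
            if aromatic_contrib is None:
                raise ValueError("aromatic bond encountered in kekulized graph")
            total += aromatic_contrib
        else:
            total += b.order.numeric
    return total


def molecule_valencies(mol: MoleculeGraph, mode: ValencyMode) -> list[AtomValency]:
    """Valency of every atom, in atom order.

    Under ``KEKULIZED`` a single kekulization is computed and shared across
    atoms (the per-atom sum is invariant to the kekulé structure chosen);
    :class:`KekulizationError` propagates and callers map it to "unstable".
    """
    if mode is ValencyMode.KEKULIZED:
        kmol = kekulize(mol)
        return [AtomValency(i, _sum_orders(kmol, i, None))
                for i in range(kmol.n_atoms)]
    contrib = _AROMATIC_CONTRIB[mode]
    return [AtomValency(i, _sum_orders(mol, i, contrib))
            for i in range(mol.n_atoms)]


def atom_valency(mol: MoleculeGraph, atom_index: int,
                 mode: ValencyMode) -> AtomValency:
    if not 0 <= atom_index < mol.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    if mode is ValencyMode.KEKULIZED:
        kmol = kekulize(mol)
        return AtomValency(atom_index, _sum_orders(kmol, atom_index, None))
    return AtomValency(atom_index,
                       _sum_orders(mol, atom_index, _AROMATIC_CONTRIB[mode]))


def aromatic_tuple(mol: MoleculeGraph, atom_index: int) -> AromaticTuple:
    """Aromatic tuple for one atom, on the graph as given (no kekulization).

    For atoms with no aromatic bonds, ``v_other`` equals the kekulized
    valency.  Aromatic bonds outside rings (malformed raw output) are still
    counted in ``n_arom``; the table lookup then fails naturally.
    """
    if not 0 <= atom_index < mol.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    n_arom = 0
    v_other = 0
    for b in mol.incident_bonds(atom_index):
        if b.order is BondOrder.AROMATIC:
            n_arom += 1
        else:
            v_other += b.order.numeric
    return AromaticTuple(n_arom, v_other)


def molecule_aromatic_tuples(mol: MoleculeGraph) -> list[AromaticTuple]:
    return [aromatic_tuple(mol, i) for i in range(mol.n_atoms)]
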