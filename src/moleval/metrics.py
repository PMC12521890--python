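"""Stability and validity metrics over molecule collections.

Atom stability (AS): fraction of atoms whose valency — or aromatic tuple —
appears in a reference lookup table.  Molecule stability (MS): fraction of
molecules where *all* atoms are stable, hence MS ≤ AS always.  Validity &
connectedness (V&C): fraction of molecules that pass sanitization (without
the sanitizer altering them) and form a single connected component.

A molecule that cannot be kekulized counts as fully unstable and invalid —
skipping it would inflate the very scores these metrics exist to deflate.

`evaluate_with_splits` implements the split protocol used for uncertainty:
disjoint random splits (default 5 × 1000 out of 5000 generated molecules),
reporting mean ± sample standard deviation across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .graph import (KekulizationError, MoleculeGraph, connected_components,
                    sanitize_check)
from .tables import AromaticValencyTable, ValencyTable
from .valency import ValencyMode, aromatic_tuple, molecule_valencies

__all__ = [
    "UnstableReason",
    "StabilityVerdict",
    "MetricReport",
    "UndefinedMetricError",
    "classify_atom",
    "classify_molecule",
    "stability_verdicts",
    "molecule_stability",
    "validity_and_connected",
    "evaluate_with_splits",
]

AnyTable = Union[ValencyTable, AromaticValencyTable]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested over an empty collection."""


@dataclass(frozen=True)
class UnstableReason:
    atom_index: int
    element: str
    formal_charge: int
    observed: str  # valency or tuple, rendered
    detail: str = ""


@dataclass
class StabilityVerdict:
    atom_flags: list[bool]
    reasons: list[UnstableReason] = field(default_factory=list)

    @property
    def molecule_stable(self) -> bool:
        return all(self.atom_flags)

    @property
    def n_stable_atoms(self) -> int:
        return sum(self.atom_flags)


@dataclass
class MetricReport:
    name: str
    value: float
    uncertainty: Optional[float] = None  # std across splits, if split protocol used
    n_molecules: int = 0
    n_splits: Optional[int] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.name,
            "value": self.value,
            "std": self.uncertainty,
            "n_molecules": self.n_molecules,
            "n_splits": self.n_splits,
            "config": self.config,
        }


def _classify_simple(mol: MoleculeGraph, table: ValencyTable,
                     mode: ValencyMode) -> StabilityVerdict:
    try:
        valencies = molecule_valencies(mol, mode)
    except KekulizationError as exc:
        reasons = [UnstableReason(i, a.element, a.formal_charge, "n/a",
                                  f"non-kekulizable: {exc}")
                   for i, a in enumerate(mol.atoms)]
        return StabilityVerdict([False] * mol.n_atoms, reasons)
    flags, reasons = [], []
    for atom, av in zip(mol.atoms, valencies):
        ok = table.permits(atom.element, atom.formal_charge, av.value)
        flags.append(ok)
        if not ok:
            reasons.append(UnstableReason(
                av.atom_index, atom.element, atom.formal_charge,
                str(av.value), "valency not in allowed set"))
    return StabilityVerdict(flags, reasons)


def _classify_aromatic(mol: MoleculeGraph,
                       table: AromaticValencyTable) -> StabilityVerdict:
    flags, reasons = [], []
    for i, atom in enumerate(mol.atoms):
        t = aromatic_tuple(mol, i)
        ok = table.permits(atom.element, t.n_arom, atom.formal_charge,
                           t.v_other)
        flags.append(ok)
        if not ok:
            reasons.append(UnstableReason(
                i, atom.element, atom.formal_charge,
                f"({t.n_arom}, {t.v_other})", "tuple not in allowed set"))
    return StabilityVerdict(flags, reasons)


def classify_molecule(mol: MoleculeGraph, table: AnyTable,
                      mode: ValencyMode = ValencyMode.KEKULIZED
                      ) -> StabilityVerdict:
    """Per-atom stable/unstable flags for one molecule.

    With a simple :class:`ValencyTable` the valency is computed under
    ``mode`` (one shared kekulization per molecule under KEKULIZED, with
    kekulization failure rendering every atom unstable).  With an
    :class:`AromaticValencyTable` the aromatic-tuple lookup is used and
    ``mode`` is irrelevant.  A missing key means unstable.
    """
    if isinstance(table, AromaticValencyTable):
        return _classify_aromatic(mol, table)
    return _classify_simple(mol, table, mode)


def classify_atom(mol: MoleculeGraph, atom_index: int, table: AnyTable,
                  mode: ValencyMode = ValencyMode.KEKULIZED
                  ) -> tuple[bool, Optional[UnstableReason]]:
    """Stable flag (and reason when unstable) for a single atom."""
    verdict = classify_molecule(mol, table, mode)
    if verdict.atom_flags[atom_index]:
        return True, None
    reason = next(r for r in verdict.reasons if r.atom_index == atom_index)
    return False, reason


def stability_verdicts(mols: Sequence[MoleculeGraph], table: AnyTable,
                       mode: ValencyMode = ValencyMode.KEKULIZED
                       ) -> list[StabilityVerdict]:
    return [classify_molecule(m, table, mode) for m in mols]


def _config(table: AnyTable, mode: Optional[ValencyMode]) -> dict:
    cfg = {"table": table.label, "table_kind": table.kind}
    if mode is not None and table.kind == "simple":
        cfg["mode"] = mode.value
    return cfg


def molecule_stability(mols: Sequence[MoleculeGraph], table: AnyTable,
                       mode: ValencyMode = ValencyMode.KEKULIZED
                       ) -> tuple[MetricReport, MetricReport]:
    """Molecule stability (MS) and atom stability (AS) over a collection.

    Returns ``(ms_report, as_report)``.  Per-molecule verdicts are
    retrievable via :func:`stability_verdicts`.
    """
    if len(mols) == 0:
        raise UndefinedMetricError("stability undefined on an empty collection")
    verdicts = stability_verdicts(mols, table, mode)
    n_stable_mols = sum(v.molecule_stable for v in verdicts)
    n_atoms = sum(len(v.atom_flags) for v in verdicts)
    n_stable_atoms = sum(v.n_stable_atoms for v in verdicts)
    cfg = _config(table, mode)
    ms = MetricReport("molecule_stability", n_stable_mols / len(mols),
                      n_molecules=len(mols), config=cfg)
    as_ = MetricReport("atom_stability",
                       n_stable_atoms / n_atoms if n_atoms else 0.0,
                       n_molecules=len(mols), config=cfg)
    return ms, as_


def is_valid_and_connected(mol: MoleculeGraph) -> bool:
    return bool(sanitize_check(mol)) and len(connected_components(mol)) == 1


def validity_and_connected(mols: Sequence[MoleculeGraph]) -> MetricReport:
    """V&C: fraction of molecules that are chemically valid (sanitization
    without sanitizer modification) and a single connected component."""
    if len(mols) == 0:
        raise UndefinedMetricError("V&C undefined on an empty collection")
    n_ok = sum(is_valid_and_connected(m) for m in mols)
    return MetricReport("validity_and_connected", n_ok / len(mols),
                        n_molecules=len(mols))


def evaluate_with_splits(mols: Sequence[MoleculeGraph],
                         metric: Callable[[Sequence[MoleculeGraph]], float],
                         n_splits: int = 5, split_size: int = 1000,
                         seed: int = 0) -> MetricReport:
    """Mean ± sample std of ``metric`` over disjoint random splits.

    Molecules are permuted with a seeded generator and the first
    ``n_splits × split_size`` are chunked into disjoint splits (uniform
    without replacement).  The reported uncertainty is the sample standard
    deviation (ddof=1) of the per-split metric values.
    """
    need = n_splits * split_size
    if need > len(mols):
        raise UndefinedMetricError(
            f"{n_splits} splits of {split_size} need {need} molecules; "
            f"got {len(mols)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(mols))[:need]
    values = []
    for s in range(n_splits):
        idx = perm[s * split_size:(s + 1) * split_size]
        values.append(metric([mols[i] for i in idx]))
    values = np.asarray(values, dtype=float)
    std = float(values.std(ddof=1)) if n_splits > 1 else 0.0
    return MetricReport("split_metric", float(values.mean()), uncertainty=std,
                        n_molecules=need, n_splits=n_splits,
                        config={"split_size": split_size, "seed": seed})
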