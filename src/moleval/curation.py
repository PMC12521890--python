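"""Dataset curation pipeline mirroring the corrected GEOM-drugs preprocessing.

Order of operations: (1) remove records whose bond graph is fragmented into
multiple components (an artifact of failed GFN2-xTB geometry optimization —
never repaired, always removed outright); (2) kekulize the retained
molecules so the dataset carries no explicit aromatic bonds; (3) flag atoms
matching known optimizer-failure signatures (a hydrogen with no covalent
bonds, a neutral carbon with valency 2, or any valency absent from the
corrected reference table).  Flags feed review; valency tables built from
the curated output no longer inherit those corrupted entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .graph import KekulizationError, MoleculeGraph, connected_components
from .tables import load_shipped_table
from .valency import ValencyMode, molecule_valencies

__all__ = [
    "CurationReport",
    "SuspiciousFlag",
    "filter_fragmented",
    "kekulize_dataset",
    "flag_suspicious",
    "curate",
]


@dataclass(frozen=True)
class SuspiciousFlag:
    molecule: str
    atom_index: int
    kind: str
    detail: str = ""


@dataclass
class CurationReport:
    n_input: int = 0
    n_fragmented_removed: int = 0
    n_kekulization_failures: int = 0
    removed_ids: list[str] = field(default_factory=list)
    kekulization_failure_ids: list[str] = field(default_factory=list)
    flags: list[SuspiciousFlag] = field(default_factory=list)

    @property
    def fraction_removed(self) -> float:
        """Percent of input records removed by the fragment filter."""
        if self.n_input == 0:
            return 0.0
        return 100.0 * self.n_fragmented_removed / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_fragmented_removed": self.n_fragmented_removed,
            "fraction_removed_percent": self.fraction_removed,
            "n_kekulization_failures": self.n_kekulization_failures,
            "removed_ids": self.removed_ids,
            "kekulization_failure_ids": self.kekulization_failure_ids,
            "flags": [vars(f) for f in self.flags],
        }


def filter_fragmented(mols: Sequence[MoleculeGraph]
                      ) -> tuple[list[MoleculeGraph], CurationReport]:
    """Keep molecules with exactly one connected component; count and list
    the rest.  Idempotent."""
    report = CurationReport(n_input=len(mols))
    retained = []
    for k, mol in enumerate(mols):
        if len(connected_components(mol)) == 1:
            retained.append(mol)
        else:
            report.n_fragmented_removed += 1
            report.removed_ids.append(mol.name or f"record-{k}")
    return retained, report


def kekulize_dataset(mols: Sequence[MoleculeGraph]
                     ) -> tuple[list[MoleculeGraph], list[str]]:
    """Kekulize every molecule; failures are reported, never silently
    dropped from the count.  Already-kekulized input passes through, so the
    operation is idempotent."""
    out: list[MoleculeGraph] = []
    failures: list[str] = []
    for k, mol in enumerate(mols):
        try:
            from .graph import kekulize
            out.append(kekulize(mol))
        except KekulizationError:
            failures.append(mol.name or f"record-{k}")
    return out, failures


_FAILURE_SIGNATURES = "isolated_hydrogen", "carbon_valency_2", "not_in_reference"


def flag_suspicious(mols: Sequence[MoleculeGraph]) -> list[SuspiciousFlag]:
    """Flag atoms bearing the known GFN2-xTB failure signatures.

    ``isolated_hydrogen``: H (any charge) with valency 0.
    ``carbon_valency_2``: neutral C with kekulized valency 2.
    ``not_in_reference``: any (element, charge, valency) absent from the
    shipped corrected table.
    ``non_kekulizable``: the whole molecule could not be kekulized, so
    valencies are undefined.
    """
    reference = load_shipped_table("corrected")
    flags: list[SuspiciousFlag] = []
    for k, mol in enumerate(mols):
        mol_id = mol.name or f"record-{k}"
        try:
            valencies = molecule_valencies(mol, ValencyMode.KEKULIZED)
        except KekulizationError as exc:
            flags.append(SuspiciousFlag(mol_id, -1, "non_kekulizable", str(exc)))
            continue
        for atom, av in zip(mol.atoms, valencies):
            v = av.value
            if atom.element == "H" and v == 0:
                flags.append(SuspiciousFlag(
                    mol_id, av.atom_index, "isolated_hydrogen",
                    f"H charge {atom.formal_charge:+d} with valency 0"))
            elif atom.element == "C" and atom.formal_charge == 0 and v == 2:
                flags.append(SuspiciousFlag(
                    mol_id, av.atom_index, "carbon_valency_2",
                    "neutral carbon with valency 2"))
            elif not reference.permits(atom.element, atom.formal_charge, v):
                flags.append(SuspiciousFlag(
                    mol_id, av.atom_index, "not_in_reference",
                    f"({atom.element}, {atom.formal_charge:+d}, {v})"))
    return flags


def curate(mols: Sequence[MoleculeGraph]
           ) -> tuple[list[MoleculeGraph], CurationReport]:
    """Full pipeline: fragment filter → kekulize → flag.

    Retained molecules keep their atom/bond content exactly, except
    aromatic bonds become their kekulé single/double assignment.
    Train/validation/test identities travel untouched in provenance.
    """
    retained, report = filter_fragmented(mols)
    kekulized, failures = kekulize_dataset(retained)
    report.n_kekulization_failures = len(failures)
    report.kekulization_failure_ids = failures
    report.flags = flag_suspicious(kekulized)
    return kekulized, report
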