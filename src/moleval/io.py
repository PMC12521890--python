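"""Readers and writers: SDF (primary), SMILES (topology-only fixtures) and
XYZ (optimizer interchange).

All readers parse *without sanitization* so the molecule under evaluation is
exactly what the file says: aromatic bonds (SDF type 4) stay aromatic,
hydrogen counts are untouched, valence errors are not "fixed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
from rdkit import Chem

from ._tables_data import SUPPORTED_ELEMENTS
from .graph import MoleculeGraph, from_rdkit, to_rdkit

__all__ = [
    "ParseFailure",
    "SDFError",
    "read_sdf",
    "iter_sdf",
    "write_sdf",
    "read_smiles",
    "write_xyz",
    "read_xyz",
]

_V2000_ATOM_LIMIT = 999


class SDFError(ValueError):
    pass


@dataclass(frozen=True)
class ParseFailure:
    """A record that failed to parse; carried along instead of dropped so
    counts stay honest."""

    record_index: int
    message: str


def _flag_elements(mol: MoleculeGraph) -> MoleculeGraph:
    unknown = sorted({a.element for a in mol.atoms
                      if a.element not in SUPPORTED_ELEMENTS})
    if unknown:
        mol.provenance["flagged_elements"] = unknown
    return mol


def iter_sdf(path: Union[str, Path], strict: bool = False
             ) -> Iterator[Union[MoleculeGraph, ParseFailure]]:
    """Yield one :class:`MoleculeGraph` per SDF record (V2000 or V3000).

    Records that fail to parse are yielded as :class:`ParseFailure` items
    carrying the record index, or abort the read when ``strict``.  Elements
    outside the supported reference set are flagged in provenance, not
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise SDFError(f"no such file: {path}")
    if path.stat().st_size == 0:  # an empty file is a valid empty record set
        return
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            if strict:
                raise SDFError(f"record {idx} of {path} failed to parse")
            yield ParseFailure(idx, f"record {idx} failed to parse")
            continue
        try:
            mol = from_rdkit(rdmol)
        except Exception as exc:
            if strict:
                raise SDFError(f"record {idx} of {path}: {exc}") from exc
            yield ParseFailure(idx, str(exc))
            continue
        mol.provenance.setdefault("source", str(path))
        mol.provenance.setdefault("record_index", idx)
        yield _flag_elements(mol)


def read_sdf(path: Union[str, Path], strict: bool = False
             ) -> tuple[list[MoleculeGraph], list[ParseFailure]]:
    """Read an SDF file; return ``(molecules, parse_failures)``."""
    mols: list[MoleculeGraph] = []
    failures: list[ParseFailure] = []
    for item in iter_sdf(path, strict=strict):
        (failures if isinstance(item, ParseFailure) else mols).append(item)
    return mols, failures


def write_sdf(mols: Sequence[MoleculeGraph], path: Union[str, Path]) -> int:
    """Write molecules as SDF (V2000; V3000 with a warning for oversize
    records) and return the record count.

    Aromatic bonds are written as bond type 4, formal charges via
    ``M  CHG``; a read-back reproduces elements, charges, bond orders and
    coordinates to 4 decimals.  Molecules without coordinates get an
    all-zero coordinate block.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    n = 0
    try:
        for mol in mols:
            mol.validate()
            padded = mol if mol.has_coords else mol.with_coords(
                np.zeros((mol.n_atoms, 3)))
            rdmol = to_rdkit(padded)
            rdmol.UpdatePropertyCache(strict=False)
            if mol.n_atoms > _V2000_ATOM_LIMIT:
                warnings.warn(
                    f"molecule {mol.name!r} has {mol.n_atoms} atoms; "
                    "writing V3000", stacklevel=2)
                writer.SetForceV3000(True)
            else:
                writer.SetForceV3000(False)
            writer.write(rdmol)
            n += 1
    finally:
        writer.close()
    return n


def read_smiles(smiles: str, name: str = "", add_hs: bool = True) -> MoleculeGraph:
    """Topology-only molecule from SMILES, for fixture construction.

    ``add_hs`` makes hydrogens explicit (the evaluation contract); it is a
    loader convenience and is never applied inside metrics.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if add_hs:
        rdmol = Chem.AddHs(rdmol)
    return from_rdkit(rdmol, name=name or smiles,
                      provenance={"smiles": smiles})


# ---------------------------------------------------------------------------
# XYZ interchange (element symbol + 3 floats per line, Å)
# ---------------------------------------------------------------------------

def write_xyz(elements: Sequence[str], coords: np.ndarray,
              path: Union[str, Path], comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(elements), 3):
        raise ValueError("coords must be N×3 matching elements")
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(elements, coords):
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: Union[str, Path]) -> tuple[list[str], np.ndarray, str]:
    """Read a single-frame XYZ file → (elements, N×3 coords Å, comment)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords = np.zeros((n, 3))
    for k in range(n):
        parts = lines[2 + k].split()
        elements.append(parts[0])
        coords[k] = [float(p) for p in parts[1:4]]
    return elements, coords, comment
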