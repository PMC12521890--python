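"""Optimizer backends: the contract behind the geometry benchmark.

A backend takes a molecule with coordinates and returns a
:class:`~moleval.graph.ConformerPair` — initial and optimized coordinates
with energies in kcal/mol on one consistent scale.  The reference level of
theory for GEOM-drugs-style data is GFN2-xTB (consumed through the external
``xtb`` program, never reimplemented); MMFF94 is available only as a coarse
filter, and two analytic backends (identity, harmonic) exist for dry runs
and exact tests.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np

from .graph import ConformerPair, MoleculeGraph, to_rdkit
from .io import read_xyz, write_xyz

__all__ = [
    "HARTREE_TO_KCALMOL",
    "BackendError",
    "BackendUnavailableError",
    "OptimizerBackend",
    "IdentityBackend",
    "HarmonicBackend",
    "MMFFBackend",
    "XTBBackend",
    "parse_xtb_total_energy",
]

#: Conversion applied at the backend boundary; fixed in exactly one place.
HARTREE_TO_KCALMOL = 627.509474


class BackendError(RuntimeError):
    """Per-molecule backend failure (parameterization, convergence, parse)."""


class BackendUnavailableError(BackendError):
    """The backend cannot run at all (e.g. missing executable)."""


class OptimizerBackend:
    """Contract: ``optimize`` returns a ConformerPair with the same atom
    ordering, and the optimized energy does not exceed the initial energy
    beyond the backend's convergence tolerance."""

    id: str = "abstract"
    capability: str = "optimize"  # or "energy-only"

    def optimize(self, mol: MoleculeGraph) -> ConformerPair:
        raise NotImplementedError


class IdentityBackend(OptimizerBackend):
    """Optimized structure = initial structure, energies 0.  Dry runs."""

    id = "identity"

    def optimize(self, mol: MoleculeGraph) -> ConformerPair:
        if not mol.has_coords:
            raise BackendError(f"{mol.name!r} has no coordinates")
        c = mol.coords
        return ConformerPair(mol, c, c.copy(), 0.0, 0.0, backend_id=self.id)


class HarmonicBackend(OptimizerBackend):
    """Toy potential E = ½k Σ‖x − x_ref‖² (kcal/mol, k in kcal/mol/Å²).

    "Optimization" returns the reference coordinates exactly, so this
    backend doubles as the record-the-original backend for perturbation
    fixtures: the reference is taken from a supplied callable/mapping or
    from ``provenance['reference_coords']``.
    """

    def __init__(self, reference: Union[None, dict,
                                        Callable[[MoleculeGraph], np.ndarray]] = None,
                 k: float = 1.0, backend_id: str = "harmonic"):
        self.reference = reference
        self.k = float(k)
        self.id = backend_id

    def _reference_coords(self, mol: MoleculeGraph) -> np.ndarray:
        if callable(self.reference):
            ref = self.reference(mol)
        elif isinstance(self.reference, dict):
            ref = self.reference.get(mol.name)
        else:
            ref = mol.provenance.get("reference_coords")
        if ref is None:
            raise BackendError(
                f"no reference coordinates for {mol.name!r}")
        ref = np.asarray(ref, dtype=float)
        if ref.shape != (mol.n_atoms, 3):
            raise BackendError(
                f"reference shape {ref.shape} mismatches {mol.name!r}")
        return ref

    def energy(self, mol: MoleculeGraph, coords: np.ndarray) -> float:
        ref = self._reference_coords(mol)
        disp = np.asarray(coords, dtype=float) - ref
        return 0.5 * self.k * float(np.sum(disp * disp))

    def optimize(self, mol: MoleculeGraph) -> ConformerPair:
        if not mol.has_coords:
            raise BackendError(f"{mol.name!r} has no coordinates")
        init = mol.coords
        ref = self._reference_coords(mol)
        return ConformerPair(mol, init, ref, self.energy(mol, init), 0.0,
                             backend_id=self.id)


class MMFFBackend(OptimizerBackend):
    """MMFF94 force-field optimization via the toolkit.

    A classical potential substantially different from the semi-empirical
    reference; useful only as a coarse plausibility filter.  Molecules the
    force field cannot parameterize fail per-molecule.
    """

    id = "mmff94"

    def __init__(self, variant: str = "MMFF94", max_iters: int = 2000):
        if variant not in ("MMFF94", "MMFF94s"):
            raise ValueError(f"unknown MMFF variant {variant!r}")
        self.variant = variant
        self.max_iters = max_iters

    def optimize(self, mol: MoleculeGraph) -> ConformerPair:
        from rdkit import Chem
        from rdkit.Chem import AllChem

        if not mol.has_coords:
            raise BackendError(f"{mol.name!r} has no coordinates")
        rdmol = to_rdkit(mol)
        try:
            Chem.SanitizeMol(rdmol)
        except Exception as exc:
            raise BackendError(f"{mol.name!r}: sanitization failed: {exc}")
        props = AllChem.MMFFGetMoleculeProperties(rdmol, mmffVariant=self.variant)
        if props is None:
            raise BackendError(f"{mol.name!r}: MMFF parameterization failed")
        ff = AllChem.MMFFGetMoleculeForceField(rdmol, props)
        if ff is None:
            raise BackendError(f"{mol.name!r}: MMFF force field setup failed")
        e_init = float(ff.CalcEnergy())
        ff.Minimize(maxIts=self.max_iters)
        e_opt = float(ff.CalcEnergy())
        conf = rdmol.GetConformer()
        opt = np.array([[conf.GetAtomPosition(i).x,
                         conf.GetAtomPosition(i).y,
                         conf.GetAtomPosition(i).z]
                        for i in range(rdmol.GetNumAtoms())])
        return ConformerPair(mol, mol.coords, opt, e_init, e_opt,
                             backend_id=self.id)


# ---------------------------------------------------------------------------
# GFN2-xTB via the external xtb program
# ---------------------------------------------------------------------------

_XTB_ENERGY_RE = re.compile(r"TOTAL ENERGY\s+(-?\d+\.\d+)\s+Eh")


def parse_xtb_total_energy(text: str) -> float:
    """Extract the (last) total energy in Hartree from xtb stdout."""
    matches = _XTB_ENERGY_RE.findall(text)
    if not matches:
        raise BackendError("no TOTAL ENERGY found in xtb output")
    return float(matches[-1])


class XTBBackend(OptimizerBackend):
    """GFN2-xTB single-point + geometry optimization through the ``xtb``
    executable (XYZ interchange; Hartree converted to kcal/mol here).

    Defaults: GFN2 Hamiltonian, normal optimization level, net charge from
    the molecule's formal charges, singlet multiplicity.  The executable is
    probed at construction so a missing installation fails fast rather than
    mid-benchmark.
    """

    id = "gfn2-xtb"

    def __init__(self, executable: str = "xtb", opt_level: str = "normal",
                 workdir: Optional[Union[str, Path]] = None,
                 gfn: int = 2, timeout: float = 600.0):
        resolved = shutil.which(executable)
        if resolved is None:
            raise BackendUnavailableError(
                f"xtb executable {executable!r} not found on PATH")
        self.executable = resolved
        self.opt_level = opt_level
        self.workdir = Path(workdir) if workdir else None
        self.gfn = gfn
        self.timeout = timeout

    def _run(self, args: list[str], cwd: Path) -> str:
        proc = subprocess.run(
            [self.executable, *args], cwd=cwd, capture_output=True,
            text=True, timeout=self.timeout)
        if proc.returncode != 0:
            tail = "\n".join(proc.stdout.splitlines()[-15:])
            raise BackendError(
                f"xtb exited with {proc.returncode}; log tail:\n{tail}")
        return proc.stdout

    def optimize(self, mol: MoleculeGraph) -> ConformerPair:
        if not mol.has_coords:
            raise BackendError(f"{mol.name!r} has no coordinates")
        charge = mol.net_charge
        elements = [a.element for a in mol.atoms]
        ctx = (tempfile.TemporaryDirectory() if self.workdir is None else None)
        cwd = Path(ctx.name) if ctx else self.workdir
        try:
            xyz = cwd / "mol.xyz"
            write_xyz(elements, mol.coords, xyz, comment=mol.name)
            common = ["--gfn", str(self.gfn), "--chrg", str(charge)]
            sp_out = self._run(["mol.xyz", *common], cwd)
            e_init = parse_xtb_total_energy(sp_out) * HARTREE_TO_KCALMOL
            opt_out = self._run(
                ["mol.xyz", *common, "--opt", self.opt_level], cwd)
            e_opt = parse_xtb_total_energy(opt_out) * HARTREE_TO_KCALMOL
            opt_xyz = cwd / "xtbopt.xyz"
            if not opt_xyz.exists():
                raise BackendError("xtb produced no xtbopt.xyz")
            out_elements, opt_coords, _ = read_xyz(opt_xyz)
            if out_elements != elements:
                raise BackendError("xtb changed atom ordering")
            return ConformerPair(mol, mol.coords, opt_coords, e_init, e_opt,
                                 backend_id=self.id)
        finally:
            if ctx:
                ctx.cleanup()
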