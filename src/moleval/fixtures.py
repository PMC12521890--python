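"""Deterministic synthetic inputs: toy molecules, known failure modes,
fragmented records, and conformer pairs with injected perturbations.

Everything here is generated in code — idealized ring/chain geometries from
a small embedded builder, no external optimizer, no dataset download — so
every metric in the package is testable offline.  The same spec and seed
always produce the identical fixture set.

The failure-mode molecules reproduce the defect patterns that inflated
published stability numbers: a neutral carbon with three single bonds, a
neutral nitrogen with two single bonds, an N⁺ carrying both a triple and an
aromatic bond, a fragmented record with an isolated H⁺, and a neutral
carbon with valency two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import (AtomRecord, BondOrder, BondRecord, ConformerPair,
                    MoleculeGraph, kekulize)
from .geometry import enumerate_internal_coords

__all__ = [
    "FixtureSpec",
    "toy_molecule_set",
    "invalid_molecule_set",
    "fragmented_molecule_set",
    "chain_molecule",
    "perturbed_pairs",
    "corpus",
]

_CC_AROM = 1.394   # Å, aromatic ring edge
_CH = 1.09
_NH = 1.01
_OH = 0.96


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible fixture-set parameters.

    Perturbation magnitudes default to the recovery-test conditions
    (0.05 Å bond stretch, 5° angle bend, 10° torsion twist).  Corpus
    defaults emulate the published evaluation protocol: 5000 molecules per
    collection, with invalid/fragmented fractions of the order seen for
    contemporary generative models (stability ≈ 0.9) and optimizer
    fragmentation failures being rare.
    """

    seed: int = 0
    n_molecules: int = 5000
    fraction_invalid: float = 0.10
    fraction_fragmented: float = 0.02
    bond_delta: float = 0.05     # Å
    angle_delta: float = 5.0     # degrees
    torsion_delta: float = 10.0  # degrees
    harmonic_k: float = 1.0      # kcal/mol/Å²

    def __post_init__(self) -> None:
        for f in (self.fraction_invalid, self.fraction_fragmented):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be within [0, 1]")
        if self.fraction_invalid + self.fraction_fragmented > 1.0:
            raise ValueError("category fractions exceed 1")


# ---------------------------------------------------------------------------
# Embedded geometry builders (idealized bond lengths/angles, deterministic)
# ---------------------------------------------------------------------------

def _hexagon_vertices(center: tuple[float, float], r: float) -> list[tuple[float, float]]:
    return [(center[0] + r * math.cos(math.radians(30 + 60 * k)),
             center[1] + r * math.sin(math.radians(30 + 60 * k)))
            for k in range(6)]


def _fused_ring_system(hex_centers: Sequence[tuple[float, float]],
                       r: float = _CC_AROM,
                       name: str = "") -> MoleculeGraph:
    """Planar fused-hexagon aromatic carbon skeleton: dedupe shared
    vertices, bond vertices at ring-edge distance, hydrogens radially on
    rim (degree-2) atoms."""
    verts: list[tuple[float, float]] = []
    for c in hex_centers:
        for v in _hexagon_vertices(c, r):
            if not any(math.dist(v, w) < 1e-6 for w in verts):
                verts.append(v)
    verts.sort(key=lambda v: (round(v[0], 6), round(v[1], 6)))
    atoms = [AtomRecord("C", 0, (x, y, 0.0)) for (x, y) in verts]
    bonds = []
    for i in range(len(verts)):
        for j in range(i + 1, len(verts)):
            if math.dist(verts[i], verts[j]) < 1.05 * r:
                bonds.append(BondRecord(i, j, BondOrder.AROMATIC))
    mol = MoleculeGraph(atoms, bonds, name)
    n_heavy = len(atoms)
    adj = mol.adjacency()
    for i in range(n_heavy):
        if len(adj[i]) != 2:
            continue
        el = atoms[i].element
        x, y, _ = atoms[i].coords
        nx = np.mean([atoms[n].coords[0] for n in adj[i]])
        ny = np.mean([atoms[n].coords[1] for n in adj[i]])
        d = np.array([x - nx, y - ny])
        d /= np.linalg.norm(d)
        length = _CH if el == "C" else _NH
        h = AtomRecord("H", 0, (x + length * d[0], y + length * d[1], 0.0))
        mol.atoms.append(h)
        mol.bonds.append(BondRecord(i, len(mol.atoms) - 1, BondOrder.SINGLE))
    return mol


def _pentagon(elements: Sequence[str], h_on: Sequence[bool],
              side: float = 1.37, name: str = "") -> MoleculeGraph:
    r = side / (2 * math.sin(math.pi / 5))
    atoms = []
    for k, el in enumerate(elements):
        a = math.radians(90 + 72 * k)
        atoms.append(AtomRecord(el, 0, (r * math.cos(a), r * math.sin(a), 0.0)))
    bonds = [BondRecord(k, (k + 1) % 5, BondOrder.AROMATIC) for k in range(5)]
    mol = MoleculeGraph(atoms, bonds, name)
    for k, put_h in enumerate(h_on):
        if not put_h:
            continue
        x, y, _ = atoms[k].coords
        d = np.array([x, y])
        d /= np.linalg.norm(d)
        length = _CH if elements[k] == "C" else _NH
        mol.atoms.append(AtomRecord("H", 0,
                                    (x + length * d[0], y + length * d[1], 0.0)))
        mol.bonds.append(BondRecord(k, len(mol.atoms) - 1, BondOrder.SINGLE))
    return mol


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                dist: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place D so that |D−c| = dist, angle(D,c,b) = angle and
    dihedral(D,c,b,a) = dihedral (NeRF construction)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-dist * math.cos(theta),
                  dist * math.sin(theta) * math.cos(phi),
                  dist * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _tetrahedral(center_el: str, arm_el: str, n_arms: int, arm_len: float,
                 name: str, charge: int = 0) -> MoleculeGraph:
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                    dtype=float) / math.sqrt(3)
    atoms = [AtomRecord(center_el, charge, (0.0, 0.0, 0.0))]
    bonds = []
    for k in range(n_arms):
        atoms.append(AtomRecord(arm_el, 0, tuple(arm_len * dirs[k])))
        bonds.append(BondRecord(0, k + 1, BondOrder.SINGLE))
    return MoleculeGraph(atoms, bonds, name)


def _water(name: str = "water", offset: tuple[float, float, float] = (0, 0, 0)
           ) -> MoleculeGraph:
    ang = math.radians(104.5 / 2)
    ox, oy, oz = offset
    atoms = [
        AtomRecord("O", 0, (ox, oy, oz)),
        AtomRecord("H", 0, (ox + _OH * math.sin(ang), oy + _OH * math.cos(ang), oz)),
        AtomRecord("H", 0, (ox - _OH * math.sin(ang), oy + _OH * math.cos(ang), oz)),
    ]
    return MoleculeGraph(atoms, [BondRecord(0, 1, BondOrder.SINGLE),
                                 BondRecord(0, 2, BondOrder.SINGLE)], name)


def _ethane() -> MoleculeGraph:
    cc = 1.54
    atoms = [AtomRecord("C", 0, (0.0, 0.0, 0.0)),
             AtomRecord("C", 0, (cc, 0.0, 0.0))]
    bonds = [BondRecord(0, 1, BondOrder.SINGLE)]
    mol = MoleculeGraph(atoms, bonds, "ethane")
    theta = math.radians(109.47)
    for ci, (base, sign) in enumerate([(0, -1.0), (1, 1.0)]):
        for k in range(3):
            phi = math.radians(120 * k + (60 if ci else 0))
            x = atoms[base].coords[0] + sign * _CH * math.cos(math.pi - theta)
            rad = _CH * math.sin(math.pi - theta)
            h = (x, rad * math.cos(phi), rad * math.sin(phi))
            mol.atoms.append(AtomRecord("H", 0, h))
            mol.bonds.append(BondRecord(base, len(mol.atoms) - 1,
                                        BondOrder.SINGLE))
    return mol


def chain_molecule(n_inner: int = 4, name: Optional[str] = None,
                   dihedral: float = 180.0) -> MoleculeGraph:
    """H–(S)ₙ–H polysulfane-like zigzag chain: every interior atom has
    degree 2, so bond/angle/torsion perturbations are exactly independent.
    Planar (trans) by default."""
    if n_inner < 2:
        raise ValueError("need at least 2 interior atoms")
    name = name or f"chain-S{n_inner}"
    sh, ss, ang = 1.34, 2.05, 105.0
    pos = [np.array([0.0, 0.0, 0.0]), np.array([sh, 0.0, 0.0])]
    # second S placed in the xy plane
    t = math.radians(180 - ang)
    pos.append(pos[1] + ss * np.array([math.cos(t), math.sin(t), 0.0]))
    lengths = [ss] * (n_inner - 2) + [sh]
    for k, dist in enumerate(lengths):
        pos.append(_place_atom(pos[-3], pos[-2], pos[-1], dist, ang, dihedral))
    elements = ["H"] + ["S"] * n_inner + ["H"]
    atoms = [AtomRecord(el, 0, tuple(p)) for el, p in zip(elements, pos)]
    bonds = [BondRecord(k, k + 1, BondOrder.SINGLE)
             for k in range(len(atoms) - 1)]
    return MoleculeGraph(atoms, bonds, name)


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

_SQ3 = math.sqrt(3)


def _aromatic_library() -> list[MoleculeGraph]:
    benzene = _fused_ring_system([(0.0, 0.0)], name="benzene")
    pyridine = _fused_ring_system([(0.0, 0.0)], name="pyridine")
    # vertex 0 → bare nitrogen (drop its hydrogen)
    _substitute_bare_nitrogen(pyridine, 0)
    naphthalene = _fused_ring_system([(0.0, 0.0), (_SQ3 * _CC_AROM, 0.0)],
                                     name="naphthalene")
    d = _SQ3 * _CC_AROM
    triphenylene = _fused_ring_system(
        [(0.0, 0.0)] + [(d * math.cos(math.radians(a)),
                         d * math.sin(math.radians(a)))
                        for a in (0, 120, 240)],
        name="triphenylene")
    pyrrole = _pentagon(["N", "C", "C", "C", "C"], [True] * 5, name="pyrrole")
    imidazole = _pentagon(["N", "C", "N", "C", "C"],
                          [True, True, False, True, True], name="imidazole")
    return [benzene, pyridine, pyrrole, imidazole, naphthalene, triphenylene]


def _substitute_bare_nitrogen(mol: MoleculeGraph, ring_index: int) -> None:
    """Turn ring atom ``ring_index`` into an N and remove its hydrogen."""
    h_index = None
    for b in mol.incident_bonds(ring_index):
        other = b.j if b.i == ring_index else b.i
        if mol.atoms[other].element == "H":
            h_index = other
    a = mol.atoms[ring_index]
    mol.atoms[ring_index] = AtomRecord("N", 0, a.coords)
    if h_index is None:
        return
    mol.atoms.pop(h_index)
    mol.bonds = [
        BondRecord(b.i - (b.i > h_index), b.j - (b.j > h_index), b.order)
        for b in mol.bonds if h_index not in (b.i, b.j)
    ]


def toy_molecule_set() -> list[MoleculeGraph]:
    """Fixed library of small valid molecules with clean 3D coordinates.

    Aromatic molecules appear twice: with aromatic-typed ring bonds
    (``name/aromatic``) and in kekulized form (``name/kekulized``).
    Deterministic across runs.
    """
    out: list[MoleculeGraph] = []
    for mol in _aromatic_library():
        arom = mol.copy()
        arom.name = f"{mol.name}/aromatic"
        arom.provenance["representation"] = "aromatic"
        kek = kekulize(mol)
        kek.name = f"{mol.name}/kekulized"
        kek.provenance["representation"] = "kekulized"
        out.extend([arom, kek])
    out.append(_tetrahedral("C", "H", 4, _CH, "methane"))
    out.append(_ethane())
    out.append(_water())
    ammonia = _tetrahedral("N", "H", 3, _NH, "ammonia")
    out.append(ammonia)
    for mol in out:
        mol.validate()
    return out


def invalid_molecule_set() -> list[MoleculeGraph]:
    """The five failure-mode molecules, deterministic across runs.

    Each is unstable against the corrected reference table; the
    three-single-bond carbon and two-single-bond nitrogen are *stable*
    against the legacy table — that asymmetry is exactly the historical
    inflation the corrected metric removes.
    """
    out = []
    # (a) neutral carbon with three single bonds
    out.append(_tetrahedral("C", "H", 3, _CH, "carbon-three-single-bonds"))
    # (b) neutral nitrogen with two single bonds
    out.append(_tetrahedral("N", "H", 2, _NH, "nitrogen-two-single-bonds"))
    # (c) N+ bonded via both a triple bond and an aromatic bond
    atoms = [AtomRecord("N", 1, (0.0, 0.0, 0.0)),
             AtomRecord("C", 0, (-1.16, 0.0, 0.0)),
             AtomRecord("H", 0, (-2.22, 0.0, 0.0)),
             AtomRecord("C", 0, (1.35, 0.0, 0.0)),
             AtomRecord("H", 0, (1.90, 0.93, 0.0)),
             AtomRecord("H", 0, (1.90, -0.93, 0.0)),
             AtomRecord("H", 0, (1.35, -0.63, 0.89))]
    bonds = [BondRecord(0, 1, BondOrder.TRIPLE),
             BondRecord(1, 2, BondOrder.SINGLE),
             BondRecord(0, 3, BondOrder.AROMATIC),
             BondRecord(3, 4, BondOrder.SINGLE),
             BondRecord(3, 5, BondOrder.SINGLE),
             BondRecord(3, 6, BondOrder.SINGLE)]
    out.append(MoleculeGraph(atoms, bonds, "n-plus-triple-aromatic"))
    # fragmented record with an isolated H+
    frag = _water("fragmented-isolated-h-plus")
    frag.atoms.append(AtomRecord("H", 1, (4.0, 0.0, 0.0)))
    out.append(frag)
    # neutral carbon with valency two (carbene-like)
    out.append(_tetrahedral("C", "H", 2, _CH, "carbene-valency-2"))
    for mol in out:
        mol.validate()
        mol.provenance["expected"] = "invalid"
    return out


def fragmented_molecule_set() -> list[MoleculeGraph]:
    """Multi-component records whose atoms are individually well-valenced:
    they fail connectedness, not stability."""
    two_waters = _water("two-waters")
    far = _water(offset=(5.0, 0.0, 0.0))
    n0 = two_waters.n_atoms
    two_waters.atoms.extend(far.atoms)
    two_waters.bonds.extend(BondRecord(b.i + n0, b.j + n0, b.order)
                            for b in far.bonds)
    mols = [two_waters]
    benz = _fused_ring_system([(0.0, 0.0)], name="benzene-plus-methane")
    methane = _tetrahedral("C", "H", 4, _CH, "")
    shift = np.array([8.0, 0.0, 0.0])
    n0 = benz.n_atoms
    for a in methane.atoms:
        benz.atoms.append(AtomRecord(a.element, a.formal_charge,
                                     tuple(np.array(a.coords) + shift)))
    benz.bonds.extend(BondRecord(b.i + n0, b.j + n0, b.order)
                      for b in methane.bonds)
    mols.append(benz)
    for mol in mols:
        mol.validate()
        mol.provenance["expected"] = "fragmented"
    return mols


# ---------------------------------------------------------------------------
# Perturbed conformer pairs
# ---------------------------------------------------------------------------

def _branch(adj: dict[int, list[int]], start: int, blocked_from: int) -> set[int]:
    """Atoms reachable from ``start`` with the edge (blocked_from, start)
    removed."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if v == start and w == blocked_from:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _rotate(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
            angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    p = points - origin
    rot = (p * math.cos(th)
           + np.cross(axis, p) * math.sin(th)
           + np.outer(p @ axis, axis) * (1 - math.cos(th)))
    return rot + origin


def perturbed_pairs(base: Sequence[MoleculeGraph],
                    spec: FixtureSpec) -> list[ConformerPair]:
    """Conformer pairs with known injected deviations.

    ``coords_opt`` is the base geometry; ``coords_init`` stretches every
    non-ring bond by ``bond_delta`` (moving the rigid branch along the bond
    axis), bends every angle at a degree-2 center by ``angle_delta``, and
    twists every rotatable (non-ring) central bond by ``torsion_delta``.
    Each class is exactly independent on acyclic topologies; skipped
    perturbations (ring bonds, crowded centers) are recorded in
    ``provenance['skipped_perturbations']``.  Energies come from the
    harmonic toy potential E = ½k Σ‖x − x_ref‖².
    """
    pairs = []
    for mol in base:
        if not mol.has_coords:
            raise ValueError(f"{mol.name!r} lacks coordinates")
        ref = mol.coords
        coords = ref.copy()
        adj = mol.adjacency()
        skipped: list[str] = []
        ics = enumerate_internal_coords(mol)

        if spec.torsion_delta:
            central = sorted({(t[1], t[2]) for t in ics.torsions})
            for (j, k) in central:
                branch = _branch(adj, k, j)
                if j in branch:
                    skipped.append(f"torsion about ring bond ({j},{k})")
                    continue
                idx = sorted(branch)
                coords[idx] = _rotate(coords[idx], coords[j],
                                      coords[k] - coords[j],
                                      spec.torsion_delta)
        if spec.angle_delta:
            for (i, j, k) in ics.angles:
                if len(adj[j]) != 2:
                    skipped.append(f"angle ({i},{j},{k}): crowded center")
                    continue
                branch = _branch(adj, k, j)
                if j in branch or i in branch:
                    skipped.append(f"angle ({i},{j},{k}): ring")
                    continue
                u = coords[i] - coords[j]
                v = coords[k] - coords[j]
                normal = np.cross(u, v)
                if np.linalg.norm(normal) < 1e-9:
                    skipped.append(f"angle ({i},{j},{k}): collinear")
                    continue
                idx = sorted(branch)
                coords[idx] = _rotate(coords[idx], coords[j], normal,
                                      spec.angle_delta)
        if spec.bond_delta:
            for (i, j) in ics.bonds:
                branch = _branch(adj, j, i)
                if i in branch:
                    skipped.append(f"bond ({i},{j}): ring")
                    continue
                direction = coords[j] - coords[i]
                direction /= np.linalg.norm(direction)
                idx = sorted(branch)
                coords[idx] = coords[idx] + spec.bond_delta * direction

        top = mol.copy()
        top.provenance["reference_coords"] = ref.tolist()
        if skipped:
            top.provenance["skipped_perturbations"] = skipped
        disp = coords - ref
        e_init = 0.5 * spec.harmonic_k * float(np.sum(disp * disp))
        pairs.append(ConformerPair(top.with_coords(coords), coords, ref,
                                   e_init, 0.0, backend_id="harmonic"))
    return pairs


# ---------------------------------------------------------------------------
# Mixed corpus with ground-truth labels
# ---------------------------------------------------------------------------

def corpus(spec: FixtureSpec) -> list[MoleculeGraph]:
    """Mixed collection with exact category counts and ground-truth labels.

    Categories are disjoint by construction: ``valid`` molecules are stable
    and single-component, ``invalid`` ones carry a valency defect,
    ``fragmented`` ones are well-valenced but multi-component.  Labels sit
    in ``provenance['label']`` so metric outputs can be verified exactly.
    Seed changes the order, never the counts.
    """
    n = spec.n_molecules
    n_invalid = round(spec.fraction_invalid * n)
    n_frag = round(spec.fraction_fragmented * n)
    n_valid = n - n_invalid - n_frag
    pools = {
        "valid": toy_molecule_set(),
        "invalid": invalid_molecule_set(),
        "fragmented": fragmented_molecule_set(),
    }
    out: list[MoleculeGraph] = []
    for label, count in (("valid", n_valid), ("invalid", n_invalid),
                         ("fragmented", n_frag)):
        pool = pools[label]
        for k in range(count):
            m = pool[k % len(pool)].copy()
            m.provenance = dict(m.provenance)
            m.provenance["label"] = label
            m.provenance["template"] = m.name
            m.name = f"corpus-{label}-{k:05d}"
            out.append(m)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(out))
    return [out[i] for i in order]
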