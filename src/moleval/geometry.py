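"""Internal-coordinate deviation statistics and the relaxation benchmark.

The benchmark measures how far a generated structure sits from the nearest
local minimum of the reference potential: each molecule is optimized by a
backend and the deviations between initial and optimized structures are
collected over the molecule's internal coordinates —

* bond lengths:   Δr   = |r_init − r_opt|                       (Å)
* bond angles:    Δθ   = min(|Δ|, 180° − |Δ|)                   (degrees)
* torsion angles: Δφ   = min(|Δ|, 360° − |Δ|)                   (degrees)

together with the relaxation energy ΔE_relax = E_init − E_opt (kcal/mol,
signed; a negative value means the optimizer ended *higher*, flagged as a
convergence anomaly, never clipped).

Deviations are pooled over all internal coordinates of all molecules in a
split and then averaged; per-molecule means are also retained.  Degenerate
geometries (coincident atoms, collinear arms) are excluded from averages
and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import ConformerPair, MoleculeGraph
from .metrics import is_valid_and_connected

__all__ = [
    "InternalCoordinateSet",
    "DeviationSummary",
    "DegenerateGeometryError",
    "BenchmarkError",
    "enumerate_internal_coords",
    "bond_length",
    "bond_angle",
    "dihedral_angle",
    "bond_length_diff",
    "angle_diff",
    "torsion_diff",
    "delta_e_relax",
    "benchmark",
]

_EPS = 1e-6


class DegenerateGeometryError(ValueError):
    """Coincident or collinear atoms make the internal coordinate undefined."""


class BenchmarkError(RuntimeError):
    pass


@dataclass(frozen=True)
class InternalCoordinateSet:
    """Unique bonds, angles (centered at the middle atom, i < k) and proper
    torsions (central bond ordered) of a topology, in deterministic order."""

    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    torsions: tuple[tuple[int, int, int, int], ...]


def enumerate_internal_coords(mol: MoleculeGraph) -> InternalCoordinateSet:
    adj = mol.adjacency()
    for nbrs in adj.values():
        nbrs.sort()
    bonds = tuple(sorted(b.key for b in mol.bonds))
    angles = []
    for j in range(mol.n_atoms):
        nbrs = adj[j]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    torsions = []
    for (j, k) in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                torsions.append((i, j, k, l))
    # canonical orientation: torsion reversed if needed so (j,k) ascending,
    # deduped modulo reversal
    canon = set()
    ordered = []
    for t in torsions:
        key = t if (t[1], t[2], t[0], t[3]) <= (t[2], t[1], t[3], t[0]) \
            else (t[3], t[2], t[1], t[0])
        if key not in canon:
            canon.add(key)
            ordered.append(key)
    return InternalCoordinateSet(bonds, tuple(sorted(angles)),
                                 tuple(sorted(ordered)))


# ---------------------------------------------------------------------------
# Geometry primitives (coords: N×3 array, Å; angles in degrees)
# ---------------------------------------------------------------------------

def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    d = float(np.linalg.norm(coords[i] - coords[j]))
    if d < _EPS:
        raise DegenerateGeometryError(f"atoms {i},{j} coincide")
    return d


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError(f"zero-length arm in angle {(i, j, k)}")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral in (−180°, 180°] via the atan2 formulation."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS or nb2 < _EPS:
        raise DegenerateGeometryError(
            f"collinear atoms make torsion {(i, j, k, l)} undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# Deviation operators
# ---------------------------------------------------------------------------

def bond_length_diff(pair: ConformerPair, bond: tuple[int, int]) -> float:
    i, j = bond
    return abs(bond_length(pair.coords_init, i, j)
               - bond_length(pair.coords_opt, i, j))


def angle_diff(pair: ConformerPair, angle: tuple[int, int, int]) -> float:
    d = abs(bond_angle(pair.coords_init, *angle)
            - bond_angle(pair.coords_opt, *angle))
    return min(d, 180.0 - d)


def torsion_diff(pair: ConformerPair, torsion: tuple[int, int, int, int]) -> float:
    d = abs(dihedral_angle(pair.coords_init, *torsion)
            - dihedral_angle(pair.coords_opt, *torsion))
    return min(d, 360.0 - d)


def delta_e_relax(pair: ConformerPair) -> float:
    """Signed relaxation energy E_init − E_opt in kcal/mol."""
    if pair.energy_init is None or pair.energy_opt is None:
        raise ValueError(
            f"backend {pair.backend_id!r} delivered no energy for "
            f"{pair.topology.name!r}")
    return pair.energy_init - pair.energy_opt


@dataclass
class PairDeviations:
    """All internal-coordinate deviations of one conformer pair."""

    name: str
    bond_devs: list[float]
    angle_devs: list[float]
    torsion_devs: list[float]
    dE_relax: float
    n_degenerate: int = 0


def pair_deviations(pair: ConformerPair) -> PairDeviations:
    ics = enumerate_internal_coords(pair.topology)
    out = PairDeviations(pair.topology.name, [], [], [], 0.0)
    for bond in ics.bonds:
        try:
            out.bond_devs.append(bond_length_diff(pair, bond))
        except DegenerateGeometryError:
            out.n_degenerate += 1
    for angle in ics.angles:
        try:
            out.angle_devs.append(angle_diff(pair, angle))
        except DegenerateGeometryError:
            out.n_degenerate += 1
    for torsion in ics.torsions:
        try:
            out.torsion_devs.append(torsion_diff(pair, torsion))
        except DegenerateGeometryError:
            out.n_degenerate += 1
    out.dE_relax = delta_e_relax(pair)
    return out


@dataclass
class DeviationSummary:
    mean_bond_dev: float
    mean_angle_dev: float
    mean_torsion_dev: float
    median_dE_relax: float
    mean_dE_relax: float
    bond_dev_std: Optional[float] = None
    angle_dev_std: Optional[float] = None
    torsion_dev_std: Optional[float] = None
    median_dE_std: Optional[float] = None
    mean_dE_std: Optional[float] = None
    n_molecules: int = 0
    n_splits: Optional[int] = None
    n_backend_failures: int = 0
    n_degenerate: int = 0
    n_energy_anomalies: int = 0  # negative dE_relax: optimizer went uphill
    backend_id: str = ""
    per_molecule: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "per_molecule"}
        return d


def _pooled_means(devs: Sequence[PairDeviations]) -> tuple[float, float, float,
                                                           float, float]:
    def mean(xs):
        return float(np.mean(xs)) if xs else 0.0
    bonds = [d for p in devs for d in p.bond_devs]
    angles = [d for p in devs for d in p.angle_devs]
    torsions = [d for p in devs for d in p.torsion_devs]
    energies = [p.dE_relax for p in devs]
    return (mean(bonds), mean(angles), mean(torsions),
            float(np.median(energies)) if energies else 0.0,
            mean(energies))


def benchmark(mols: Sequence[MoleculeGraph], backend, *,
              valid_only: bool = False, n_splits: Optional[int] = None,
              split_size: Optional[int] = None, seed: int = 0,
              max_failure_fraction: float = 0.10) -> DeviationSummary:
    """Optimize each molecule with ``backend`` and summarize deviations.

    ``valid_only`` restricts the benchmark to molecules passing the V&C
    criterion (how published summaries are reported).  With ``n_splits``/
    ``split_size`` the split protocol is applied: per-quantity pooled means
    are computed within each disjoint split and reported as mean ± sample
    std across splits.  Backend failures are excluded and counted; more
    than ``max_failure_fraction`` of failures voids the benchmark.
    """
    from .backends import BackendError

    candidates = [m for m in mols if m.has_coords]
    if valid_only:
        candidates = [m for m in candidates if is_valid_and_connected(m)]
    if not candidates:
        raise BenchmarkError("no molecules to benchmark")

    devs: list[PairDeviations] = []
    n_failures = 0
    for mol in candidates:
        try:
            pair = backend.optimize(mol)
            devs.append(pair_deviations(pair))
        except BackendError:
            n_failures += 1
    if n_failures > max_failure_fraction * len(candidates):
        raise BenchmarkError(
            f"{n_failures}/{len(candidates)} backend failures exceed "
            f"{max_failure_fraction:.0%}; benchmark not representative")
    if not devs:
        raise BenchmarkError("every molecule failed in the backend")

    n_degenerate = sum(p.n_degenerate for p in devs)
    n_anomalies = sum(p.dE_relax < 0 for p in devs)

    if n_splits:
        split_size = split_size or len(devs) // n_splits
        need = n_splits * split_size
        if need > len(devs):
            raise BenchmarkError(
                f"{n_splits}×{split_size} needs {need} molecules; "
                f"have {len(devs)}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(devs))[:need]
        rows = []
        for s in range(n_splits):
            chunk = [devs[i] for i in perm[s * split_size:(s + 1) * split_size]]
            rows.append(_pooled_means(chunk))
        arr = np.asarray(rows)
        means = arr.mean(axis=0)
        stds = arr.std(axis=0, ddof=1) if n_splits > 1 else np.zeros(5)
        return DeviationSummary(
            *map(float, means),
            bond_dev_std=float(stds[0]), angle_dev_std=float(stds[1]),
            torsion_dev_std=float(stds[2]), median_dE_std=float(stds[3]),
            mean_dE_std=float(stds[4]),
            n_molecules=need, n_splits=n_splits,
            n_backend_failures=n_failures, n_degenerate=n_degenerate,
            n_energy_anomalies=n_anomalies,
            backend_id=getattr(backend, "id", ""), per_molecule=devs)

    pooled = _pooled_means(devs)
    return DeviationSummary(
        *pooled, n_molecules=len(devs), n_splits=None,
        n_backend_failures=n_failures, n_degenerate=n_degenerate,
        n_energy_anomalies=n_anomalies,
        backend_id=getattr(backend, "id", ""), per_molecule=devs)
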