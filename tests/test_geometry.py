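"""Internal-coordinate enumeration, deviation operators and the benchmark."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moleval as mv
from moleval.backends import BackendError, HarmonicBackend, IdentityBackend
from moleval.geometry import (BenchmarkError, DegenerateGeometryError,
                              bond_angle, dihedral_angle, pair_deviations)


def pair_from_coords(mol, init, opt, e_init=0.0, e_opt=0.0):
    return mv.ConformerPair(mol, init, opt, e_init, e_opt, "test")


def random_rotation(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0, 2 * math.pi)
    kx = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(theta) * kx + (1 - math.cos(theta)) * kx @ kx


def water_pair(toy, theta_init, theta_opt):
    wat = toy("water")

    def coords(theta):
        t = math.radians(theta / 2)
        return np.array([[0.0, 0.0, 0.0],
                         [math.sin(t), math.cos(t), 0.0],
                         [-math.sin(t), math.cos(t), 0.0]])
    return wat, pair_from_coords(wat, coords(theta_init), coords(theta_opt))


class TestEnumeration:
    def test_ethane_counts(self, toy):
        ics = mv.enumerate_internal_coords(toy("ethane"))
        assert (len(ics.bonds), len(ics.angles), len(ics.torsions)) \
            == (7, 12, 9)

    def test_water_counts(self, toy):
        ics = mv.enumerate_internal_coords(toy("water"))
        assert (len(ics.bonds), len(ics.angles), len(ics.torsions)) \
            == (2, 1, 0)

    def test_single_atom_all_empty(self):
        mol = mv.MoleculeGraph([mv.AtomRecord("He")], [])
        ics = mv.enumerate_internal_coords(mol)
        assert ics.bonds == () and ics.angles == () and ics.torsions == ()

    def test_no_duplicates_modulo_reversal(self, toys):
        for mol in toys:
            ics = mv.enumerate_internal_coords(mol)
            assert len({tuple(sorted(b)) for b in ics.bonds}) \
                == len(ics.bonds)
            assert len({(min(a, c), j, max(a, c))
                        for a, j, c in ics.angles}) == len(ics.angles)
            canon = {min(t, t[::-1]) for t in ics.torsions}
            assert len(canon) == len(ics.torsions)


class TestDiffOperators:
    def test_bond_diff_arithmetic(self, toy):
        wat = toy("water")
        init = np.array([[0, 0, 0], [1.54, 0, 0], [0, 1.0, 0]], dtype=float)
        opt = np.array([[0, 0, 0], [1.50, 0, 0], [0, 1.0, 0]], dtype=float)
        pair = pair_from_coords(wat, init, opt)
        assert mv.bond_length_diff(pair, (0, 1)) == pytest.approx(0.04)
        assert mv.bond_length_diff(pair, (0, 2)) == 0.0
        swapped = pair_from_coords(wat, opt, init)
        assert mv.bond_length_diff(swapped, (0, 1)) == pytest.approx(0.04)

    def test_coincident_atoms_degenerate(self, toy):
        wat = toy("water")
        init = np.zeros((3, 3))
        pair = pair_from_coords(wat, init, init)
        with pytest.raises(DegenerateGeometryError):
            mv.bond_length_diff(pair, (0, 1))

    @pytest.mark.parametrize("t_init,t_opt,expected", [
        (100.0, 95.0, 5.0),
        (1.0, 179.0, 2.0),    # wrap case forced by the formula
        (45.0, 135.0, 90.0),  # maximum
    ])
    def test_angle_diff_cases(self, toy, t_init, t_opt, expected):
        _, pair = water_pair(toy, t_init, t_opt)
        assert mv.angle_diff(pair, (1, 0, 2)) == pytest.approx(expected,
                                                               abs=1e-9)

    @pytest.mark.parametrize("p_init,p_opt,expected", [
        (350.0, 10.0, 20.0),
        (-180.0, 180.0, 0.0),
        (0.0, 180.0, 180.0),
    ])
    def test_torsion_diff_cases(self, toy, p_init, p_opt, expected):
        eth = toy("ethane")

        def coords(phi):
            c = eth.coords.copy()
            # rotate one methyl group about the C–C axis to dihedral phi
            base = dihedral_angle(c, 2, 0, 1, 5)
            axis = c[1] - c[0]
            from moleval.fixtures import _rotate
            idx = [1, 5, 6, 7]
            c[idx] = _rotate(c[idx], c[0], axis, phi - base)
            return c
        pair = pair_from_coords(eth, coords(p_init), coords(p_opt))
        assert mv.torsion_diff(pair, (2, 0, 1, 5)) == pytest.approx(
            expected, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ranges_and_rigid_motion_invariance(self, seed):
        """Δθ ∈ [0, 90], Δφ ∈ [0, 180]; both (and Δr) are invariant to any
        rigid rotation+translation applied to either coordinate set."""
        rng = np.random.default_rng(seed)
        mol = mv.chain_molecule(4)
        n = mol.n_atoms
        init = mol.coords + rng.normal(scale=0.3, size=(n, 3))
        opt = mol.coords + rng.normal(scale=0.3, size=(n, 3))
        pair = pair_from_coords(mol, init, opt)
        ics = mv.enumerate_internal_coords(mol)

        # random rigid motion of the initial frame
        rot = random_rotation(rng)
        shift = rng.normal(scale=5.0, size=3)
        moved = pair_from_coords(mol, init @ rot.T + shift, opt)

        for angle in ics.angles:
            d = mv.angle_diff(pair, angle)
            assert 0.0 <= d <= 90.0
            assert mv.angle_diff(moved, angle) == pytest.approx(d, abs=1e-8)
        for torsion in ics.torsions:
            d = mv.torsion_diff(pair, torsion)
            assert 0.0 <= d <= 180.0
            assert mv.torsion_diff(moved, torsion) == pytest.approx(d,
                                                                    abs=1e-8)
        for bond in ics.bonds:
            assert mv.bond_length_diff(moved, bond) == pytest.approx(
                mv.bond_length_diff(pair, bond), abs=1e-8)


class TestDeltaE:
    def test_identity_backend_zero(self, toy):
        pair = IdentityBackend().optimize(toy("water"))
        assert mv.delta_e_relax(pair) == 0.0

    def test_harmonic_closed_form(self, toy):
        wat = toy("water")
        ref = wat.coords
        k = 3.7
        backend = HarmonicBackend(reference={"water": ref}, k=k)
        x = 0.25
        displaced = ref + np.array([[x, 0, 0], [0, 0, 0], [0, 0, 0]])
        pair = backend.optimize(wat.with_coords(displaced))
        assert mv.delta_e_relax(pair) == pytest.approx(0.5 * k * x * x)

    def test_signed_antisymmetry(self, toy):
        wat = toy("water")
        c = wat.coords
        pair = pair_from_coords(wat, c, c, e_init=5.0, e_opt=2.0)
        rev = pair_from_coords(wat, c, c, e_init=2.0, e_opt=5.0)
        assert mv.delta_e_relax(pair) == -mv.delta_e_relax(rev)


class TestBenchmark:
    def test_identity_backend_all_zero(self, toys):
        summary = mv.benchmark(toys, IdentityBackend())
        assert summary.mean_bond_dev == 0.0
        assert summary.mean_angle_dev == 0.0
        assert summary.mean_torsion_dev == 0.0
        assert summary.mean_dE_relax == 0.0
        assert summary.n_molecules == len(toys)

    def test_perturbation_recovery_per_class(self):
        chains = [mv.chain_molecule(n) for n in (3, 4, 6)]
        cases = [
            ("bond", mv.FixtureSpec(bond_delta=0.05, angle_delta=0,
                                    torsion_delta=0)),
            ("angle", mv.FixtureSpec(bond_delta=0, angle_delta=5.0,
                                     torsion_delta=0)),
            ("torsion", mv.FixtureSpec(bond_delta=0, angle_delta=0,
                                       torsion_delta=10.0)),
        ]
        for label, spec in cases:
            pairs = mv.perturbed_pairs(chains, spec)
            backend = HarmonicBackend(k=spec.harmonic_k)
            summary = mv.benchmark([p.topology for p in pairs], backend)
            means = {"bond": summary.mean_bond_dev,
                     "angle": summary.mean_angle_dev,
                     "torsion": summary.mean_torsion_dev}
            expected = {"bond": 0.05, "angle": 5.0, "torsion": 10.0}[label]
            assert means.pop(label) == pytest.approx(expected, abs=1e-6)
            for other, value in means.items():
                assert value == pytest.approx(0.0, abs=1e-6), (label, other)

    def test_harmonic_mean_dE_matches_closed_form(self, toy):
        k = 2.0
        wat = toy("water")
        ref = wat.coords
        displacements = [0.1, 0.2, 0.3]
        mols = []
        for m, x in enumerate(displacements):
            moved = wat.with_coords(ref + [[x, 0, 0], [0, 0, 0], [0, 0, 0]])
            moved.name = f"water-{m}"
            moved.provenance["reference_coords"] = ref.tolist()
            mols.append(moved)
        summary = mv.benchmark(mols, HarmonicBackend(k=k))
        expected = np.mean([0.5 * k * x * x for x in displacements])
        assert summary.mean_dE_relax == pytest.approx(expected)
        assert summary.median_dE_relax == pytest.approx(0.5 * k * 0.2 ** 2)

    def test_valid_only_filters_by_vc(self, toys, invalid_set):
        mols = list(toys) + list(invalid_set)
        summary = mv.benchmark(mols, IdentityBackend(), valid_only=True)
        assert summary.n_molecules == len(toys)

    def test_failure_budget_enforced(self, toys):
        class FailingBackend(IdentityBackend):
            id = "flaky"

            def optimize(self, mol):
                raise BackendError("nope")

        with pytest.raises(BenchmarkError, match="not representative"):
            mv.benchmark(toys, FailingBackend())

    def test_split_protocol_shapes(self, toys):
        mols = toys * 10  # 160 molecules
        summary = mv.benchmark(mols, IdentityBackend(), n_splits=5,
                               split_size=30, seed=0)
        assert summary.n_splits == 5
        assert summary.n_molecules == 150
        assert summary.bond_dev_std == 0.0

    def test_permutation_invariance_single_split(self, small_corpus):
        mols = [m for m in small_corpus if m.has_coords][:30]
        s1 = mv.benchmark(mols, IdentityBackend())
        s2 = mv.benchmark(list(reversed(mols)), IdentityBackend())
        assert s1.mean_bond_dev == s2.mean_bond_dev
        assert s1.mean_dE_relax == s2.mean_dE_relax
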