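"""Shipped reference tables, table construction, diffing and serialization."""

import json

import pytest

import moleval as mv
from moleval.graph import AtomRecord, MoleculeGraph
from moleval.tables import TableFormatError
from moleval.valency import ValencyMode


class TestShippedTables:
    def test_corrected_spot_values(self, corrected):
        assert corrected.allowed("C", 0) == {4}
        assert corrected.allowed("N", 0) == {3}
        assert corrected.allowed("O", -1) == {1}
        assert corrected.allowed("S", 0) == {2, 3, 6}
        assert corrected.allowed("S", 3) == {2, 5}
        assert corrected.allowed("P", 0) == {3, 5}
        assert corrected.allowed("Bi", 2) == {5}
        assert max(corrected.allowed("S", 0)) == 6

    def test_legacy_contains_implausible_entries(self, legacy):
        assert legacy.allowed("C", 0) == {3, 4}
        assert legacy.allowed("N", 0) == {2, 3}
        assert legacy.allowed("N", 1) == {2, 3, 4}
        assert legacy.allowed("H", 1) == {0}
        assert legacy.allowed("H", -1) == {0}
        assert legacy.allowed("F", -1) == {0}
        # italic-marked entries were missing historically: excluded
        assert legacy.allowed("B", -1) is None
        assert legacy.allowed("Si", 1) is None
        assert legacy.allowed("I", 2) is None
        assert legacy.allowed("S", -1) == {3}

    def test_aromatic_spot_values(self, aromatic_table):
        assert aromatic_table.allowed("C", 2, 0) == {1, 2}
        assert aromatic_table.allowed("C", 3, 0) == {0}
        assert aromatic_table.allowed("N", 2, 0) == {0, 1}
        assert aromatic_table.allowed("N", 2, 1) == {0, 1, 2}
        assert aromatic_table.allowed("S", 2, 0) == {0}
        assert aromatic_table.allowed("O", 2, 0) == {0}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            mv.load_shipped_table("bogus")

    def test_aromatic_n0_consistency_with_corrected(self, aromatic_table,
                                                    corrected):
        report = mv.aromatic_consistency_report(aromatic_table, corrected)
        # shared keys agree exactly
        assert report.differing == {}
        # known, deliberately unreconciled discrepancy: (O, -1)
        assert set(report.only_in_b) == {("O", -1)}
        assert report.only_in_a == {}


class TestBuildTables:
    def test_small_molecule_dataset(self, toy):
        table = mv.build_simple_table(
            [toy("methane"), toy("ammonia"), toy("water")])
        assert table.entries == {
            ("C", 0): frozenset({4}), ("N", 0): frozenset({3}),
            ("O", 0): frozenset({2}), ("H", 0): frozenset({1})}

    def test_isolated_h_plus_corrupts_table(self, invalid_set):
        frag = next(m for m in invalid_set if "h-plus" in m.name)
        table = mv.build_simple_table([frag])
        assert table.allowed("H", 1) == {0}

    def test_empty_dataset(self):
        assert len(mv.build_simple_table([])) == 0

    def test_deterministic_under_input_order(self, toys):
        a = mv.build_simple_table(toys)
        b = mv.build_simple_table(list(reversed(toys)))
        assert a == b

    def test_kekulization_failures_counted(self, invalid_set):
        triple_arom = next(m for m in invalid_set if "triple-aromatic" in m.name)
        table = mv.build_simple_table([triple_arom])
        assert table.meta["n_kekulization_failures"] == 1
        assert len(table) == 0

    def test_aromatic_table_from_benzene(self, toy):
        t = mv.build_aromatic_table([toy("benzene/aromatic")])
        assert t.entries == {("C", 2, 0): frozenset({1}),
                             ("H", 0, 0): frozenset({1})}

    def test_aromatic_table_from_triphenylene(self, toy):
        t = mv.build_aromatic_table([toy("triphenylene/aromatic")])
        assert t.allowed("C", 2, 0) == {1}
        assert t.allowed("C", 3, 0) == {0}

    def test_aromatic_table_from_methane(self, toy):
        t = mv.build_aromatic_table([toy("methane")])
        assert t.allowed("C", 0, 0) == {4}

    def test_monotonicity_under_dataset_growth(self, toys, small_corpus):
        small = mv.build_simple_table(toys)
        grown = mv.build_simple_table(list(toys) + list(small_corpus))
        for key, vals in small.entries.items():
            assert vals <= grown.entries[key]

    def test_self_consistency_every_atom_stable_vs_own_table(self, toys):
        table = mv.build_simple_table(toys, ValencyMode.KEKULIZED)
        for mol in toys:
            verdict = mv.classify_molecule(mol, table, ValencyMode.KEKULIZED)
            assert verdict.molecule_stable, mol.name
        arom = mv.build_aromatic_table(toys)
        for mol in toys:
            assert mv.classify_molecule(mol, arom).molecule_stable, mol.name

    def test_self_consistency_limit_of_1_5_mode(self, toys):
        """Under 1.5-aromatic counting, ring-fusion atoms get non-integer
        valencies that an integer-valued table cannot contain, so
        self-consistency holds only for non-fused datasets — the very
        failure of the 1.5 approximation the aromatic table fixes."""
        no_fusion = [m for m in toys
                     if all(t.n_arom < 3
                            for t in mv.molecule_aromatic_tuples(m))]
        assert no_fusion
        table = mv.build_simple_table(no_fusion, ValencyMode.AROM_1_5)
        for mol in no_fusion:
            verdict = mv.classify_molecule(mol, table, ValencyMode.AROM_1_5)
            assert verdict.molecule_stable, mol.name
        fused = next(m for m in toys if "naphthalene/aromatic" == m.name)
        table_all = mv.build_simple_table(toys, ValencyMode.AROM_1_5)
        verdict = mv.classify_molecule(fused, table_all, ValencyMode.AROM_1_5)
        assert not verdict.molecule_stable


class TestDiffTables:
    def test_legacy_vs_corrected_includes_carbon_3(self, legacy, corrected):
        diff = mv.diff_tables(legacy, corrected)
        assert diff.differing[("C", 0)] == (frozenset({3, 4}),
                                            frozenset({4}))
        assert diff.differing[("N", 0)] == (frozenset({2, 3}),
                                            frozenset({3}))

    def test_self_diff_empty(self, corrected):
        assert mv.diff_tables(corrected, corrected).empty

    def test_diff_against_empty(self, corrected):
        empty = mv.ValencyTable({}, label="empty")
        diff = mv.diff_tables(empty, corrected)
        assert diff.only_in_b == corrected.entries
        assert not diff.only_in_a and not diff.differing

    def test_kind_mismatch_rejected(self, corrected, aromatic_table):
        with pytest.raises(ValueError):
            mv.diff_tables(corrected, aromatic_table)


class TestSerialization:
    @pytest.mark.parametrize("name", ["corrected", "legacy", "aromatic"])
    def test_round_trip(self, name, tmp_path):
        t = mv.load_shipped_table(name)
        path = tmp_path / f"{name}.json"
        mv.save_table(t, path)
        back = mv.load_table(path)
        assert back == t and back.label == t.label

    def test_negative_valency_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(
            {"kind": "simple", "label": "x", "entries": {"C|0": [-1]}}))
        with pytest.raises(TableFormatError, match="C\\|0"):
            mv.load_table(path)

    def test_empty_allowed_set_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(
            {"kind": "aromatic", "label": "x", "entries": {"C|2|0": []}}))
        with pytest.raises(TableFormatError):
            mv.load_table(path)

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"kind": "weird", "entries": {}}))
        with pytest.raises(TableFormatError):
            mv.load_table(path)

    def test_output_bytes_stable(self, corrected, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        mv.save_table(corrected, p1)
        mv.save_table(mv.load_shipped_table("corrected"), p2)
        assert p1.read_bytes() == p2.read_bytes()
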