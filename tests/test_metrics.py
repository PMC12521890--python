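"""Stability / validity metrics and the split-wise uncertainty protocol."""

import math

import numpy as np
import pytest

import moleval as mv
from moleval.metrics import UndefinedMetricError, is_valid_and_connected
from moleval.valency import ValencyMode


class TestClassifyAtom:
    def test_triphenylene_fusion_carbon_1_5_vs_simple_table(self, toy,
                                                            corrected,
                                                            aromatic_table):
        tri = toy("triphenylene/aromatic")
        fusion = next(i for i, t
                      in enumerate(mv.molecule_aromatic_tuples(tri))
                      if t.n_arom == 3)
        ok, reason = mv.classify_atom(tri, fusion, corrected,
                                      ValencyMode.AROM_1_5)
        assert not ok and reason.observed == "9/2"
        ok, _ = mv.classify_atom(tri, fusion, aromatic_table)
        assert ok

    def test_undervalent_nitrogen_legacy_vs_corrected(self, invalid_set, legacy,
                                                corrected):
        n2_mol = next(m for m in invalid_set if "nitrogen-two" in m.name)
        assert mv.classify_atom(n2_mol, 0, legacy, ValencyMode.KEKULIZED)[0]
        ok, reason = mv.classify_atom(n2_mol, 0, corrected,
                                      ValencyMode.KEKULIZED)
        assert not ok and reason.element == "N"

    def test_non_kekulizable_molecule_fully_unstable(self, invalid_set,
                                                     corrected):
        triple_arom = next(m for m in invalid_set if "triple-aromatic" in m.name)
        verdict = mv.classify_molecule(triple_arom, corrected,
                                       ValencyMode.KEKULIZED)
        assert not any(verdict.atom_flags)
        assert all("non-kekulizable" in r.detail for r in verdict.reasons)

    def test_missing_key_means_unstable(self, corrected):
        hplus = mv.MoleculeGraph([mv.AtomRecord("H", 1)], [])
        ok, reason = mv.classify_atom(hplus, 0, corrected,
                                      ValencyMode.KEKULIZED)
        assert not ok


class TestMoleculeStability:
    def test_self_consistent_fixtures_score_one(self, toys):
        table = mv.build_simple_table(toys)
        ms, as_ = mv.molecule_stability(toys, table)
        assert ms.value == 1.0 and as_.value == 1.0

    def test_half_bad_collection(self, toy, invalid_set, corrected):
        carbene = next(m for m in invalid_set if "carbene" in m.name)
        mols = [toy("water")] * 5 + [carbene] * 5
        ms, as_ = mv.molecule_stability(mols, corrected)
        assert ms.value == 0.5
        assert as_.value > ms.value  # only the carbon atoms are bad

    def test_ms_never_exceeds_as(self, small_corpus, corrected,
                                 aromatic_table):
        ms, as_ = mv.molecule_stability(small_corpus, corrected)
        assert ms.value <= as_.value
        ms2, as2 = mv.molecule_stability(small_corpus, aromatic_table)
        assert ms2.value <= as2.value

    def test_legacy_table_never_scores_below_corrected(self, small_corpus,
                                                       legacy, corrected):
        # On every (element, charge) the corpus exercises, the legacy
        # allowed set is a superset of the corrected one (checked via
        # diff_tables), so legacy MS can only be inflated.
        diff = mv.diff_tables(legacy, corrected)
        exercised = {(a.element, a.formal_charge)
                     for m in small_corpus for a in m.atoms}
        for key in exercised & set(diff.differing):
            lv, cv = diff.differing[key]
            assert lv >= cv, key
        ms_l, _ = mv.molecule_stability(small_corpus, legacy)
        ms_c, _ = mv.molecule_stability(small_corpus, corrected)
        assert ms_l.value >= ms_c.value

    def test_table_growth_monotonicity(self, small_corpus, corrected):
        grown = mv.ValencyTable(
            {**corrected.entries,
             ("C", 0): frozenset({2, 3, 4}),
             ("N", 0): frozenset({2, 3}),
             ("H", 1): frozenset({0})},
            label="grown")
        ms_g, as_g = mv.molecule_stability(small_corpus, grown)
        ms_c, as_c = mv.molecule_stability(small_corpus, corrected)
        assert ms_g.value >= ms_c.value
        assert as_g.value >= as_c.value

    def test_legacy_mode_scores_higher_than_1_5_on_legacy_table(
            self, small_corpus, legacy):
        """The historical pairing (legacy counting + legacy table) inflates
        stability relative to honest 1.5 counting against the same table —
        the direction of the published 'original' vs '1.5 Arom' collapse."""
        aromatic_mols = [m for m in small_corpus
                         if any(b.order is mv.BondOrder.AROMATIC
                                for b in m.bonds)]
        ms_legacy, _ = mv.molecule_stability(aromatic_mols, legacy,
                                             ValencyMode.AROM_1_LEGACY)
        ms_15, _ = mv.molecule_stability(aromatic_mols, legacy,
                                         ValencyMode.AROM_1_5)
        assert ms_legacy.value > ms_15.value

    def test_order_invariance(self, small_corpus, corrected):
        ms_a, _ = mv.molecule_stability(small_corpus, corrected)
        ms_b, _ = mv.molecule_stability(list(reversed(small_corpus)),
                                        corrected)
        assert ms_a.value == ms_b.value

    def test_empty_input_is_undefined(self, corrected):
        with pytest.raises(UndefinedMetricError):
            mv.molecule_stability([], corrected)


class TestValidityAndConnected:
    def test_all_benzene_scores_one(self, toy):
        rep = mv.validity_and_connected([toy("benzene/aromatic")] * 10)
        assert rep.value == 1.0

    def test_one_fragmented_of_ten(self, toy):
        frag = mv.fragmented_molecule_set()[0]
        rep = mv.validity_and_connected([toy("water")] * 9 + [frag])
        assert rep.value == 0.9

    def test_triple_arom_counts_invalid(self, invalid_set):
        triple_arom = next(m for m in invalid_set if "triple-aromatic" in m.name)
        assert not is_valid_and_connected(triple_arom)

    def test_empty_input_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mv.validity_and_connected([])


class TestSplitProtocol:
    @staticmethod
    def _label_mols(p, n, seed):
        rng = np.random.default_rng(seed)
        flags = rng.random(n) < p
        return [mv.MoleculeGraph([], [], f"m{i}", {"ok": bool(f)})
                for i, f in enumerate(flags)]

    @staticmethod
    def _metric(mols):
        return float(np.mean([m.provenance["ok"] for m in mols]))

    def test_constant_metric_gives_zero_std(self, toy):
        mols = [toy("water")] * 50
        rep = mv.evaluate_with_splits(mols, lambda ms: 1.0, n_splits=5,
                                      split_size=10)
        assert rep.value == 1.0 and rep.uncertainty == 0.0

    def test_splits_are_disjoint_and_reproducible(self):
        mols = self._label_mols(0.5, 5000, seed=1)
        seen = []
        rep1 = mv.evaluate_with_splits(mols, self._metric, 5, 1000, seed=11)
        rep2 = mv.evaluate_with_splits(mols, self._metric, 5, 1000, seed=11)
        rep3 = mv.evaluate_with_splits(mols, self._metric, 5, 1000, seed=12)
        assert rep1.value == rep2.value and rep1.uncertainty == rep2.uncertainty
        assert rep3.value != rep1.value or rep3.uncertainty != rep1.uncertainty

    def test_bernoulli_std_matches_binomial_closed_form(self):
        """5 splits of 1000 Bernoulli(0.9) verdicts: the split std estimates
        sqrt(p(1-p)/1000), within generous Monte-Carlo tolerance."""
        mols = self._label_mols(0.9, 5000, seed=42)
        rep = mv.evaluate_with_splits(mols, self._metric, 5, 1000, seed=0)
        theory = math.sqrt(0.9 * 0.1 / 1000)
        assert abs(rep.value - 0.9) < 3 * math.sqrt(0.9 * 0.1 / 5000)
        assert theory / 3 < rep.uncertainty < 3 * theory

    def test_insufficient_molecules_sizing_error(self, toy):
        with pytest.raises(UndefinedMetricError, match="5000"):
            mv.evaluate_with_splits([toy("water")] * 100, lambda ms: 1.0,
                                    n_splits=5, split_size=1000)
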