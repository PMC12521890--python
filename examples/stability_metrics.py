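"""Score a molecule collection with corrected vs legacy stability metrics.

Builds a labelled synthetic corpus (90% chemically sound molecules, 8%
valency-defect molecules, 2% fragmented records), then computes molecule
stability (MS), atom stability (AS) and validity-and-connectedness (V&C)
under the corrected reference table, the aromatic-tuple table, and the
flawed legacy artifacts, using the 5×1000-split uncertainty protocol.
"""

from moleval import (FixtureSpec, ValencyMode, corpus, evaluate_with_splits,
                     load_shipped_table, molecule_stability,
                     validity_and_connected)

spec = FixtureSpec(seed=0, n_molecules=5000, fraction_invalid=0.08,
                   fraction_fragmented=0.02)
mols = corpus(spec)

corrected = load_shipped_table("corrected")
aromatic = load_shipped_table("aromatic")
legacy = load_shipped_table("legacy")

print(f"corpus: {len(mols)} molecules "
      f"(labels: {spec.fraction_invalid:.0%} invalid, "
      f"{spec.fraction_fragmented:.0%} fragmented)\n")

for label, table, mode in [
        ("corrected table, kekulized valency", corrected,
         ValencyMode.KEKULIZED),
        ("aromatic-tuple table", aromatic, ValencyMode.KEKULIZED),
        ("legacy table, legacy 1.0-aromatic counting (historical bug)",
         legacy, ValencyMode.AROM_1_LEGACY)]:
    ms = evaluate_with_splits(
        mols, lambda ms_: molecule_stability(ms_, table, mode)[0].value,
        n_splits=5, split_size=1000, seed=0)
    print(f"{label}:\n  MS = {ms.value:.3f} ± {ms.uncertainty:.3f}")

vc = evaluate_with_splits(mols, lambda ms_: validity_and_connected(ms_).value,
                          n_splits=5, split_size=1000, seed=0)
print(f"\nV&C = {vc.value:.3f} ± {vc.uncertainty:.3f}")
print("\nMS under the corrected table tracks the injected defect rate; the "
      "legacy pairing overstates stability because its lookup table admits "
      "impossible valencies. V&C drops further: fragmented records are "
      "well-valenced but not connected.")
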