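"""Shipped empirical valency reference tables derived from curated GEOM-drugs.

Three references are bundled:

``CORRECTED``
    Chemically accurate allowed valencies by (element, formal charge), built
    from the fragment-filtered, kekulized dataset.  Valencies count every
    covalent bond, explicit hydrogens included.
``LEGACY``
    The historically circulated table, reproduced verbatim *including* its
    chemically implausible entries (e.g. neutral carbon with valency 3,
    neutral nitrogen with valency 2) and *excluding* entries that were
    missing from historical tables even though the dataset contains them.
    Shipped only so that published (inflated) stability numbers can be
    reproduced deliberately.
``AROMATIC``
    Aromatic-aware allowed combinations keyed by
    (element, number of incident aromatic bonds, formal charge), with the
    allowed values being v_other — the total bond order of the atom's
    non-aromatic bonds.
"""

from __future__ import annotations

# (element, formal_charge) -> frozenset of allowed valencies
CORRECTED: dict[tuple[str, int], frozenset[int]] = {
    ("H", 0): frozenset({1}),
    ("B", -1): frozenset({4}),
    ("B", 0): frozenset({3}),
    ("C", -1): frozenset({3}),
    ("C", 0): frozenset({4}),
    ("C", 1): frozenset({3}),
    ("N", -2): frozenset({1}),
    ("N", -1): frozenset({2}),
    ("N", 0): frozenset({3}),
    ("N", 1): frozenset({4}),
    ("O", -1): frozenset({1}),
    ("O", 0): frozenset({2}),
    ("O", 1): frozenset({3}),
    ("F", 0): frozenset({1}),
    ("Si", 0): frozenset({4}),
    ("Si", 1): frozenset({5}),
    ("P", 0): frozenset({3, 5}),
    ("P", 1): frozenset({4}),
    ("S", -1): frozenset({1}),
    ("S", 0): frozenset({2, 3, 6}),
    ("S", 1): frozenset({3}),
    ("S", 2): frozenset({4}),
    ("S", 3): frozenset({2, 5}),
    ("Cl", 0): frozenset({1}),
    ("Cl", 1): frozenset({2}),
    ("Br", 0): frozenset({1}),
    ("Br", 1): frozenset({2}),
    ("I", 0): frozenset({1}),
    ("I", 1): frozenset({2}),
    ("I", 2): frozenset({3}),
    ("Bi", 0): frozenset({3}),
    ("Bi", 2): frozenset({5}),
}

# Historical table: bold (implausible but present) entries kept, italic
# (observed but historically missing) entries dropped.
LEGACY: dict[tuple[str, int], frozenset[int]] = {
    ("H", -1): frozenset({0}),
    ("H", 0): frozenset({1}),
    ("H", 1): frozenset({0}),
    ("B", 0): frozenset({3}),
    ("C", -1): frozenset({3}),
    ("C", 0): frozenset({3, 4}),
    ("C", 1): frozenset({3}),
    ("N", -2): frozenset({1}),
    ("N", -1): frozenset({2}),
    ("N", 0): frozenset({2, 3}),
    ("N", 1): frozenset({2, 3, 4}),
    ("O", -1): frozenset({1}),
    ("O", 0): frozenset({2}),
    ("O", 1): frozenset({3}),
    ("F", -1): frozenset({0}),
    ("F", 0): frozenset({1}),
    ("Al", 0): frozenset({3}),
    ("Si", 0): frozenset({4}),
    ("P", 0): frozenset({3, 5}),
    ("P", 1): frozenset({4}),
    ("S", -1): frozenset({3}),
    ("S", 0): frozenset({2, 6}),
    ("S", 1): frozenset({2, 3}),
    ("S", 2): frozenset({4}),
    ("S", 3): frozenset({5}),
    ("Cl", 0): frozenset({1}),
    ("Cl", 1): frozenset({2}),
    ("Br", 0): frozenset({1}),
    ("Br", 1): frozenset({2}),
    ("Se", 0): frozenset({2, 4, 6}),
    ("I", 0): frozenset({1}),
    ("I", 1): frozenset({2}),
    ("Hg", 0): frozenset({1, 2}),
    ("Bi", 0): frozenset({3}),
    ("Bi", 2): frozenset({5}),
}

# (element, n_arom, formal_charge) -> frozenset of allowed v_other values
AROMATIC: dict[tuple[str, int, int], frozenset[int]] = {
    ("H", 0, 0): frozenset({1}),
    ("B", 0, -1): frozenset({4}),
    ("B", 0, 0): frozenset({3}),
    ("C", 0, -1): frozenset({3}),
    ("C", 0, 0): frozenset({4}),
    ("C", 0, 1): frozenset({3}),
    ("C", 2, -1): frozenset({1}),
    ("C", 2, 0): frozenset({1, 2}),
    ("C", 2, 1): frozenset({1}),
    ("C", 3, -1): frozenset({0}),
    ("C", 3, 0): frozenset({0}),
    ("C", 3, 1): frozenset({0}),
    ("N", 0, -2): frozenset({1}),
    ("N", 0, -1): frozenset({2}),
    ("N", 0, 0): frozenset({3}),
    ("N", 0, 1): frozenset({4}),
    ("N", 2, -1): frozenset({0}),
    ("N", 2, 0): frozenset({0, 1}),
    ("N", 2, 1): frozenset({0, 1, 2}),
    ("N", 3, 0): frozenset({0}),
    ("N", 3, 1): frozenset({0}),
    ("O", 0, 0): frozenset({2}),
    ("O", 0, 1): frozenset({3}),
    ("O", 2, 0): frozenset({0}),
    ("F", 0, 0): frozenset({1}),
    ("Si", 0, 0): frozenset({4}),
    ("Si", 0, 1): frozenset({5}),
    ("P", 0, 0): frozenset({3, 5}),
    ("P", 0, 1): frozenset({4}),
    ("S", 0, -1): frozenset({1}),
    ("S", 0, 0): frozenset({2, 3, 6}),
    ("S", 0, 1): frozenset({3}),
    ("S", 0, 2): frozenset({4}),
    ("S", 0, 3): frozenset({2, 5}),
    ("S", 2, 0): frozenset({0}),
    ("S", 2, 1): frozenset({0, 1}),
    ("S", 3, 1): frozenset({0}),
    ("Cl", 0, 0): frozenset({1}),
    ("Cl", 0, 1): frozenset({2}),
    ("Br", 0, 0): frozenset({1}),
    ("Br", 0, 1): frozenset({2}),
    ("I", 0, 0): frozenset({1}),
    ("I", 0, 1): frozenset({2}),
    ("I", 0, 2): frozenset({3}),
    ("Bi", 0, 0): frozenset({3}),
    ("Bi", 0, 2): frozenset({5}),
}

#: Elements appearing in any shipped table; inputs with other elements are
#: flagged (not dropped) by the SDF reader.
SUPPORTED_ELEMENTS: frozenset[str] = frozenset(
    {k[0] for k in CORRECTED} | {k[0] for k in LEGACY} | {k[0] for k in AROMATIC}
)
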