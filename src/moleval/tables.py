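"""Valency lookup tables: the stability reference.

A :class:`ValencyTable` maps ``(element, formal_charge)`` to the set of
allowed integer valencies; an :class:`AromaticValencyTable` maps
``(element, n_arom, formal_charge)`` to allowed ``v_other`` values.  Tables
can be built from any dataset (the definition of "valid valency" is "one
observed in the training data"), loaded from JSON, or taken from the three
shipped references (corrected, legacy, aromatic).

The JSON dialect is deliberately diff-able and bit-stable: string keys
``"element|charge"`` / ``"element|n_arom|charge"``, sorted integer arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from . import _tables_data
from .graph import KekulizationError, MoleculeGraph
from .valency import ValencyMode, aromatic_tuple, molecule_valencies

__all__ = [
    "ValencyTable",
    "AromaticValencyTable",
    "TableDiff",
    "TableFormatError",
    "load_shipped_table",
    "build_simple_table",
    "build_aromatic_table",
    "diff_tables",
    "save_table",
    "load_table",
    "aromatic_consistency_report",
]

SimpleKey = tuple[str, int]
AromaticKey = tuple[str, int, int]


class TableFormatError(ValueError):
    pass


@dataclass
class ValencyTable:
    """Allowed valencies keyed by (element, formal charge)."""

    entries: dict[SimpleKey, frozenset[int]]
    label: str = ""
    meta: dict = field(default_factory=dict)

    kind = "simple"

    def allowed(self, element: str, charge: int) -> Optional[frozenset[int]]:
        return self.entries.get((element, charge))

    def permits(self, element: str, charge: int, valency) -> bool:
        """Exact membership: a non-integer valency is never permitted
        (9/2 does not round to 4)."""
        allowed = self.allowed(element, charge)
        if allowed is None:
            return False
        return valency in allowed  # Fraction == int is exact

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ValencyTable)
                and self.entries == other.entries)


@dataclass
class AromaticValencyTable:
    """Allowed v_other values keyed by (element, n_arom, formal charge)."""

    entries: dict[AromaticKey, frozenset[int]]
    label: str = ""
    meta: dict = field(default_factory=dict)

    kind = "aromatic"

    def allowed(self, element: str, n_arom: int,
                charge: int) -> Optional[frozenset[int]]:
        return self.entries.get((element, n_arom, charge))

    def permits(self, element: str, n_arom: int, charge: int,
                v_other: int) -> bool:
        allowed = self.allowed(element, n_arom, charge)
        return allowed is not None and v_other in allowed

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (isinstance(other, AromaticValencyTable)
                and self.entries == other.entries)


AnyTable = Union[ValencyTable, AromaticValencyTable]


def load_shipped_table(name: str) -> AnyTable:
    """One of the three bundled references: ``corrected`` and ``legacy``
    simple tables, or the ``aromatic`` tuple table.

    The legacy table reproduces historical behavior verbatim, chemically
    implausible entries included — required to replicate previously
    published stability numbers, and only for that.
    """
    if name == "corrected":
        return ValencyTable(dict(_tables_data.CORRECTED), label="corrected")
    if name == "legacy":
        return ValencyTable(dict(_tables_data.LEGACY), label="legacy")
    if name == "aromatic":
        return AromaticValencyTable(dict(_tables_data.AROMATIC), label="aromatic")
    raise ValueError(f"unknown shipped table {name!r}; "
                     "expected corrected|legacy|aromatic")


def build_simple_table(dataset: Iterable[MoleculeGraph],
                       mode: ValencyMode = ValencyMode.KEKULIZED,
                       label: str = "built") -> ValencyTable:
    """Record every observed (element, charge) → valency over the dataset.

    Non-integer valencies (possible under AROM_1_5) are recorded only when
    integral — the table stores integers by contract.  Molecules that fail
    kekulization under KEKULIZED are skipped and counted in
    ``table.meta['n_kekulization_failures']``; a properly curated input has
    none.  Output is deterministic regardless of input order.
    """
    entries: dict[SimpleKey, set[int]] = {}
    n_failures = 0
    skipped: list[str] = []
    for mol in dataset:
        try:
            valencies = molecule_valencies(mol, mode)
        except KekulizationError:
            n_failures += 1
            skipped.append(mol.name)
            continue
        for atom, av in zip(mol.atoms, valencies):
            if av.value.denominator != 1:
                continue
            entries.setdefault((atom.element, atom.formal_charge),
                               set()).add(int(av.value))
    table = ValencyTable(
        {k: frozenset(v) for k, v in sorted(entries.items())}, label=label)
    table.meta["mode"] = mode.value
    table.meta["n_kekulization_failures"] = n_failures
    if skipped:
        table.meta["skipped"] = skipped
    return table


def build_aromatic_table(dataset: Iterable[MoleculeGraph],
                         label: str = "built-aromatic") -> AromaticValencyTable:
    """Record every observed (element, n_arom, charge) → v_other.  No
    kekulization involved; operates on the graphs as given."""
    entries: dict[AromaticKey, set[int]] = {}
    for mol in dataset:
        for i, atom in enumerate(mol.atoms):
            t = aromatic_tuple(mol, i)
            entries.setdefault((atom.element, t.n_arom, atom.formal_charge),
                               set()).add(t.v_other)
    return AromaticValencyTable(
        {k: frozenset(v) for k, v in sorted(entries.items())}, label=label)


@dataclass(frozen=True)
class TableDiff:
    only_in_a: dict
    only_in_b: dict
    differing: dict  # key -> (set_a, set_b)

    @property
    def empty(self) -> bool:
        return not (self.only_in_a or self.only_in_b or self.differing)


def diff_tables(a: AnyTable, b: AnyTable) -> TableDiff:
    """Symmetric, exhaustive difference between two tables of the same kind."""
    if a.kind != b.kind:
        raise ValueError(f"cannot diff a {a.kind} table against a {b.kind} table")
    only_a = {k: a.entries[k] for k in a.entries.keys() - b.entries.keys()}
    only_b = {k: b.entries[k] for k in b.entries.keys() - a.entries.keys()}
    differing = {k: (a.entries[k], b.entries[k])
                 for k in a.entries.keys() & b.entries.keys()
                 if a.entries[k] != b.entries[k]}
    return TableDiff(only_a, only_b, differing)


def aromatic_consistency_report(aromatic: AromaticValencyTable,
                                simple: ValencyTable) -> TableDiff:
    """Compare the aromatic table restricted to n_arom = 0 against a simple
    table.  The shipped pair is *almost* consistent; known discrepancies
    (e.g. (O, −1) present in the corrected simple table but absent from the
    aromatic one) are reported here rather than silently reconciled."""
    restricted = ValencyTable(
        {(el, chg): vals for (el, n, chg), vals in aromatic.entries.items()
         if n == 0},
        label=f"{aromatic.label}|n_arom=0")
    return diff_tables(restricted, simple)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _key_to_str(key: tuple) -> str:
    return "|".join(str(p) for p in key)


def _str_to_key(s: str, kind: str) -> tuple:
    parts = s.split("|")
    want = 2 if kind == "simple" else 3
    if len(parts) != want:
        raise TableFormatError(f"malformed key {s!r} for kind {kind!r}")
    return (parts[0], *map(int, parts[1:]))


def save_table(table: AnyTable, path: Union[str, Path]) -> None:
    payload = {
        "kind": table.kind,
        "label": table.label,
        "entries": {_key_to_str(k): sorted(v)
                    for k, v in sorted(table.entries.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_table(path: Union[str, Path]) -> AnyTable:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TableFormatError(f"invalid JSON in {path}: {exc}") from exc
    kind = payload.get("kind")
    if kind not in ("simple", "aromatic"):
        raise TableFormatError(f"unknown table kind {kind!r}")
    entries = {}
    for key_s, vals in payload.get("entries", {}).items():
        key = _str_to_key(key_s, kind)
        if not vals:
            raise TableFormatError(f"empty allowed set for key {key_s!r}")
        for v in vals:
            if not isinstance(v, int) or v < 0:
                raise TableFormatError(
                    f"invalid valency {v!r} for key {key_s!r}")
        entries[key] = frozenset(vals)
    cls = ValencyTable if kind == "simple" else AromaticValencyTable
    return cls(entries, label=payload.get("label", ""))
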