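"""Binary structural fingerprints: 166-bit MACCS, 117-bit bonded atom pairs
(BAPS), and their 283-bit concatenation.

MACCS uses the public 166-key substructure dictionary (RDKit exposes it as a
167-slot vector whose slot 0 is unused; that slot is stripped here so emitted
fingerprints are exactly 166 bits, bit i corresponding to public MACCS key
i+1).

BAPS keys describe one bond each: two atom classes joined in a ring (``@``) or
non-ring (``!@``) bond context, written in the field's grammar, e.g. ``c-!@N``
(aromatic carbon bonded acyclically to aliphatic nitrogen). The original
117-key vocabulary is not publicly deposited, so the package ships a versioned
default table built from all 55 unordered pairs over the ten atom classes
{C, c, N, n, O, o, S, s, P, halogen [G7]} in both bond contexts (110 keys)
plus 7 generic keys (a-@a, a-!@a, A-@A, A-!@A, a-@A, a-!@A, a-[G7]),
totalling exactly 117. The table is a plain TSV resource and user-replaceable;
all downstream code reads lengths from the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

BAPS_RESOURCE = "baps_keys.tsv"


class Scheme(str, Enum):
    MACCS166 = "maccs"
    BAPS117 = "baps"
    COMBINED283 = "combined"


SCHEME_LENGTHS = {Scheme.MACCS166: 166, Scheme.BAPS117: 117, Scheme.COMBINED283: 283}


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary fingerprint; ``bits`` holds the 0-based ON positions."""

    scheme: Scheme
    length: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.length != SCHEME_LENGTHS[self.scheme]:
            raise ValueError(f"{self.scheme} requires length {SCHEME_LENGTHS[self.scheme]}")
        if any(not (0 <= b < self.length) for b in self.bits):
            raise ValueError("bit position out of range")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr


@dataclass(frozen=True)
class KeyEntry:
    index: int
    pattern: str
    query: str
    description: str


class BAPSKeyTable:
    """Ordered table of 117 bonded-atom-pair keys with compiled SMARTS."""

    def __init__(self, entries: Sequence[KeyEntry]):
        if len(entries) != 117:
            raise ValueError(f"BAPS key table must have 117 entries, got {len(entries)}")
        if [e.index for e in entries] != list(range(117)):
            raise ValueError("BAPS key indices must be 0..116 in order")
        patterns = [e.pattern for e in entries]
        if len(set(patterns)) != len(patterns):
            raise ValueError("BAPS key patterns must be unique")
        self.entries = list(entries)
        self._queries = []
        for e in entries:
            q = Chem.MolFromSmarts(e.query)
            if q is None:
                raise ValueError(f"key {e.index} query does not compile: {e.query!r}")
            self._queries.append(q)

    def __len__(self) -> int:
        return len(self.entries)

    def query_mol(self, index: int) -> Chem.Mol:
        return self._queries[index]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BAPSKeyTable":
        entries = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                index, pattern, query, description = line.split("\t")
                entries.append(KeyEntry(int(index), pattern, query, description))
        return cls(entries)


_DEFAULT_TABLE: BAPSKeyTable | None = None


def default_baps_table() -> BAPSKeyTable:
    """The packaged default 117-key BAPS vocabulary (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        res = resources.files("selectisom.resources") / BAPS_RESOURCE
        with resources.as_file(res) as path:
            _DEFAULT_TABLE = BAPSKeyTable.from_tsv(path)
    return _DEFAULT_TABLE


def as_mol(molecule: str | Chem.Mol) -> Chem.Mol:
    """Accept a SMILES string or an RDKit Mol; raise on parse failure."""
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {molecule!r}")
    return mol


def compute_maccs(molecule: str | Chem.Mol) -> BitFingerprint:
    """166-bit MACCS fingerprint (public key dictionary, unused slot stripped)."""
    mol = as_mol(molecule)
    vect = MACCSkeys.GenMACCSKeys(mol)
    bits = frozenset(i - 1 for i in vect.GetOnBits() if i >= 1)
    return BitFingerprint(Scheme.MACCS166, 166, bits)


def compute_baps(
    molecule: str | Chem.Mol, table: BAPSKeyTable | None = None
) -> BitFingerprint:
    """117-bit bonded-atom-pair fingerprint: bit i ON iff some bond matches key i."""
    mol = as_mol(molecule)
    table = table or default_baps_table()
    bits = frozenset(
        e.index for e in table.entries if mol.HasSubstructMatch(table.query_mol(e.index))
    )
    return BitFingerprint(Scheme.BAPS117, 117, bits)


def combine(maccs: BitFingerprint, baps: BitFingerprint) -> BitFingerprint:
    """Concatenate MACCS (positions 0-165) and BAPS (positions 166-282)."""
    if maccs.scheme is not Scheme.MACCS166 or baps.scheme is not Scheme.BAPS117:
        raise ValueError("combine() expects a MACCS166 and a BAPS117 fingerprint")
    bits = frozenset(maccs.bits) | frozenset(b + 166 for b in baps.bits)
    return BitFingerprint(Scheme.COMBINED283, 283, bits)


def compute_fingerprint(
    molecule: str | Chem.Mol,
    scheme: Scheme,
    table: BAPSKeyTable | None = None,
) -> BitFingerprint:
    if scheme is Scheme.MACCS166:
        return compute_maccs(molecule)
    if scheme is Scheme.BAPS117:
        return compute_baps(molecule, table)
    mol = as_mol(molecule)
    return combine(compute_maccs(mol), compute_baps(mol, table))


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a AND b| / |a OR b|; defined as 1.0 when both are empty."""
    if a.scheme is not b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def tanimoto_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity on dense 0/1 vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def key_description(scheme: Scheme, bit: int, table: BAPSKeyTable | None = None) -> tuple[str, str]:
    """(pattern, description) of a bit under a scheme.

    Combined bits below 166 are MACCS, at or above 166 are BAPS (shifted).
    MACCS descriptions come from the public SMARTS dictionary.
    """
    table = table or default_baps_table()
    if scheme is Scheme.COMBINED283:
        if bit < 166:
            return key_description(Scheme.MACCS166, bit)
        return key_description(Scheme.BAPS117, bit - 166, table)
    if scheme is Scheme.MACCS166:
        smarts, count = MACCSkeys.smartsPatts[bit + 1]
        label = f"MACCS key {bit + 1}"
        if count:
            label += f" (>{count} occurrences)"
        return smarts, label
    entry = table.entries[bit]
    return entry.pattern, entry.description


def marker_query(scheme: Scheme, bit: int, table: BAPSKeyTable | None = None) -> Chem.Mol | None:
    """Compiled substructure query behind a bit, or None when not expressible."""
    table = table or default_baps_table()
    if scheme is Scheme.COMBINED283:
        return marker_query(Scheme.MACCS166, bit) if bit < 166 else marker_query(
            Scheme.BAPS117, bit - 166, table
        )
    if scheme is Scheme.BAPS117:
        return table.query_mol(bit)
    smarts, _ = MACCSkeys.smartsPatts[bit + 1]
    if smarts in ("?", ""):
        return None
    return Chem.MolFromSmarts(smarts)


# --- scikit-learn style transformers -------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class _FingerprintTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of SMILES/Mol -> dense 0/1 matrix."""

    scheme: Scheme

    def fit(self, X: Iterable[str | Chem.Mol], y=None):
        return self

    def transform(self, X: Iterable[str | Chem.Mol]) -> np.ndarray:
        fps = [self._compute(m) for m in X]
        if not fps:
            return np.zeros((0, SCHEME_LENGTHS[self.scheme]), dtype=np.uint8)
        return np.stack([fp.to_array() for fp in fps])

    def fingerprints(self, X: Iterable[str | Chem.Mol]) -> list[BitFingerprint]:
        return [self._compute(m) for m in X]

    def _compute(self, molecule: str | Chem.Mol) -> BitFingerprint:
        raise NotImplementedError


class MACCSFingerprinter(_FingerprintTransformer):
    scheme = Scheme.MACCS166

    def _compute(self, molecule):
        return compute_maccs(molecule)


class BAPSFingerprinter(_FingerprintTransformer):
    scheme = Scheme.BAPS117

    def __init__(self, key_table: BAPSKeyTable | None = None):
        self.key_table = key_table

    def _compute(self, molecule):
        return compute_baps(molecule, self.key_table)


class CombinedFingerprinter(_FingerprintTransformer):
    scheme = Scheme.COMBINED283

    def __init__(self, key_table: BAPSKeyTable | None = None):
        self.key_table = key_table

    def _compute(self, molecule):
        mol = as_mol(molecule)
        return combine(compute_maccs(mol), compute_baps(mol, self.key_table))


def fingerprinter_for(scheme: Scheme, table: BAPSKeyTable | None = None) -> _FingerprintTransformer:
    if scheme is Scheme.MACCS166:
        return MACCSFingerprinter()
    if scheme is Scheme.BAPS117:
        return BAPSFingerprinter(table)
    return CombinedFingerprinter(table)
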