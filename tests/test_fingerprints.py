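import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from selectisom.fingerprints import (
    BAPSFingerprinter,
    BAPSKeyTable,
    BitFingerprint,
    KeyEntry,
    Scheme,
    combine,
    compute_baps,
    compute_maccs,
    default_baps_table,
    tanimoto,
)

TABLE = default_baps_table()
PATTERN_INDEX = {e.pattern: e.index for e in TABLE.entries}


def test_default_table_shape_and_compiling_queries():
    assert len(TABLE) == 117
    assert len({e.pattern for e in TABLE.entries}) == 117
    # every query already compiled at load; spot-check semantics of one
    assert TABLE.entries[PATTERN_INDEX["a-[G7]"]].query == "[a]~[F,Cl,Br,I]"


def test_malformed_key_tables_rejected():
    entries = [KeyEntry(i, f"p{i}", "[C]", "x") for i in range(117)]
    bad = entries[:116] + [KeyEntry(116, "p0", "[C]", "dup pattern")]
    with pytest.raises(ValueError, match="unique"):
        BAPSKeyTable(bad)
    with pytest.raises(ValueError, match="117"):
        BAPSKeyTable(entries[:50])
    bad_query = entries[:116] + [KeyEntry(116, "p116", "[[", "broken")]
    with pytest.raises(ValueError, match="compile"):
        BAPSKeyTable(bad_query)


def test_maccs_length_and_benzene_aromatic_key():
    fp = compute_maccs("c1ccccc1")
    assert fp.length == 166
    # independent oracle: find the public-dictionary keys benzene matches
    mol = Chem.MolFromSmiles("c1ccccc1")
    expected = set()
    for key, (smarts, count) in MACCSkeys.smartsPatts.items():
        if smarts in ("?", ""):
            continue
        matches = mol.GetSubstructMatches(Chem.MolFromSmarts(smarts), uniquify=True)
        if len(matches) > count:
            expected.add(key - 1)
    assert expected <= fp.bits
    assert any(b in fp.bits for b in expected)  # aromatic/ring keys fire


def test_methane_has_no_nitrogen_keys():
    fp = compute_maccs("C")
    n_keys = {
        key - 1
        for key, (smarts, _) in MACCSkeys.smartsPatts.items()
        if smarts not in ("?", "") and ("N" in smarts or "#7" in smarts)
    }
    assert fp.bits.isdisjoint(n_keys)


def test_baps_acetonitrile_manual_bond_enumeration():
    """CC#N has exactly two bonds: C-C and C#N, both acyclic aliphatic."""
    fp = compute_baps("CC#N")
    expected = {
        PATTERN_INDEX["C-!@C"],
        PATTERN_INDEX["C-!@N"],
        PATTERN_INDEX["A-!@A"],
    }
    assert fp.bits == expected


def test_baps_chlorobenzene_halogen_keys():
    fp = compute_baps("c1ccccc1Cl")
    assert PATTERN_INDEX["a-[G7]"] in fp.bits
    assert PATTERN_INDEX["c-!@[G7]"] in fp.bits
    assert PATTERN_INDEX["c-@c"] in fp.bits


def test_single_atom_has_all_bits_off():
    assert compute_baps("C").bits == frozenset()
    assert compute_baps("[Na+]").bits == frozenset()


def test_baps_monotone_under_fragment_addition():
    """Extending a molecule never clears an ON bond-pair bit."""
    pairs = [("CCO", "CCOC(=O)c1ccccc1"), ("c1ccccc1", "c1ccccc1SC"), ("CC#N", "CC#N.CCl")]
    for small, large in pairs:
        assert compute_baps(small).bits <= compute_baps(large).bits


@pytest.mark.parametrize("smiles", ["c1ccccc1C#N", "Clc1ccncc1", "CC(=O)NC1CCCCC1"])
def test_atom_order_invariance(smiles, rng):
    mol = Chem.MolFromSmiles(smiles)
    ref_maccs = compute_maccs(mol).bits
    ref_baps = compute_baps(mol).bits
    for _ in range(10):
        order = rng.permutation(mol.GetNumAtoms()).tolist()
        renumbered = Chem.RenumberAtoms(mol, order)
        shuffled = Chem.MolFromSmiles(Chem.MolToSmiles(renumbered, canonical=False))
        assert compute_maccs(shuffled).bits == ref_maccs
        assert compute_baps(shuffled).bits == ref_baps


bitsets = st.sets(st.integers(min_value=0, max_value=116), max_size=30)


@given(bitsets, bitsets)
def test_combine_places_baps_bits_at_offset(maccs_bits, baps_bits):
    maccs = BitFingerprint(Scheme.MACCS166, 166, frozenset(b % 166 for b in maccs_bits))
    baps = BitFingerprint(Scheme.BAPS117, 117, frozenset(baps_bits))
    both = combine(maccs, baps)
    assert both.length == 283
    assert len(both.bits) == len(maccs.bits) + len(baps.bits)
    for i in range(117):
        assert ((166 + i) in both.bits) == (i in baps.bits)
    for i in range(166):
        assert (i in both.bits) == (i in maccs.bits)


def test_combine_rejects_scheme_mismatch():
    baps = BitFingerprint(Scheme.BAPS117, 117, frozenset())
    with pytest.raises(ValueError):
        combine(baps, baps)


@given(bitsets, bitsets)
def test_tanimoto_matches_set_arithmetic(a_bits, b_bits):
    a = BitFingerprint(Scheme.BAPS117, 117, frozenset(a_bits))
    b = BitFingerprint(Scheme.BAPS117, 117, frozenset(b_bits))
    got = tanimoto(a, b)
    union = set(a_bits) | set(b_bits)
    expected = 1.0 if not union else len(set(a_bits) & set(b_bits)) / len(union)
    assert got == pytest.approx(expected)
    assert 0.0 <= got <= 1.0


def test_tanimoto_identical_and_disjoint():
    a = BitFingerprint(Scheme.MACCS166, 166, frozenset({1, 5}))
    b = BitFingerprint(Scheme.MACCS166, 166, frozenset({7, 9}))
    assert tanimoto(a, a) == 1.0
    assert tanimoto(a, b) == 0.0
    with pytest.raises(ValueError):
        tanimoto(a, BitFingerprint(Scheme.BAPS117, 117, frozenset()))


def test_transformer_matrix_shape_and_determinism():
    smiles = ["c1ccccc1", "CCO", "CC#N"]
    X1 = BAPSFingerprinter().fit(smiles).transform(smiles)
    X2 = BAPSFingerprinter().transform(smiles)
    assert X1.shape == (3, 117)
    assert np.array_equal(X1, X2)
    assert BAPSFingerprinter().transform([]).shape == (0, 117)
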