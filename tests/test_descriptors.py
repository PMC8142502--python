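"""Descriptor formulas: printed vector lengths, worked examples,
brute-force oracle equivalence and structural invariants."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from mooncop import descriptors as D
from mooncop import tables
from mooncop.seqio import ALPHABET
from mooncop.synthdata import worked_fixtures

SEQS = {r.id: r.sequence for r in worked_fixtures()}

sequences = st.text(alphabet=ALPHABET, min_size=2, max_size=60)


def _matrix_dicts():
    out = []
    for name in tables.DISTANCE_MATRIX_NAMES:
        m = tables.distance_matrix(name)
        out.append({(a, b): m(a, b) for a in ALPHABET for b in ALPHABET})
    return out


def _partitions():
    return [(p.name, p.classes) for p in tables.ctd_partitions()]


# ------------------------------------------------------------ vector lengths

PRINTED_LENGTHS = {
    "SAAC": 60, "SGAAC": 24, "AAKpart": 60, "kAAComposition": 8000,
    "kGAAComposition": 512, "CkSAApair": 400, "CkSGAApair": 64,
    "DDE": 400, "GrpDDE": 64, "CTDC": 21, "CTDT": 21, "CTDD": 105,
    "CTD": 147, "SOCNumber": 60, "QSOrder": 50, "AAutoCor": 456,
    "PseKRAAC-T1": 16, "PseKRAAC-T3A": 16, "PseKRAAC-T3B": 16,
    "PseKRAAC-T14": 16, "PseKRAAC-T15": 16, "PseKRAAC-T16": 16,
    "PseKRAAC-T5": 256, "PseKRAAC-T13": 256, "PseKRAAC-T4": 625,
    "PseKRAAC-T6A": 625, "PseKRAAC-T6B": 625, "PseKRAAC-T7": 625,
    "PseKRAAC-T8": 625, "PseKRAAC-T9": 625, "PseKRAAC-T10": 625,
    "PseKRAAC-T11": 625, "PseKRAAC-T12": 625,
}


@pytest.mark.parametrize("name,length", sorted(PRINTED_LENGTHS.items()))
def test_default_vector_lengths(name, length):
    """Each descriptor's default output length equals its published value."""
    spec = D.get_spec(name)
    assert spec.expected_length == length
    seq = (ALPHABET * 4)[:65]
    vec = spec.compute(seq)
    assert vec.shape == (length,)
    assert len(spec.feature_names()) == length


def test_reduced_ktuple_length_is_g_to_the_k():
    for alph, k in [("murphy4", 2), ("murphy4", 3), ("wang5", 4),
                    ("murphy8", 2), ("identity20", 2)]:
        g = tables.grouped_alphabet(alph).g
        vec = D.reduced_ktuple(ALPHABET * 3, tables.grouped_alphabet(alph), k)
        assert vec.shape == (g ** k,)


# ------------------------------------------------------------ worked examples

def test_aac_examples():
    assert D.aac("AAAA")[0] == 1.0 and D.aac("AAAA")[1:].sum() == 0
    assert np.allclose(D.aac(ALPHABET), 0.05)
    np.testing.assert_allclose(D.aac("AAC")[[0, 1]], [2 / 3, 1 / 3])


def test_aak_part_examples():
    vec = D.aak_part_composition(SEQS["blocks_acd"], k=3)
    a, c, d = ALPHABET.index("A"), ALPHABET.index("C"), ALPHABET.index("D")
    assert vec[a] == 1.0 and vec[20 + c] == 1.0 and vec[40 + d] == 1.0
    # remainder residues go to the earliest parts: "AAAAC" -> "AAA", "AC"
    vec = D.aak_part_composition("AAAAC", k=2)
    assert vec[a] == 1.0
    np.testing.assert_allclose(vec[[20 + a, 20 + c]], [0.5, 0.5])


def test_saac_segment_boundaries():
    vec = D.saac(SEQS["segments_acd"])
    a, c, d = (ALPHABET.index(x) for x in "ACD")
    assert vec[a] == 1.0 and vec[20 + c] == 1.0 and vec[40 + d] == 1.0
    # length 11: middle segment is the single residue C
    vec = D.saac("AAAAACAAAAA")
    assert vec[20 + c] == 1.0


def test_kmer_examples():
    vec = D.kmer_composition("AAAA", k=3)
    assert vec[0] == 1.0 and vec.sum() == 1.0
    vec = D.kmer_composition("ACAC", k=2)
    ac, ca = ALPHABET.index("C"), 20 * ALPHABET.index("C")
    np.testing.assert_allclose(vec[[ac, ca]], [2 / 3, 1 / 3])


def test_cks_pair_examples():
    vec = D.cks_pair("ACAC", gap=0)
    np.testing.assert_allclose(vec[[1, 20]], [2 / 3, 1 / 3])
    vec = D.cks_pair("ACAC", gap=1)
    np.testing.assert_allclose(vec[[0, 21]], [0.5, 0.5])


def test_dde_direct_evaluation():
    vec = D.dde("AC")
    tm = (4 / 61) * (2 / 61)
    tv = tm * (1 - tm) / 1
    assert vec[1] == pytest.approx((1 - tm) / math.sqrt(tv))
    # dipeptides with zero observed frequency standardize to -Tm/sqrt(Tv)
    tm_aa = (4 / 61) ** 2
    assert vec[0] == pytest.approx(-tm_aa / math.sqrt(tm_aa * (1 - tm_aa)))


def test_ctd_homopolymer():
    seq = SEQS["homopolymer_k10"]
    c, t, d = D.ctdc(seq), D.ctdt(seq), D.ctdd(seq)
    assert not t.any()
    for prop_i, part in enumerate(tables.ctd_partitions()):
        cls = part.encode("K")[0]
        block = c[3 * prop_i: 3 * prop_i + 3]
        assert block[cls] == 1.0 and block.sum() == 1.0
        dist = d[15 * prop_i + 5 * cls: 15 * prop_i + 5 * cls + 5]
        np.testing.assert_allclose(dist, [10, 30, 50, 80, 100])


def test_socnumber_examples():
    assert not D.socnumber("A" * 40).any()
    vec = D.socnumber("AC", nlag=1)
    for i, name in enumerate(tables.DISTANCE_MATRIX_NAMES):
        assert vec[i] == pytest.approx(tables.distance_matrix(name)("A", "C") ** 2)


def test_qsorder_homopolymer():
    vec = D.qsorder("A" * 10)
    for block in (vec[:25], vec[25:]):
        assert block[0] == 1.0 and block[1:].sum() == 0


# ------------------------------------------------------- oracle equivalence

def test_counting_descriptors_match_bruteforce(random_sequences):
    g8 = tables.grouped_alphabet("murphy8")
    mapping = {aa: f"G{g8.mapping[aa] + 1}" for aa in ALPHABET}
    syms = [f"G{i + 1}" for i in range(8)]
    for seq in random_sequences:
        np.testing.assert_allclose(D.aac(seq), oracle.composition(seq),
                                   atol=1e-12)
        np.testing.assert_allclose(
            D.saac(seq),
            oracle.composition(seq[:5]) + oracle.composition(seq[5:-5])
            + oracle.composition(seq[-5:]), atol=1e-12)
        np.testing.assert_allclose(
            D.kmer_composition(seq, k=2),
            oracle.kmer_freqs(seq, 2), atol=1e-12)
        np.testing.assert_allclose(
            D.kmer_composition(seq, k=3, alphabet=g8),
            oracle.kmer_freqs(seq, 3, syms, mapping), atol=1e-12)
        for gap in (0, 1, 3):
            np.testing.assert_allclose(
                D.cks_pair(seq, gap=gap),
                oracle.cks_pair_freqs(seq, gap), atol=1e-12)


def test_kmer3_matches_bruteforce_subset(random_sequences):
    # full 8000-cell enumeration is slow; spot-check a subset of sequences
    for seq in random_sequences[:8]:
        np.testing.assert_allclose(D.kmer_composition(seq, k=3),
                                   oracle.kmer_freqs(seq, 3), atol=1e-12)


def test_dde_matches_bruteforce(random_sequences):
    cod = tables.codon_counts()
    g8 = tables.grouped_alphabet("murphy8")
    mapping = {aa: f"G{g8.mapping[aa] + 1}" for aa in ALPHABET}
    syms = [f"G{i + 1}" for i in range(8)]
    for seq in random_sequences[:25]:
        np.testing.assert_allclose(D.dde(seq), oracle.dde(seq, cod),
                                   atol=1e-10)
        np.testing.assert_allclose(D.dde(seq, alphabet=g8),
                                   oracle.dde(seq, cod, syms, mapping),
                                   atol=1e-10)


def test_ctd_matches_bruteforce(random_sequences):
    parts = _partitions()
    for seq in random_sequences[:25]:
        c, t, d = oracle.ctd_parts(seq, parts)
        np.testing.assert_allclose(D.ctdc(seq), c, atol=1e-12)
        np.testing.assert_allclose(D.ctdt(seq), t, atol=1e-12)
        np.testing.assert_allclose(D.ctdd(seq), d, atol=1e-12)
        np.testing.assert_allclose(D.ctd(seq), c + t + d, atol=1e-12)


def test_sequence_order_matches_bruteforce(random_sequences):
    mats = _matrix_dicts()
    for seq in random_sequences[:20]:
        np.testing.assert_allclose(D.socnumber(seq, nlag=10),
                                   oracle.socnumber(seq, 10, mats),
                                   rtol=1e-12)
        np.testing.assert_allclose(D.qsorder(seq, nlag=5, w=0.1),
                                   oracle.qsorder(seq, 5, 0.1, mats),
                                   rtol=1e-12)


def test_moreau_broto_matches_bruteforce():
    seq = "AC" * 10
    scale = {aa: v for aa, v in zip(
        ALPHABET, D._standardize(D.AUTOCORR_SCALES["hydropathy"]))}
    got = D.autocorrelation(seq, properties=("hydropathy",), nlag=3,
                            kinds=("moreau_broto",))
    np.testing.assert_allclose(got, oracle.moreau_broto(seq, scale, 3),
                               rtol=1e-12)


def test_autocorrelation_degenerate_variance():
    vec = D.autocorrelation("A" * 30, properties=("hydropathy",), nlag=2,
                            kinds=("moran", "geary"))
    assert not vec.any()


# ------------------------------------------------------------- invariants

@settings(derandomize=True, max_examples=40, deadline=None)
@given(seq=st.text(alphabet=ALPHABET, min_size=12, max_size=60))
def test_composition_blocks_normalized(seq):
    g8 = tables.grouped_alphabet("murphy8")
    for vec in (D.aac(seq), D.kmer_composition(seq, 2),
                D.cks_pair(seq, 1), D.reduced_ktuple(seq, g8, 2)):
        assert (vec >= 0).all()
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
    saac_vec = D.saac(seq)
    for block in (saac_vec[:20], saac_vec[20:40], saac_vec[40:]):
        assert block.sum() == pytest.approx(1.0, abs=1e-12)
    qso = D.qsorder(seq)
    assert qso[:25].sum() == pytest.approx(1.0, abs=1e-12)
    assert qso[25:].sum() == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seq=st.text(alphabet=ALPHABET, min_size=2, max_size=60))
def test_observed_dipeptide_freqs_partition(seq):
    # the observed dipeptide frequencies inside DDE sum to 1
    assert D.cks_pair(seq, gap=0).sum() == pytest.approx(1.0, abs=1e-12)


def test_permutation_invariance():
    rng = np.random.default_rng(5)
    seq = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=50))
    perm = "".join(rng.permutation(list(seq)))
    np.testing.assert_allclose(D.aac(seq), D.aac(perm))
    np.testing.assert_allclose(D.kmer_composition(seq, 1),
                               D.kmer_composition(perm, 1))
    np.testing.assert_allclose(D.ctdc(seq), D.ctdc(perm))
    # sequence-order descriptors are NOT permutation invariant
    assert not np.allclose(D.qsorder(seq), D.qsorder(perm))
    assert not np.allclose(D.socnumber(seq, nlag=10),
                           D.socnumber(perm, nlag=10))


def test_dde_decreasing_in_tm():
    # at fixed Dc and L, the standardized deviation falls as Tm rises
    dc, L = 0.3, 50
    tms = np.linspace(0.01, 0.6, 25)
    vals = [(dc - tm) / math.sqrt(tm * (1 - tm) / (L - 1)) for tm in tms]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# --------------------------------------------------------------- extraction

def test_extract_matrix_shape(small_dataset):
    feats = D.extract("SAAC", small_dataset.subset(small_dataset.ids[:3]))
    assert feats.shape == (3, 60)
    assert list(feats.index) == small_dataset.ids[:3]
    assert all(name.startswith("SAAC.") for name in feats.columns)


def test_extract_unknown_descriptor():
    with pytest.raises(KeyError, match="FOO"):
        D.get_spec("FOO")


def test_extract_is_deterministic(small_dataset):
    a = D.extract("QSOrder", small_dataset)
    b = D.extract("QSOrder", small_dataset)
    assert a.equals(b)


def test_extract_names_failing_protein():
    from mooncop.seqio import LabeledDataset, ProteinRecord
    ds = LabeledDataset([ProteinRecord("ok", "A" * 40),
                         ProteinRecord("shorty", "ACDE")])
    with pytest.raises(ValueError, match="shorty"):
        D.extract("SOCNumber", ds)


def test_unknown_descriptor_params_rejected():
    with pytest.raises(KeyError, match="bogus"):
        D.get_spec("SAAC", bogus=3)
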