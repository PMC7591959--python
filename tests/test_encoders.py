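import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from enhancerkit.encoders import (
    EIIP_TABLE,
    EncodingError,
    FeatureMatrix,
    encode_anf,
    encode_cksnap,
    encode_eiip,
    encode_enac,
    encode_kmer,
    encode_ncp,
    encode_onehot,
    encode_pseeiip,
    encode_rckmer,
    merge_matrices,
    rc_canonical_kmers,
)
from enhancerkit.io import SequenceRecord

dna = st.text(alphabet="ACGT", min_size=10, max_size=60)


def rec(seq, rid="s1"):
    return SequenceRecord(rid, seq)


# --- k-mer -----------------------------------------------------------------


def test_kmer_homopolymer_and_worked_dinucleotides():
    m1 = encode_kmer([rec("AAAA")], 1)
    assert dict(zip(m1.feature_names, m1.values[0])) == {"A": 1.0, "C": 0, "G": 0, "T": 0}
    m2 = encode_kmer([rec("ACGT")], 2)
    row = dict(zip(m2.feature_names, m2.values[0]))
    assert row["AC"] == row["CG"] == row["GT"] == pytest.approx(1 / 3)
    assert sum(row.values()) == pytest.approx(1.0)


def test_kmer_too_short_names_record():
    with pytest.raises(EncodingError, match="s9"):
        encode_kmer([SequenceRecord("s9", "AC")], 3)


@settings(max_examples=30, deadline=None)
@given(dna, st.integers(1, 4))
def test_kmer_matches_naive_window_counts(seq, k):
    got = encode_kmer([rec(seq)], k).values[0]
    assert np.allclose(got, oracles.naive_kmer(seq, k), atol=1e-12)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


# --- RCK-mer ---------------------------------------------------------------


def test_rckmer_dinucleotide_classes():
    assert rc_canonical_kmers(2) == ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA"]


@pytest.mark.parametrize("k,expected", [(1, 2), (2, 10), (3, 32), (4, 136)])
def test_rckmer_class_counts_match_enumeration(k, expected):
    # brute-force collapse of all 4^k words by reverse complement
    brute = {min(w, oracles.revcomp(w)) for w in oracles.all_kmers(k)}
    assert len(brute) == expected
    assert rc_canonical_kmers(k) == sorted(brute)


def test_rckmer_hand_count_aatt():
    m = encode_rckmer([rec("AATT")], 2)
    row = dict(zip(m.feature_names, m.values[0]))
    # windows AA, AT, TT; TT folds into AA
    assert row["AA"] == pytest.approx(2 / 3)
    assert row["AT"] == pytest.approx(1 / 3)


@settings(max_examples=20, deadline=None)
@given(dna, st.integers(1, 4))
def test_rckmer_matches_naive_and_sums_to_one(seq, k):
    got = encode_rckmer([rec(seq)], k).values[0]
    assert np.allclose(got, oracles.naive_rckmer(seq, k), atol=1e-12)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


# --- ENAC ------------------------------------------------------------------


def test_enac_single_window_and_width():
    m = encode_enac([rec("AAAAA")], window=5)
    assert m.feature_names == ["win1_A", "win1_C", "win1_G", "win1_T"]
    assert list(m.values[0]) == [1, 0, 0, 0]
    m200 = encode_enac([rec("ACGT" * 50)], window=5)
    assert m200.shape == (1, 4 * 196)


def test_enac_blocks_sum_to_one(rng):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    vals = encode_enac([rec(seq)], window=7).values[0].reshape(-1, 4)
    assert np.allclose(vals.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(encode_enac([rec(seq)], window=7).values[0], oracles.naive_enac(seq, 7))


def test_enac_rejects_mixed_lengths_and_big_window():
    with pytest.raises(EncodingError, match="uniform"):
        encode_enac([rec("ACGT", "a"), rec("ACGTA", "b")])
    with pytest.raises(EncodingError):
        encode_enac([rec("ACGT")], window=10)


# --- CKSNAP ----------------------------------------------------------------


def test_cksnap_gap0_equals_2mer():
    seq = "ACGTACGGTTAC"
    gap0 = encode_cksnap([rec(seq)], k_set=[0]).values[0]
    assert np.allclose(gap0, encode_kmer([rec(seq)], 2).values[0], atol=1e-12)


def test_cksnap_gap1_hand_enumeration():
    # ACGT gap-1 pairs: (A,G) and (C,T), denominator L-2 = 2
    row = dict(zip(*[encode_cksnap([rec("ACGT")], k_set=[1]).feature_names,
                     encode_cksnap([rec("ACGT")], k_set=[1]).values[0]]))
    assert row["gap1_AG"] == pytest.approx(0.5)
    assert row["gap1_CT"] == pytest.approx(0.5)
    assert sum(row.values()) == pytest.approx(1.0)


def test_cksnap_homopolymer_and_naive(rng):
    m = encode_cksnap([rec("AAAAAA" * 3)])
    row = dict(zip(m.feature_names, m.values[0]))
    for k in range(6):
        assert row[f"gap{k}_AA"] == pytest.approx(1.0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
    assert np.allclose(encode_cksnap([rec(seq)]).values[0], oracles.naive_cksnap(seq), atol=1e-12)


# --- NCP / ANF -------------------------------------------------------------


def test_ncp_fixed_mapping():
    m = encode_ncp([rec("ACGT")])
    assert list(m.values[0]) == [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]
    assert set(np.unique(m.values)) <= {0.0, 1.0}


def test_anf_worked_example_to_printed_precision():
    expected = [
        (0, 0, 1, 1), (0, 1, 0, 0.5), (1, 0, 0, 0.33), (0, 0, 1, 0.5),
        (0, 0, 1, 0.6), (0, 1, 0, 0.33), (1, 1, 1, 0.14), (0, 0, 1, 0.5),
        (1, 0, 0, 0.22), (1, 0, 0, 0.3),
    ]
    got = encode_anf([rec("TCGTTCATGG")]).values[0].reshape(10, 4)
    assert np.allclose(np.round(got, 2), np.array(expected))


def test_anf_homopolymer_and_first_position():
    got = encode_anf([rec("GGGG")]).values[0].reshape(4, 4)
    assert np.allclose(got, np.tile([1, 0, 0, 1.0], (4, 1)))
    # frequency channel at position 1 is 1/1 for any sequence
    assert encode_anf([rec("TACG")]).values[0].reshape(4, 4)[0, 3] == 1.0


# --- EIIP / PseEIIP --------------------------------------------------------


def test_eiip_constants_and_dimension():
    m = encode_eiip([rec("ACGT")])
    assert list(m.values[0]) == [0.1260, 0.1340, 0.0806, 0.1335]
    assert encode_eiip([rec("AAAA")]).values[0].tolist() == [0.1260] * 4
    assert encode_eiip([rec("A" * 33)]).shape[1] == 33


def test_pseeiip_homopolymer_arithmetic():
    m = encode_pseeiip([rec("AAA")])
    row = dict(zip(m.feature_names, m.values[0]))
    assert row["AAA"] == pytest.approx(3 * 0.1260)
    assert sum(v != 0 for v in row.values()) == 1


@settings(max_examples=20, deadline=None)
@given(st.text(alphabet="ACGT", min_size=50, max_size=50))
def test_pseeiip_matches_naive_and_bounds(seq):
    got = encode_pseeiip([rec(seq)]).values[0]
    assert np.allclose(got, oracles.naive_pseeiip(seq), atol=1e-12)
    assert got.min() >= 0 and got.max() <= 3 * 0.1340 + 1e-12


# --- One-Hot ---------------------------------------------------------------


def test_onehot_table_and_block_sums(rng):
    assert list(encode_onehot([rec("A")]).values[0]) == [1, 0, 0, 0]
    assert list(encode_onehot([rec("G")]).values[0]) == [0, 0, 1, 0]
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
    blocks = encode_onehot([rec(seq)]).values[0].reshape(-1, 4)
    assert np.allclose(blocks.sum(axis=1), 1.0)


# --- purity, merging, container --------------------------------------------


def test_encoders_are_pure(small_records):
    a = encode_kmer(small_records, 3).values
    b = encode_kmer(small_records, 3).values
    assert np.array_equal(a, b)


def test_merge_width_additivity_and_errors(small_records):
    m1 = encode_rckmer(small_records, 2)
    m2 = encode_pseeiip(small_records)
    merged = merge_matrices([m1, m2])
    assert merged.shape[1] == 10 + 64
    assert len(set(merged.feature_names)) == 74
    single = merge_matrices([m1])
    assert [n.split(".", 1)[1] for n in single.feature_names] == m1.feature_names
    with pytest.raises(ValueError, match="record ids"):
        merge_matrices([m1, encode_pseeiip(small_records[:5])])


def test_feature_matrix_validation_and_subset():
    with pytest.raises(ValueError, match="finite"):
        FeatureMatrix(["a"], np.array([[np.nan]]), ["r"])
    with pytest.raises(ValueError, match="unique"):
        FeatureMatrix(["a", "a"], np.zeros((1, 2)), ["r"])
    m = FeatureMatrix(["a", "b"], np.array([[1.0, 2.0]]), ["r"])
    assert m.subset(["b"]).values.tolist() == [[2.0]]
    with pytest.raises(KeyError):
        m.subset(["zz"])


def test_feature_matrix_csv_roundtrip(tmp_path, small_records):
    m = encode_kmer(small_records, 2)
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    assert back.feature_names == m.feature_names
    assert back.record_ids == m.record_ids
    assert np.allclose(back.values, m.values)
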