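"""Encodings against brute-force counting oracles and invariants."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_window
from kmalpred.alphabet import AA_ORDER
from kmalpred.encodings import (
    AAindexTable,
    aaindex_matrix,
    eaac_matrix,
    encode_aac,
    encode_aaindex,
    encode_comparators,
    encode_eaac,
    encode_onehot,
    encode_tokens,
    rank_aaindex_properties,
    read_aaindex,
)
from kmalpred.alphabet import detokenize
from kmalpred.records import NEGATIVE, POSITIVE

DATA = Path(__file__).parent / "data"

window_strategy = st.text(alphabet=AA_ORDER, min_size=15, max_size=15).flatmap(
    lambda left: st.text(alphabet=AA_ORDER, min_size=15, max_size=15).map(
        lambda right: left + "K" + right
    )
)


def brute_force_eaac(seq: str, slide: int = 8) -> dict[str, float]:
    """Independent counting oracle for EAAC."""
    out = {}
    half = len(seq) // 2
    for s in range(len(seq) - slide + 1):
        sub = seq[s : s + slide]
        for aa in AA_ORDER:
            out[f"{aa}[{s - half},{s + slide - 1 - half}]"] = sub.count(aa) / slide
    return out


def test_eaac_dimensions_and_names():
    fv = encode_eaac("A" * 15 + "K" + "A" * 15)
    assert len(fv) == 480
    assert fv.names[0] == "A[-15,-8]"
    assert fv.names[-1] == "Y[8,15]"
    assert len({n.split("[")[1] for n in fv.names}) == 24


def test_eaac_hand_counted_example():
    fv = encode_eaac("A" * 15 + "K" + "G" * 15).as_dict()
    assert fv["A[-15,-8]"] == 1.0
    assert fv["A[-4,3]"] == 4 / 8
    assert fv["K[-4,3]"] == 1 / 8
    assert fv["G[-4,3]"] == 3 / 8


@settings(max_examples=30, deadline=None)
@given(window_strategy)
def test_eaac_matches_brute_force_oracle(seq):
    fv = encode_eaac(seq)
    assert fv.as_dict() == pytest.approx(brute_force_eaac(seq))


@settings(max_examples=20, deadline=None)
@given(window_strategy, st.randoms(use_true_random=False))
def test_eaac_invariant_to_permutation_within_sliding_window(seq, rnd):
    fv = encode_eaac(seq).as_dict()
    # permute the first sliding window's flank residues (positions 0..7)
    chars = list(seq[:8])
    rnd.shuffle(chars)
    permuted = "".join(chars) + seq[8:]
    fv2 = encode_eaac(permuted).as_dict()
    for aa in AA_ORDER:
        assert fv2[f"{aa}[-15,-8]"] == fv[f"{aa}[-15,-8]"]


def test_eaac_gaps_dilute_rather_than_renormalize():
    fv = encode_eaac("-" * 15 + "K" + "A" * 15).as_dict()
    assert fv["A[-15,-8]"] == 0.0
    assert fv["K[-7,0]"] == 1 / 8
    assert sum(fv[f"{aa}[-15,-8]"] for aa in AA_ORDER) == 0.0


def test_aac_counts_gaps_in_denominator_only():
    fv = encode_aac("A" * 15 + "K" + "A" * 15).as_dict()
    assert fv["A"] == 30 / 31 and fv["K"] == 1 / 31
    lonely = encode_aac("-" * 15 + "K" + "-" * 15).as_dict()
    assert lonely["K"] == 1 / 31
    assert sum(lonely.values()) == 1 / 31
    assert len(lonely) == 20


@settings(max_examples=15, deadline=None)
@given(window_strategy)
def test_aac_equals_eaac_with_full_slide_on_gapfree_windows(seq):
    aac = encode_aac(seq)
    eaac = encode_eaac(seq, slide=31)
    assert np.allclose(aac.values, eaac.values)


def test_onehot_rows():
    mat = encode_onehot("A" * 15 + "K" + "-" * 15)
    assert mat.shape == (31, 20)
    assert mat[0, 0] == 1.0 and mat[0].sum() == 1.0
    assert np.all(mat[16:] == 0.05)
    assert np.allclose(mat.sum(axis=1), 1.0)


def test_tokens_roundtrip_and_locality():
    seq = "ACDEFGHIKLMNPQR" + "K" + "YWVTSRQPNMLKIHG"
    toks = encode_tokens(seq)
    assert len(toks) == 31
    assert detokenize(toks) == seq
    other = encode_tokens(seq[:5] + "W" + seq[6:])
    assert int(np.sum(toks != other)) == 1


def test_slide_bounds_checked():
    with pytest.raises(ValueError):
        encode_eaac("A" * 15 + "K" + "A" * 15, slide=0)
    with pytest.raises(ValueError):
        encode_eaac("A" * 15 + "K" + "A" * 15, slide=32)


# ---------------------------------------------------------------------------
# AAindex


def test_aaindex_parser_drops_na_records():
    tables = read_aaindex(DATA / "aaindex_sample.txt")
    assert [t.property_id for t in tables] == ["KYTJ820101", "FASG760101"]
    kd = dict(zip(AA_ORDER, tables[0].values))
    assert kd["I"] == 4.5 and kd["R"] == -4.5 and kd["G"] == -0.4


def test_aaindex_encoding_dimensions_and_gap_rule():
    tables = read_aaindex(DATA / "aaindex_sample.txt")
    eleven = [
        AAindexTable(f"PROP{i:02d}", tuple(float(j + i) for j in range(20)))
        for i in range(11)
    ]
    assert len(encode_aaindex("A" * 15 + "K" + "A" * 15, eleven)) == 341
    assert len(encode_aaindex("A" * 15 + "K" + "A" * 15, tables[:1])) == 31
    fv = encode_aaindex("-" * 15 + "K" + "-" * 15, tables)
    vals = np.array(fv.values).reshape(len(tables), 31)
    assert np.all(vals[:, :15] == 0) and np.all(vals[:, 16:] == 0)
    kd = dict(zip(AA_ORDER, tables[0].values))
    assert vals[0, 15] == kd["K"]


def test_aaindex_matrix_agrees_with_single_window_encoding(small_windows):
    tables = read_aaindex(DATA / "aaindex_sample.txt")
    X, names = aaindex_matrix(small_windows[:5], tables)
    assert X.shape == (5, 62)
    fv = encode_aaindex(small_windows[2], tables)
    assert names == fv.names
    assert np.allclose(X[2], fv.values)


def test_rank_aaindex_recovers_separating_property(small_windows):
    """A property scale that isolates glycine separates motif-planted data
    and is ranked first; a constant scale is never selected."""
    g_indicator = AAindexTable(
        "GSEP", tuple(1.0 if aa == "G" else 0.0 for aa in AA_ORDER)
    )
    constant = AAindexTable("CONST", tuple(1.0 for _ in AA_ORDER))
    ranked = rank_aaindex_properties(
        [constant, g_indicator], small_windows, auc_cutoff=0.6,
        top_n=2, k=4, n_trees=60, seed=0,
    )
    assert ranked[:1] == ["GSEP"]
    assert "CONST" not in ranked


# ---------------------------------------------------------------------------
# comparators


def test_comparator_dimensions():
    w = "A" * 15 + "K" + "A" * 15
    assert len(encode_comparators(w, "binary")) == 620
    assert len(encode_comparators(w, "blosum62")) == 620
    assert len(encode_comparators(w, "zscales")) == 155
    assert len(encode_comparators(w, "cksaap")) == 2000
    with pytest.raises(ValueError):
        encode_comparators(w, "pssm")


def test_cksaap_all_a_window_only_axa_pairs():
    w = make_window("A" * 15 + "K" + "A" * 15)
    fv = encode_comparators(w, "cksaap")
    nonzero = {n for n, v in zip(fv.names, fv.values) if v > 0}
    allowed = {f"AxA|k={k}" for k in range(5)} | \
        {f"AxK|k={k}" for k in range(5)} | {f"KxA|k={k}" for k in range(5)}
    assert nonzero <= allowed
    assert any(n.startswith("AxA") for n in nonzero)


def test_encodings_are_deterministic(small_windows):
    w = small_windows[0]
    for enc in (encode_eaac, encode_aac):
        assert enc(w).values == enc(w).values
    assert np.array_equal(encode_onehot(w), encode_onehot(w))
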