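"""Dataset-construction operations against hand-computed oracles."""

import numpy as np
import pytest

from conftest import make_window
from kmalpred.dataset import (
    build_windows,
    cluster_proteins,
    exclude_aligned_positives,
    extract_window,
    filter_high_confidence,
    group_kfold,
    pairwise_identity,
    remove_conflicting_7mers,
    select_representative,
    split_by_protein,
    windows_from_sites,
)
from kmalpred.records import NEGATIVE, POSITIVE, ProteinRecord, SiteRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(rng, pid, n):
    return ProteinRecord(pid, "".join(rng.choice(list(AA), n)))


# ---------------------------------------------------------------------------
# confidence filter


@pytest.mark.parametrize(
    "score,prob,kept",
    [
        (51.0, 0.76, True),   # both strictly above
        (50.0, 0.90, False),  # boundary is strict
        (80.0, 0.75, False),  # boundary is strict on probability too
        (49.9, 0.99, False),
    ],
)
def test_filter_strict_inequalities(score, prob, kept):
    site = SiteRecord("P", 1, POSITIVE, score, prob)
    assert (filter_high_confidence([site]) == [site]) is kept


def test_filter_counts_scores_strictly_above_cutoff():
    sites = [SiteRecord("P", i + 1, POSITIVE, 45.0 + i, 0.8) for i in range(10)]
    kept = filter_high_confidence(sites)
    assert len(kept) == 4  # scores 51..54


def test_filter_passes_negatives_and_warns_on_missing_scores(caplog):
    neg = SiteRecord("P", 1, NEGATIVE)
    orphan = SiteRecord("P", 2, POSITIVE)  # no scores
    with caplog.at_level("WARNING"):
        kept = filter_high_confidence([neg, orphan])
    assert kept == [neg]
    assert any("lacks confidence" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# clustering


def test_identical_sequences_form_one_cluster(rng):
    p1 = _rand_protein(rng, "A", 50)
    p2 = ProteinRecord("B", p1.sequence)
    clusters = cluster_proteins([p1, p2])
    assert len(clusters) == 1 and len(clusters[0].members) == 2


def test_unrelated_sequences_stay_separate():
    a = ProteinRecord("A", "AC" * 30)
    b = ProteinRecord("B", "WY" * 30)
    assert pairwise_identity(a.sequence, b.sequence) < 0.10
    clusters = cluster_proteins([a, b])
    assert len(clusters) == 2


def test_similar_pair_plus_outlier(rng):
    a = _rand_protein(rng, "A", 80)
    mutated = list(a.sequence)
    for i in range(0, 80, 10):
        mutated[i] = "W" if mutated[i] != "W" else "Y"
    b = ProteinRecord("B", "".join(mutated))  # ~90% identical to A
    c = _rand_protein(rng, "C", 80)
    clusters = cluster_proteins([a, b, c])
    memberships = sorted(tuple(sorted(m.id for m in cl.members)) for cl in clusters)
    assert memberships == [("A", "B"), ("C",)]


def test_cluster_count_monotone_in_threshold(rng):
    proteins = [_rand_protein(rng, f"P{i}", 60) for i in range(12)]
    proteins += [ProteinRecord(f"{p.id}x", p.sequence) for p in proteins[:4]]
    counts = [
        len(cluster_proteins(proteins, identity_threshold=t))
        for t in (0.15, 0.30, 0.60, 0.95)
    ]
    assert counts == sorted(counts)


def test_precomputed_assignments_hook(rng):
    proteins = [_rand_protein(rng, f"P{i}", 40) for i in range(4)]
    clusters = cluster_proteins(proteins, assignments={"P0": 0, "P1": 0, "P2": 1, "P3": 1})
    assert sorted(len(c.members) for c in clusters) == [2, 2]


# ---------------------------------------------------------------------------
# representative selection and aligned-positive exclusion


def test_representative_prefers_more_positives_then_tiebreaks(rng):
    long_p = _rand_protein(rng, "BB", 60)
    short_p = _rand_protein(rng, "AA", 40)
    cluster = cluster_proteins([long_p, short_p], assignments={"BB": 0, "AA": 0})[0]
    sites = [SiteRecord("AA", 1, POSITIVE, 99, 0.99)] * 3 + \
            [SiteRecord("BB", 1, POSITIVE, 99, 0.99)]
    assert select_representative(cluster, sites).id == "AA"
    # tie on count: longer sequence wins
    sites = [SiteRecord("AA", 1, POSITIVE, 99, 0.99),
             SiteRecord("BB", 1, POSITIVE, 99, 0.99)]
    assert select_representative(cluster, sites).id == "BB"
    # full tie: lexicographically smaller id
    same_len = ProteinRecord("AB", long_p.sequence)
    cluster = cluster_proteins([long_p, same_len], assignments={"BB": 0, "AB": 0})[0]
    assert select_representative(cluster, []).id == "AB"


def test_exclude_aligned_positive_drops_matching_negative():
    rep = ProteinRecord("R", "AAAGGGKCCCDDD")  # negative K at 7, 7-mer GGGKCCC
    member = ProteinRecord("M", "TTTGGGKCCCWWW")  # positive K at 7, same 7-mer
    sites = [
        SiteRecord("R", 7, NEGATIVE),
        SiteRecord("M", 7, POSITIVE, 99, 0.99),
    ]
    kept = exclude_aligned_positives(rep, [rep, member], sites)
    assert kept == []  # the sole negative was dropped

    lone = exclude_aligned_positives(rep, [rep], [SiteRecord("R", 7, NEGATIVE)])
    assert len(lone) == 1  # no other members -> unchanged


def test_exclude_aligned_keeps_nonmatching_negative():
    rep = ProteinRecord("R", "AAAGGGKCCCDDD")
    member = ProteinRecord("M", "TTTWWWKYYYWWW")  # positive with a unique 7-mer
    sites = [SiteRecord("R", 7, NEGATIVE), SiteRecord("M", 7, POSITIVE, 99, 0.99)]
    kept = exclude_aligned_positives(rep, [rep, member], sites)
    assert [s.position for s in kept] == [7]


# ---------------------------------------------------------------------------
# 7-mer conflicts


def _win(center7: str, label, pid="P", pos=16):
    left = "A" * 12
    right = "C" * 12
    return make_window(left + center7 + right, label, pid, pos)


def test_conflicting_7mer_removal_counts_and_idempotence():
    shared = "GGGKCCC"
    pos = [_win(shared, POSITIVE), _win("WWWKWWW", POSITIVE)]
    neg = [_win(shared, NEGATIVE), _win(shared, NEGATIVE), _win("YYYKYYY", NEGATIVE)]
    kept_pos, kept_neg = remove_conflicting_7mers(pos, neg)
    assert len(kept_pos) == 1 and len(kept_neg) == 1
    assert remove_conflicting_7mers(kept_pos, kept_neg) == (kept_pos, kept_neg)


def test_disjoint_7mers_unchanged_and_total_overlap_empties():
    pos = [_win("GGGKCCC", POSITIVE)]
    neg = [_win("YYYKYYY", NEGATIVE)]
    assert remove_conflicting_7mers(pos, neg) == (pos, neg)
    neg_same = [_win("GGGKCCC", NEGATIVE)]
    assert remove_conflicting_7mers(pos, neg_same) == ([], [])


# ---------------------------------------------------------------------------
# window extraction


def test_window_padding_at_termini():
    protein = ProteinRecord("P", "K" + "A" * 39)
    w = extract_window(protein, 1)
    assert w.sequence == "-" * 15 + "K" + "A" * 15

    tail = ProteinRecord("Q", "A" * 19 + "K")
    w = extract_window(tail, 20)
    assert w.sequence == "A" * 15 + "K" + "-" * 15
    assert w.sequence.count("-") == 15

    mid = ProteinRecord("R", "A" * 19 + "K" + "C" * 20)
    assert "-" not in extract_window(mid, 20).sequence


def test_window_strips_to_substring(small_truth):
    by_id = {p.id: p.sequence for p in small_truth.proteins}
    windows = windows_from_sites(small_truth.proteins, small_truth.sites[:200])
    for w in windows:
        assert w.sequence.strip("-") in by_id[w.protein_id]


def test_non_lysine_center_is_an_error():
    protein = ProteinRecord("P", "A" * 31)
    with pytest.raises(ValueError, match="corrupt"):
        extract_window(protein, 5)
    with pytest.raises(ValueError):
        extract_window(ProteinRecord("P", "KAK"), 2, window=4)


# ---------------------------------------------------------------------------
# splits and folds


def test_split_by_protein_counts_and_determinism(small_windows):
    split = split_by_protein(small_windows, 0.8, seed=3)
    ids_train = {w.protein_id for w in split.train}
    ids_test = {w.protein_id for w in split.test}
    assert not ids_train & ids_test
    total = len(ids_train | ids_test)
    assert len(ids_train) == int(round(0.8 * total))
    again = split_by_protein(small_windows, 0.8, seed=3)
    assert [w.sequence for w in again.train] == [w.sequence for w in split.train]


def test_split_five_proteins_holds_one_out():
    windows = []
    for i, n in enumerate([10, 10, 10, 10, 60]):
        windows += [make_window("A" * 15 + "K" + "A" * 15, NEGATIVE, f"P{i}", 16)] * n
    split = split_by_protein(windows, 0.8, seed=0)
    assert len({w.protein_id for w in split.test}) == 1
    assert not {w.protein_id for w in split.train} & {w.protein_id for w in split.test}


def test_group_kfold_partitions_without_leakage(small_windows):
    folds = group_kfold(small_windows, k=5, seed=7)
    seen = []
    for train, val in folds:
        assert not {w.protein_id for w in train} & {w.protein_id for w in val}
        seen.extend(val)
    assert len(seen) == len(small_windows)
    assert {id(w) for w in seen} == {id(w) for w in small_windows}


def test_group_kfold_balances_proteins():
    windows = [make_window("A" * 15 + "K" + "A" * 15, NEGATIVE, f"P{i}", 16)
               for i in range(20)]
    folds = group_kfold(windows, k=10, seed=0)
    assert all(len({w.protein_id for w in val}) == 2 for _, val in folds)
    with pytest.raises(ValueError):
        group_kfold(windows[:5], k=10, seed=0)


def test_build_windows_pipeline_counts(small_truth):
    windows, info = build_windows(small_truth.proteins, small_truth.sites)
    assert info["n_pos_windows"] + info["n_neg_windows"] == len(windows)
    assert info["n_clusters"] <= info["n_proteins_in"]
    assert all(w.width == 31 for w in windows)
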