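"""Dataset construction: confidence filtering, redundancy reduction,
window extraction and protein-grouped splitting.

The pipeline follows the construction used for mammalian malonylation
training data:

1. keep positive sites with identification score > 50 and localization
   probability > 0.75 (strict inequalities);
2. cluster proteins at > 30% global sequence identity (greedy longest-first,
   an internal stand-in for CD-HIT) and keep, per cluster, the member with
   the most positive sites; representative lysines whose aligned counterpart
   in another member is modified are excluded from the negatives rather than
   relabeled;
3. remove any positive/negative pair of windows sharing the same central
   7-mer (center +/-3);
4. extract fixed odd-width windows (default 31) with '-' padding at protein
   termini;
5. split train/test by protein, never by peptide, so homologous windows
   cannot leak across the split.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .records import (
    NEGATIVE,
    POSITIVE,
    DatasetSplit,
    PeptideWindow,
    ProteinCluster,
    ProteinRecord,
    SiteRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "filter_high_confidence",
    "pairwise_identity",
    "cluster_proteins",
    "select_representative",
    "exclude_aligned_positives",
    "extract_window",
    "windows_from_sites",
    "remove_conflicting_7mers",
    "split_by_protein",
    "group_kfold",
    "build_windows",
]


# ---------------------------------------------------------------------------
# step 1: confidence filter


def filter_high_confidence(
    sites: Sequence[SiteRecord],
    min_score: float = 50.0,
    min_locprob: float = 0.75,
) -> list[SiteRecord]:
    """Keep positives identified with score > ``min_score`` AND localization
    probability > ``min_locprob`` (both strict); negatives pass through.

    Positives missing either value are rejected with a warning rather than
    raising: a missing score marks an unusable record, not a corrupt table.
    """
    kept: list[SiteRecord] = []
    for s in sites:
        if s.label != POSITIVE:
            kept.append(s)
            continue
        if s.andromeda_score is None or s.localization_prob is None:
            logger.warning(
                "positive site %s:%d lacks confidence values; rejected",
                s.protein_id,
                s.position,
            )
            continue
        if s.andromeda_score > min_score and s.localization_prob > min_locprob:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# step 2: clustering and representative selection


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Matches are counted from the extended CIGAR of an edit-distance-optimal
    Needleman-Wunsch alignment (unit costs; edlib), and divided by the full
    alignment length (matches + mismatches + gap columns). Normalizing by
    the shorter sequence instead would grossly overestimate identity for
    length-mismatched pairs, because the forced terminal gaps let the
    shorter sequence cherry-pick matching columns anywhere in the longer.
    """
    if not a or not b:
        return 0.0
    result = edlib.align(a, b, mode="NW", task="path")
    matches = aln_len = 0
    for n, op in _CIGAR_RE.findall(result["cigar"]):
        aln_len += int(n)
        if op == "=":
            matches += int(n)
    return matches / aln_len if aln_len else 0.0


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_proteins(
    proteins: Sequence[ProteinRecord],
    identity_threshold: float = 0.30,
    prefilter_k: int = 5,
    assignments: Optional[dict[str, int]] = None,
) -> list[ProteinCluster]:
    """Greedy longest-first single-pass clustering.

    Proteins are visited longest first (ties by id); each joins the first
    existing cluster whose seed shares > ``identity_threshold`` global
    identity, else founds a new cluster. Pairs sharing no ``prefilter_k``-mer
    are skipped without alignment. ``assignments`` (protein id -> cluster
    index) bypasses the internal estimator entirely, e.g. to inject CD-HIT
    output.
    """
    if not proteins:
        raise ValueError("cluster_proteins requires at least one protein")

    if assignments is not None:
        by_idx: dict[int, list[ProteinRecord]] = defaultdict(list)
        for p in proteins:
            by_idx[assignments[p.id]].append(p)
        return [
            ProteinCluster(members=members, representative=members[0])
            for _, members in sorted(by_idx.items())
        ]

    order = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    seeds: list[ProteinRecord] = []
    seed_kmers: list[frozenset[str]] = []
    clusters: list[list[ProteinRecord]] = []
    for p in order:
        kmers = _kmer_set(p.sequence, prefilter_k)
        home = None
        for ci, seed in enumerate(seeds):
            if seed_kmers[ci] and kmers and seed_kmers[ci].isdisjoint(kmers):
                continue
            if pairwise_identity(seed.sequence, p.sequence) > identity_threshold:
                home = ci
                break
        if home is None:
            seeds.append(p)
            seed_kmers.append(kmers)
            clusters.append([p])
        else:
            clusters[home].append(p)
    return [
        ProteinCluster(members=members, representative=seed)
        for seed, members in zip(seeds, clusters)
    ]


def _positive_counts(sites: Iterable[SiteRecord]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for s in sites:
        if s.label == POSITIVE:
            counts[s.protein_id] += 1
    return counts


def select_representative(
    cluster: ProteinCluster, sites: Sequence[SiteRecord]
) -> ProteinRecord:
    """Member with the most positive sites; ties broken by longer sequence,
    then lexicographically smaller id."""
    if not cluster.members:
        raise ValueError("empty cluster")
    counts = _positive_counts(sites)
    return max(
        cluster.members,
        key=lambda p: (counts.get(p.id, 0), len(p.sequence), _NegStr(p.id)),
    )


class _NegStr(str):
    """Reverses string comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _site_7mer(protein: ProteinRecord, position: int) -> str:
    """Center +/-3 7-mer around a 1-based position, '-'-padded at termini."""
    i = position - 1
    seq = protein.sequence
    left = seq[max(0, i - 3) : i]
    right = seq[i + 1 : i + 4]
    return "-" * (3 - len(left)) + left + seq[i] + right + "-" * (3 - len(right))


def exclude_aligned_positives(
    representative: ProteinRecord,
    members: Sequence[ProteinRecord],
    sites: Sequence[SiteRecord],
) -> list[SiteRecord]:
    """Sites of the representative, minus negatives whose aligned counterpart
    in another cluster member is modified.

    Correspondence is approximated by exact center-7-mer match: a negative
    lysine of the representative is dropped (not relabeled) when some other
    member carries a positive lysine with an identical +/-3 flank.
    """
    by_id = {m.id: m for m in members}
    foreign_pos_7mers = {
        _site_7mer(by_id[s.protein_id], s.position)
        for s in sites
        if s.label == POSITIVE
        and s.protein_id in by_id
        and s.protein_id != representative.id
    }
    out = []
    for s in sites:
        if s.protein_id != representative.id:
            continue
        if (
            s.label == NEGATIVE
            and foreign_pos_7mers
            and _site_7mer(representative, s.position) in foreign_pos_7mers
        ):
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# steps 3-4: window extraction and conflict removal


def extract_window(
    protein: ProteinRecord,
    position: int,
    window: int = 31,
    label: int = NEGATIVE,
) -> PeptideWindow:
    """The ``window``-residue peptide centered on a 1-based lysine position,
    '-'-padded where the protein terminates."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window size must be odd and positive, got {window}")
    i = position - 1
    seq = protein.sequence
    if i < 0 or i >= len(seq):
        raise ValueError(f"position {position} outside protein {protein.id}")
    if seq[i] != "K":
        raise ValueError(
            f"site table corrupt: residue at {protein.id}:{position} is "
            f"{seq[i]!r}, not 'K'"
        )
    half = window // 2
    left = seq[max(0, i - half) : i]
    right = seq[i + 1 : i + 1 + half]
    padded = "-" * (half - len(left)) + left + "K" + right + "-" * (half - len(right))
    return PeptideWindow(
        sequence=padded, label=label, protein_id=protein.id, center_position=position
    )


def windows_from_sites(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteRecord],
    window: int = 31,
) -> list[PeptideWindow]:
    by_id = {p.id: p for p in proteins}
    return [
        extract_window(by_id[s.protein_id], s.position, window=window, label=s.label)
        for s in sites
    ]


def remove_conflicting_7mers(
    windows_pos: Sequence[PeptideWindow],
    windows_neg: Sequence[PeptideWindow],
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Drop every window (either label) whose center 7-mer occurs in both a
    positive and a negative window."""
    pos7 = {w.center_7mer() for w in windows_pos}
    neg7 = {w.center_7mer() for w in windows_neg}
    shared = pos7 & neg7
    keep_pos = [w for w in windows_pos if w.center_7mer() not in shared]
    keep_neg = [w for w in windows_neg if w.center_7mer() not in shared]
    return keep_pos, keep_neg


# ---------------------------------------------------------------------------
# step 5: protein-grouped splitting


def _proteins_of(windows: Sequence[PeptideWindow]) -> list[str]:
    return sorted({w.protein_id for w in windows})


def split_by_protein(
    windows: Sequence[PeptideWindow],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition proteins (not windows) into train/test."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = _proteins_of(windows)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1) if len(ids) > 1 else len(ids)
    train_ids = set(ids[:n_train])
    train = [w for w in windows if w.protein_id in train_ids]
    test = [w for w in windows if w.protein_id not in train_ids]
    return DatasetSplit(train=train, test=test, seed=seed)


def group_kfold(
    windows: Sequence[PeptideWindow],
    k: int = 10,
    seed: int = 0,
) -> list[tuple[list[PeptideWindow], list[PeptideWindow]]]:
    """k folds with each protein's windows confined to one validation fold;
    folds balanced by protein count."""
    ids = _proteins_of(windows)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} proteins, have {len(ids)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    fold_of = {pid: i % k for i, pid in enumerate(ids)}
    folds: list[tuple[list[PeptideWindow], list[PeptideWindow]]] = []
    for f in range(k):
        val = [w for w in windows if fold_of[w.protein_id] == f]
        train = [w for w in windows if fold_of[w.protein_id] != f]
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# end-to-end convenience


def build_windows(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteRecord],
    window: int = 31,
    identity_threshold: float = 0.30,
    min_score: float = 50.0,
    min_locprob: float = 0.75,
    cluster_assignments: Optional[dict[str, int]] = None,
) -> tuple[list[PeptideWindow], dict]:
    """Run construction steps 1-4 and return windows plus stage counts."""
    sites = filter_high_confidence(sites, min_score=min_score, min_locprob=min_locprob)
    clusters = cluster_proteins(
        proteins, identity_threshold=identity_threshold, assignments=cluster_assignments
    )
    kept_sites: list[SiteRecord] = []
    representatives: list[ProteinRecord] = []
    for cl in clusters:
        rep = select_representative(cl, sites)
        cl.representative = rep
        representatives.append(rep)
        kept_sites.extend(exclude_aligned_positives(rep, cl.members, sites))
    all_windows = windows_from_sites(representatives, kept_sites, window=window)
    pos = [w for w in all_windows if w.label == POSITIVE]
    neg = [w for w in all_windows if w.label == NEGATIVE]
    pos, neg = remove_conflicting_7mers(pos, neg)
    info = {
        "n_proteins_in": len(proteins),
        "n_clusters": len(clusters),
        "n_sites_high_confidence": len(sites),
        "n_sites_representatives": len(kept_sites),
        "n_pos_windows": len(pos),
        "n_neg_windows": len(neg),
        "window": window,
    }
    return pos + neg, info
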