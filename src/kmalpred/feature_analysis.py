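"""Interpretation analyses.

* ``two_sample_logo`` — per-(position, residue) comparison of modified vs
  unmodified window sets: a two-proportion z-test on occurrence indicators
  (the large-sample equivalent of a two-sample t-test on 0/1 data) with a
  Fisher-exact fallback for sparse cells, Bonferroni-corrected over all
  30 x 20 = 600 (position, residue) pairs of a 31-mer (the constant center
  is excluded).
* ``information_gain_ranking`` — ranks features by the reduction in label
  entropy (bits) after supervised minimum-description-length discretization
  (equal-frequency 10-bin fallback when MDL accepts no split).
* ``cluster_embeddings`` — average-linkage hierarchical clustering of the 20
  learned residue word-vectors under Euclidean distance, exportable as a
  Newick tree.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.stats import fisher_exact, norm

from .alphabet import AA_ORDER
from .models import EmbeddingMatrix
from .records import PeptideWindow


# ---------------------------------------------------------------------------
# two-sample logo statistics


@dataclass(frozen=True)
class EnrichmentCell:
    """One significant (position, residue) contrast between the two sets."""

    position: int  # center-relative, never 0
    residue: str
    freq_pos: float
    freq_neg: float
    p_raw: float
    p_adj: float
    direction: str  # 'enriched' (in positives) or 'depleted'


def _occurrence_counts(windows: Sequence[PeptideWindow], width: int) -> np.ndarray:
    """(width, 20) counts of each residue at each window index."""
    counts = np.zeros((width, 20), dtype=np.int64)
    idx = {aa: j for j, aa in enumerate(AA_ORDER)}
    for w in windows:
        for i, ch in enumerate(w.sequence):
            j = idx.get(ch)
            if j is not None:
                counts[i, j] += 1
    return counts


def _two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided p for H0: p1 == p2; exact test when any cell count is < 5."""
    if min(x1, n1 - x1, x2, n2 - x2) < 5:
        _, p = fisher_exact([[x1, n1 - x1], [x2, n2 - x2]], alternative="two-sided")
        return float(p)
    p1, p2 = x1 / n1, x2 / n2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se == 0.0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * norm.sf(abs(z)))


def two_sample_logo(
    pos_windows: Sequence[PeptideWindow],
    neg_windows: Sequence[PeptideWindow],
    alpha: float = 0.05,
) -> list[EnrichmentCell]:
    """Significant residue enrichments/depletions around the modified lysine.

    Returns the cells with Bonferroni-adjusted p < ``alpha``; the family is
    every (position, residue) pair excluding the constant center.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window sets must be non-empty")
    width = pos_windows[0].width
    cpos = _occurrence_counts(pos_windows, width)
    cneg = _occurrence_counts(neg_windows, width)
    n1, n2 = len(pos_windows), len(neg_windows)
    center = width // 2
    n_tests = (width - 1) * 20
    cells: list[EnrichmentCell] = []
    for i in range(width):
        if i == center:
            continue
        offset = i - center
        for j, aa in enumerate(AA_ORDER):
            x1, x2 = int(cpos[i, j]), int(cneg[i, j])
            f1, f2 = x1 / n1, x2 / n2
            if f1 == f2:
                continue
            p = _two_proportion_p(x1, n1, x2, n2)
            p_adj = min(1.0, p * n_tests)
            if p_adj < alpha:
                cells.append(
                    EnrichmentCell(
                        position=offset, residue=aa, freq_pos=f1, freq_neg=f2,
                        p_raw=p, p_adj=p_adj,
                        direction="enriched" if f1 > f2 else "depleted",
                    )
                )
    cells.sort(key=lambda c: (c.p_adj, c.position, c.residue))
    return cells


def write_enrichment_table(cells: Sequence[EnrichmentCell], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "residue", "freq_pos", "freq_neg",
                         "p_raw", "p_adj", "direction"])
        for c in cells:
            writer.writerow([c.position, c.residue, f"{c.freq_pos:.6f}",
                             f"{c.freq_neg:.6f}", f"{c.p_raw:.3e}",
                             f"{c.p_adj:.3e}", c.direction])


# ---------------------------------------------------------------------------
# information gain


@dataclass(frozen=True)
class RankedFeature:
    name: str
    information_gain: float  # bits
    rank: int  # 1-based
    binning: str  # 'mdl' or 'quantile10'


def _entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _mdl_split_points(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Fayyad-Irani recursive entropy splitting with the MDL stop rule."""
    order = np.argsort(x, kind="stable")
    return _mdl_recurse(x[order], y[order])


def _mdl_recurse(x: np.ndarray, y: np.ndarray) -> list[float]:
    n = len(y)
    if n < 2:
        return []
    h_all = _entropy(y)
    if h_all == 0.0:
        return []
    # candidate cut points: midpoints between distinct adjacent values
    change = np.nonzero(np.diff(x) > 0)[0]
    best_gain, best_i = -1.0, None
    for i in change:
        left, right = y[: i + 1], y[i + 1 :]
        h = (len(left) * _entropy(left) + len(right) * _entropy(right)) / n
        gain = h_all - h
        if gain > best_gain:
            best_gain, best_i = gain, i
    if best_i is None:
        return []
    left, right = y[: best_i + 1], y[best_i + 1 :]
    k = len(np.unique(y))
    k1, k2 = len(np.unique(left)), len(np.unique(right))
    delta = math.log2(3**k - 2) - (
        k * _entropy(y) - k1 * _entropy(left) - k2 * _entropy(right)
    )
    threshold = (math.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return []
    cut = (x[best_i] + x[best_i + 1]) / 2.0
    return (
        _mdl_recurse(x[: best_i + 1], left)
        + [float(cut)]
        + _mdl_recurse(x[best_i + 1 :], right)
    )


def _binned_ig(x: np.ndarray, y: np.ndarray, cuts: Sequence[float]) -> float:
    bins = np.digitize(x, cuts) if len(cuts) else np.zeros(len(x), dtype=int)
    h = _entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _entropy(y[mask])
    return max(0.0, h - cond)


def information_gain(x: np.ndarray, y: np.ndarray, binning: str = "mdl") -> tuple[float, str]:
    """IG of one real-valued feature in bits, with the binning actually used."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if binning == "mdl":
        cuts = _mdl_split_points(x, y)
        if cuts:
            return _binned_ig(x, y, cuts), "mdl"
        binning = "quantile10"
    if binning == "quantile10":
        qs = np.unique(np.quantile(x, np.linspace(0, 1, 11)[1:-1]))
        return _binned_ig(x, y, qs), "quantile10"
    raise ValueError(f"unknown binning {binning!r}")


def information_gain_ranking(
    X: np.ndarray,
    feature_names: Sequence[str],
    labels: Sequence[int],
    top_n: int = 30,
    binning: str = "mdl",
) -> list[RankedFeature]:
    """Features ranked by information gain, descending; ties broken by name."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature names and matrix width differ")
    scored = []
    for j, name in enumerate(feature_names):
        ig, used = information_gain(X[:, j], y, binning=binning)
        scored.append((name, ig, used))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        RankedFeature(name=name, information_gain=ig, rank=r + 1, binning=used)
        for r, (name, ig, used) in enumerate(scored[:top_n])
    ]


def write_ranked_features(features: Sequence[RankedFeature], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "feature", "information_gain_bits", "binning"])
        for f in features:
            writer.writerow([f.rank, f.name, f"{f.information_gain:.6f}", f.binning])


# ---------------------------------------------------------------------------
# embedding clustering


@dataclass
class Dendrogram:
    """Average-linkage merge history over labeled leaves."""

    leaves: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        n = len(self.leaves)

        def _fmt(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.leaves[node]}:{parent_h:.6g}"
            row = self.merges[node - n]
            h = row[2]
            left = _fmt(int(row[0]), h / 2.0)
            right = _fmt(int(row[1]), h / 2.0)
            return f"({left},{right}):{max(parent_h - h / 2.0, 0.0):.6g}"

        root = 2 * n - 2
        row = self.merges[-1]
        h = row[2]
        return f"({_fmt(int(row[0]), h / 2.0)},{_fmt(int(row[1]), h / 2.0)});"


def cluster_embeddings(embedding: EmbeddingMatrix | np.ndarray,
                       labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Hierarchically cluster residue word-vectors (Euclidean distance,
    average linkage). A 21-row embedding has its gap row dropped first."""
    if isinstance(embedding, EmbeddingMatrix):
        emb = embedding.residue_rows()
        X, leaves = emb.matrix, list(emb.symbols)
    else:
        X = np.asarray(embedding, dtype=float)
        leaves = list(labels) if labels is not None else [str(i) for i in range(len(X))]
    if len(X) != len(leaves):
        raise ValueError("labels and rows differ in length")
    if len(X) < 2:
        raise ValueError("need at least two rows to cluster")
    Z = linkage(X, method="average", metric="euclidean")
    return Dendrogram(leaves=leaves, merges=Z)
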