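"""Feature encodings for peptide windows.

The central encoding is EAAC (enhanced amino-acid composition): residue
frequencies counted in a short window slid across the peptide, giving
position-resolved composition. For a 31-residue peptide and slide length 8
this yields 24 sliding windows x 20 residues = 480 features named in
center-relative coordinates, e.g. ``G[-5,2]`` is the glycine frequency in
the sliding window covering offsets -5..+2.

Conventions (recorded in model metadata):

* feature/column order of residues is fixed alphabetical (ACDEFGHIKLMNPQRSTVWY);
* terminal gaps '-' (and unknown residues 'X') contribute 0 to every residue
  count; the EAAC denominator stays the slide length, so composition near a
  terminus is diluted rather than renormalized;
* one-hot rows for gaps are 0.05 in all 20 columns (rows sum to 1 either way);
* AAindex values at gap positions are 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA_ORDER, AA_TO_INDEX, GAP_ID, tokenize
from .records import FeatureVector, PeptideWindow

GAP_ONEHOT_VALUE = 0.05


def _window_tokens(window) -> np.ndarray:
    seq = window.sequence if isinstance(window, PeptideWindow) else str(window)
    return tokenize(seq)


def _offsets(width: int) -> np.ndarray:
    half = width // 2
    return np.arange(width) - half


# ---------------------------------------------------------------------------
# EAAC / AAC


def eaac_feature_names(width: int = 31, slide: int = 8) -> list[str]:
    offs = _offsets(width)
    names = []
    for s in range(width - slide + 1):
        lo, hi = offs[s], offs[s + slide - 1]
        for aa in AA_ORDER:
            names.append(f"{aa}[{lo},{hi}]")
    return names


def eaac_matrix(
    windows: Sequence[PeptideWindow] | Sequence[str], slide: int = 8
) -> tuple[np.ndarray, list[str]]:
    """EAAC features for a batch of equal-width windows.

    Returns ``(X, names)`` with ``X`` of shape (n, (W-slide+1)*20).
    """
    if not len(windows):
        raise ValueError("no windows to encode")
    toks = np.stack([_window_tokens(w) for w in windows])
    n, width = toks.shape
    if slide <= 0 or slide > width:
        raise ValueError(f"slide {slide} incompatible with window width {width}")
    onehot = np.zeros((n, width + 1, 20))
    valid = toks < 20
    idx = np.nonzero(valid)
    onehot[idx[0], idx[1] + 1, toks[idx]] = 1.0
    csum = np.cumsum(onehot, axis=1)
    n_win = width - slide + 1
    X = np.empty((n, n_win * 20))
    for s in range(n_win):
        X[:, s * 20 : (s + 1) * 20] = (csum[:, s + slide] - csum[:, s]) / slide
    return X, eaac_feature_names(width, slide)


def encode_eaac(window: PeptideWindow | str, slide: int = 8) -> FeatureVector:
    X, names = eaac_matrix([window], slide=slide)
    return FeatureVector(names=names, values=X[0].tolist())


def encode_aac(window: PeptideWindow | str) -> FeatureVector:
    """Whole-window residue frequencies; gaps count in the denominator only."""
    toks = _window_tokens(window)
    counts = np.bincount(toks[toks < 20], minlength=20).astype(float)
    values = counts / len(toks)
    return FeatureVector(names=list(AA_ORDER), values=values.tolist())


# ---------------------------------------------------------------------------
# one-hot and tokens


def encode_onehot(window: PeptideWindow | str) -> np.ndarray:
    """(W, 20) matrix; residue rows are indicators, gap rows uniform 0.05."""
    toks = _window_tokens(window)
    out = np.full((len(toks), 20), GAP_ONEHOT_VALUE)
    for i, t in enumerate(toks):
        if t < 20:
            out[i] = 0.0
            out[i, t] = 1.0
    return out


def onehot_tensor(windows: Sequence[PeptideWindow] | Sequence[str]) -> np.ndarray:
    return np.stack([encode_onehot(w) for w in windows])


def encode_tokens(window: PeptideWindow | str) -> np.ndarray:
    """Integer token ids (0..19 residues, 20 gap); round-trips via detokenize."""
    return _window_tokens(window)


def token_matrix(windows: Sequence[PeptideWindow] | Sequence[str]) -> np.ndarray:
    return np.stack([_window_tokens(w) for w in windows])


# ---------------------------------------------------------------------------
# AAindex


@dataclass(frozen=True)
class AAindexTable:
    """One physicochemical property scale: a real value per residue."""

    property_id: str
    values: tuple[float, ...]  # aligned with AA_ORDER
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != 20 or not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"property {self.property_id}: need 20 finite values"
            )


# AAindex flat-file residue order on the two value lines following 'I'.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTVWY"


def read_aaindex(path) -> list[AAindexTable]:
    """Parse an AAindex1 flat file; properties with any 'NA' are dropped."""
    tables: list[AAindexTable] = []
    prop_id, desc, collecting, raw = None, "", False, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                prop_id = line[2:].strip()
            elif line.startswith("D "):
                desc = line[2:].strip()
            elif line.startswith("I "):
                collecting, raw = True, []
            elif collecting and line.startswith(" "):
                raw.extend(line.split())
            elif line.startswith("//"):
                if prop_id is not None and len(raw) == 20 and "NA" not in raw:
                    order = _AAINDEX_ROW1 + _AAINDEX_ROW2
                    by_aa = {aa: float(v) for aa, v in zip(order, raw)}
                    tables.append(
                        AAindexTable(
                            property_id=prop_id,
                            values=tuple(by_aa[aa] for aa in AA_ORDER),
                            description=desc,
                        )
                    )
                prop_id, desc, collecting, raw = None, "", False, []
    return tables


def encode_aaindex(
    window: PeptideWindow | str, properties: Sequence[AAindexTable]
) -> FeatureVector:
    """Per-position property values; dimension W x n_properties.

    Gap (and unknown-residue) positions contribute 0 for every property.
    """
    if not properties:
        raise ValueError("no AAindex properties supplied")
    toks = _window_tokens(window)
    offs = _offsets(len(toks))
    names, values = [], []
    for prop in properties:
        vals = np.asarray(prop.values)
        for i, t in enumerate(toks):
            names.append(f"{prop.property_id}[{offs[i]}]")
            values.append(float(vals[t]) if t < 20 else 0.0)
    return FeatureVector(names=names, values=values)


def aaindex_matrix(
    windows: Sequence[PeptideWindow] | Sequence[str],
    properties: Sequence[AAindexTable],
) -> tuple[np.ndarray, list[str]]:
    if not properties:
        raise ValueError("no AAindex properties supplied")
    toks = token_matrix(windows)
    width = toks.shape[1]
    offs = _offsets(width)
    blocks, names = [], []
    for prop in properties:
        lut = np.append(np.asarray(prop.values), 0.0)  # gap id -> 0
        blocks.append(lut[toks])
        names.extend(f"{prop.property_id}[{o}]" for o in offs)
    return np.concatenate(blocks, axis=1), names


def rank_aaindex_properties(
    tables: Sequence[AAindexTable],
    windows: Sequence[PeptideWindow],
    labels: Sequence[int] | None = None,
    auc_cutoff: float = 0.7,
    top_n: int = 11,
    k: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Rank property scales by forest cross-validation AUC, one scale at a
    time (W features each); return the ``top_n`` property ids among those
    with AUC > ``auc_cutoff``."""
    from .models import train_forest  # local import to avoid a cycle
    from .evaluation import roc_auc
    from .dataset import group_kfold

    if not windows:
        raise ValueError("empty dataset")
    if labels is None:
        labels = [w.label for w in windows]
    label_of = {id(w): y for w, y in zip(windows, labels)}
    folds = group_kfold(windows, k=k, seed=seed)
    scored: list[tuple[float, str]] = []
    for prop in tables:
        ys, ss = [], []
        for train, val in folds:
            Xtr, names = aaindex_matrix(train, [prop])
            ytr = np.array([label_of[id(w)] for w in train])
            if len(set(ytr.tolist())) < 2:
                continue
            model = train_forest(Xtr, ytr, feature_names=names, n_trees=n_trees, seed=seed)
            Xva, _ = aaindex_matrix(val, [prop])
            ss.append(model.predict_scores(Xva))
            ys.append([label_of[id(w)] for w in val])
        scores = np.concatenate(ss)
        y = np.concatenate(ys)
        _, auc = roc_auc(scores, y)
        scored.append((auc, prop.property_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [pid for auc, pid in scored if auc > auc_cutoff][:top_n]


# ---------------------------------------------------------------------------
# comparator encodings (standard published forms; not part of the core model)

# Five-dimensional z-scale descriptors (Sandberg et al. 1998): lipophilicity,
# steric bulk/polarizability, polarity, and two electronic-property scales.
_ZSCALES = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}

COMPARATOR_SCHEMES = ("blosum62", "binary", "cksaap", "zscales")


def encode_comparators(window: PeptideWindow | str, scheme: str) -> FeatureVector:
    """Reference encodings used for benchmarking against EAAC."""
    toks = _window_tokens(window)
    offs = _offsets(len(toks))
    if scheme == "binary":
        mat = encode_onehot(window)
        names = [f"bin:{aa}[{o}]" for o in offs for aa in AA_ORDER]
        return FeatureVector(names=names, values=mat.ravel().tolist())
    if scheme == "blosum62":
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        names, values = [], []
        for i, t in enumerate(toks):
            for aa in AA_ORDER:
                names.append(f"b62:{aa}[{offs[i]}]")
                values.append(float(blosum[AA_ORDER[t], aa]) if t < 20 else 0.0)
        return FeatureVector(names=names, values=values)
    if scheme == "zscales":
        names, values = [], []
        for i, t in enumerate(toks):
            zs = _ZSCALES[AA_ORDER[t]] if t < 20 else (0.0,) * 5
            for j, z in enumerate(zs):
                names.append(f"z{j + 1}[{offs[i]}]")
                values.append(z)
        return FeatureVector(names=names, values=values)
    if scheme == "cksaap":
        names, values = [], []
        for kk in range(5):
            counts = np.zeros((20, 20))
            n_pairs = len(toks) - kk - 1
            for i in range(n_pairs):
                a, b = toks[i], toks[i + kk + 1]
                if a < 20 and b < 20:
                    counts[a, b] += 1
            for a in AA_ORDER:
                for b in AA_ORDER:
                    names.append(f"{a}x{b}|k={kk}")
            values.extend((counts / n_pairs).ravel().tolist())
        return FeatureVector(names=names, values=values)
    raise ValueError(f"unknown comparator scheme {scheme!r}; choose from {COMPARATOR_SCHEMES}")
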