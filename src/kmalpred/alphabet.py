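"""Residue alphabet shared by every encoding and model.

The working alphabet is the 20 standard amino acids in fixed alphabetical
one-letter order plus the terminal-gap symbol ``-``. Token ids are stable
across runs and persisted with trained models; changing the order would
silently invalidate saved model bundles.
"""

from __future__ import annotations

import numpy as np

#: Fixed alphabetical amino-acid order used for every feature/column layout.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Terminal padding symbol for windows that overhang a protein end.
GAP: str = "-"

#: Placeholder for non-standard residues (B, Z, U, O, X ... are folded here).
UNKNOWN: str = "X"

#: Full token alphabet: 20 amino acids then the gap. ``X`` shares the gap id
#: for token purposes (it carries no composition information).
ALPHABET: str = AA_ORDER + GAP

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}
GAP_ID: int = len(AA_ORDER)  # 20
VOCAB_SIZE: int = len(ALPHABET)  # 21

_NONSTANDARD = set("BJZUOX")


def canonicalize_residue(ch: str) -> str:
    """Map an input character to the working alphabet.

    Standard residues pass through (upper-cased); any non-standard residue
    code becomes ``X``; the gap symbol is preserved. Anything else raises.
    """
    up = ch.upper()
    if up in AA_TO_INDEX or up == GAP:
        return up
    if up in _NONSTANDARD:
        return UNKNOWN
    raise ValueError(f"unmappable residue character {ch!r}")


def canonicalize_sequence(seq: str) -> str:
    return "".join(canonicalize_residue(c) for c in seq)


def tokenize(window: str) -> np.ndarray:
    """Integer token ids for a peptide window.

    Amino acids map to 0..19 (alphabetical order), the gap to 20. Unknown
    residues ('X') also map to the gap id: they contribute no composition.
    """
    out = np.empty(len(window), dtype=np.int64)
    for i, ch in enumerate(window):
        c = canonicalize_residue(ch)
        out[i] = AA_TO_INDEX.get(c, GAP_ID)
    return out


def detokenize(tokens) -> str:
    """Inverse of :func:`tokenize` (unknown residues come back as '-')."""
    return "".join(ALPHABET[int(t)] for t in tokens)
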