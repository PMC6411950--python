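"""Core record types passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

POSITIVE = 1
NEGATIVE = 0

LABEL_NAMES = {POSITIVE: "positive", NEGATIVE: "negative"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A labeled lysine site (1-based position in its protein).

    ``andromeda_score`` and ``localization_prob`` are the mass-spec
    identification confidence values used by the high-confidence filter;
    they are typically present for positive sites only.
    """

    protein_id: str
    position: int
    label: int
    andromeda_score: Optional[float] = None
    localization_prob: Optional[float] = None


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide window centered on a lysine.

    The window has odd length W (default 31), uses '-' for positions that
    overhang a protein terminus, and always carries 'K' at its center.
    """

    sequence: str
    label: int
    protein_id: str
    center_position: int  # 1-based position of the center K in the protein

    def __post_init__(self) -> None:
        w = len(self.sequence)
        if w % 2 != 1:
            raise ValueError(f"window length {w} must be odd")
        if self.sequence[w // 2] != "K":
            raise ValueError(
                f"window center is {self.sequence[w // 2]!r}, expected 'K' "
                f"({self.protein_id} pos {self.center_position})"
            )

    @property
    def width(self) -> int:
        return len(self.sequence)

    def center_7mer(self) -> str:
        """The 7-residue peptide (center +/-3) used for conflict removal."""
        c = len(self.sequence) // 2
        return self.sequence[c - 3 : c + 4]


@dataclass
class ProteinCluster:
    """A group of proteins sharing > identity-threshold sequence identity."""

    members: list[ProteinRecord]
    representative: ProteinRecord

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if self.representative.id not in ids:
            raise ValueError("representative must be a cluster member")


@dataclass
class DatasetSplit:
    """Protein-grouped train/test partition of peptide windows."""

    train: list[PeptideWindow]
    test: list[PeptideWindow]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        tr = {w.protein_id for w in self.train}
        te = {w.protein_id for w in self.test}
        overlap = tr & te
        if overlap:
            raise ValueError(f"proteins straddle the split: {sorted(overlap)[:5]}")


@dataclass
class FeatureVector:
    """Named, ordered real-valued features produced by an encoding."""

    names: list[str]
    values: "list[float]"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("feature names and values differ in length")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))
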