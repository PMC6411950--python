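"""Synthetic proteomes with plantable malonylation sequence motifs.

Every other module is testable without the original proteomic data because
this generator produces FASTA + site tables in the pipeline's own dialects,
with a controllable position-specific sequence signal around labeled lysines.

The default motif mirrors the enrichment pattern observed around real
malonylation sites: glycine enriched at positions -4..+2 and lysine depleted
at -1..+2 in positive flanks, and glutamic acid enriched around negative
sites (-4..+4 except -1 and +3). Effects are applied as log-odds shifts to a
per-position categorical residue distribution; the defaults constitute the
"strong effect" condition used throughout the test-suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, AA_TO_INDEX
from .records import NEGATIVE, POSITIVE, ProteinRecord, SiteRecord
from . import io as kio


@dataclass(frozen=True)
class MotifEffect:
    """A log-odds shift applied to one residue at a set of flank offsets.

    Offsets are center-relative (the center lysine itself, offset 0, is
    never touched). Positive ``log_odds`` enriches the residue, negative
    depletes it.
    """

    positions: tuple[int, ...]
    residue: str
    log_odds: float

    def __post_init__(self) -> None:
        if self.residue not in AA_TO_INDEX:
            raise ValueError(f"unknown residue {self.residue!r}")
        if 0 in self.positions:
            raise ValueError("offset 0 is the center lysine; it cannot carry an effect")
        if any(abs(p) > 15 for p in self.positions):
            raise ValueError("motif offsets must lie within -15..+15")


def _span(a: int, b: int, skip: tuple[int, ...] = (0,)) -> tuple[int, ...]:
    return tuple(p for p in range(a, b + 1) if p not in skip)


DEFAULT_POSITIVE_MOTIF: tuple[MotifEffect, ...] = (
    MotifEffect(_span(-4, 2), "G", +2.5),
    MotifEffect(_span(-1, 2), "K", -3.0),
)
DEFAULT_NEGATIVE_MOTIF: tuple[MotifEffect, ...] = (
    MotifEffect(_span(-4, 4, skip=(0, -1, 3)), "E", +1.5),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the strong-effect condition."""

    n_proteins: int = 2000
    mean_length: int = 80
    background_frequencies: tuple[float, ...] | None = None  # None -> uniform 1/20
    positive_fraction_of_k: float = 0.2
    positive_motif: tuple[MotifEffect, ...] = DEFAULT_POSITIVE_MOTIF
    negative_motif: tuple[MotifEffect, ...] = DEFAULT_NEGATIVE_MOTIF
    duplication_rate: float = 0.05
    min_site_spacing: int = 8
    seed: int = 0

    def background(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(20, 1.0 / 20.0)
        bg = np.asarray(self.background_frequencies, dtype=float)
        if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background_frequencies must be 20 fractions summing to 1")
        return bg / bg.sum()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.positive_fraction_of_k <= 1.0:
            raise ValueError("positive_fraction_of_k must be in [0, 1]")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must be in [0, 1]")
        self.background()

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """A configuration with no planted motif (label-independent flanks)."""
        return cls(positive_motif=(), negative_motif=(), **overrides)


@dataclass
class SyntheticTruth:
    """Generated proteome + labels + per-site provenance."""

    proteins: list[ProteinRecord]
    sites: list[SiteRecord]
    motif_planted: dict[tuple[str, int], bool]
    config: SyntheticConfig


def position_distribution(config: SyntheticConfig, label: int, offset: int) -> np.ndarray:
    """Residue distribution sampled at a center-relative flank offset of a
    planted site; this is the analytic ground truth for calibration tests.

    Positive-site flanks never sample a lysine unless the motif explicitly
    places one there: planting a positive motif must not mint new lysine
    sites whose own windows would mimic the positive pattern while being
    labeled negative.
    """
    weights = config.background().copy()
    motif = config.positive_motif if label == POSITIVE else config.negative_motif
    explicit_k = False
    for eff in motif:
        if offset in eff.positions:
            weights[AA_TO_INDEX[eff.residue]] *= math.exp(eff.log_odds)
            explicit_k = explicit_k or eff.residue == "K"
    if label == POSITIVE and motif and not explicit_k:
        weights[AA_TO_INDEX["K"]] = 0.0
    return weights / weights.sum()


def _sample_sequence(rng: np.random.Generator, length: int, bg: np.ndarray) -> np.ndarray:
    return rng.choice(20, size=length, p=bg)


def _select_site_indices(
    rng: np.random.Generator, k_positions: np.ndarray, spacing: int
) -> list[int]:
    """Random-order greedy selection of lysines pairwise >= ``spacing`` apart.

    Visiting lysines in random order (not left to right) keeps the crowding
    geometry symmetric: an enrolled site is equally likely to have a skipped
    neighboring lysine on either flank, so flank-lysine frequencies carry no
    positional artifact of the enrollment scan.
    """
    chosen: list[int] = []
    for p in rng.permutation(k_positions):
        if all(abs(int(p) - c) >= spacing for c in chosen):
            chosen.append(int(p))
    return chosen


def generate_proteome(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a proteome with labeled lysine sites; deterministic from seed.

    Residues are iid from the background; a spaced subset of lysines is
    selected as sites, labeled positive with probability
    ``positive_fraction_of_k``, and the flanks of each selected site are
    resampled under the label's motif-shifted distributions. Lysines that
    were skipped (or created by resampling) become plain negative sites with
    no planted motif. A configured fraction of proteins is duplicated with
    light mutation to exercise redundancy reduction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg = config.background()
    k_id = AA_TO_INDEX["K"]

    # Precompute per-offset sampling distributions for both labels.
    offsets = range(-15, 16)
    dist = {
        (lab, off): position_distribution(config, lab, off)
        for lab in (POSITIVE, NEGATIVE)
        for off in offsets
        if off != 0
    }

    for attempt in range(5):
        proteins: list[ProteinRecord] = []
        sites: list[SiteRecord] = []
        planted: dict[tuple[str, int], bool] = {}

        for i in range(config.n_proteins):
            length = max(31, int(rng.poisson(config.mean_length)))
            seq = _sample_sequence(rng, length, bg)
            pid = f"SYN{i:05d}"
            prot_sites = _plant_sites(rng, seq, pid, config, dist, k_id, sites, planted)
            proteins.append(ProteinRecord(id=pid, sequence=_to_str(seq)))

            if rng.random() < config.duplication_rate:
                dup_id = f"{pid}d"
                dup_seq, dup_sites = _mutate_duplicate(
                    rng, seq, prot_sites, dup_id, k_id, bg
                )
                proteins.append(ProteinRecord(id=dup_id, sequence=_to_str(dup_seq)))
                for s in dup_sites:
                    sites.append(s)
                    planted[(s.protein_id, s.position)] = planted.get((pid, s.position), False)

        if any(s.label == POSITIVE for s in sites):
            return SyntheticTruth(proteins=proteins, sites=sites, motif_planted=planted, config=config)
        warnings.warn("generated proteome contains no positive site; regenerating")
        rng = np.random.default_rng(rng.integers(2**31 - 1))
    raise RuntimeError("could not generate a proteome with at least one positive site")


def _to_str(seq: np.ndarray) -> str:
    return "".join(AA_ORDER[r] for r in seq)


def _plant_sites(rng, seq, pid, config, dist, k_id, sites, planted) -> list[SiteRecord]:
    """Label and motif-edit the lysines of one protein, in place on ``seq``."""
    k_positions = np.flatnonzero(seq == k_id)  # 0-based
    chosen = set(_select_site_indices(rng, k_positions, config.min_site_spacing))
    effect_offsets = {
        POSITIVE: {o for e in config.positive_motif for o in e.positions},
        NEGATIVE: {o for e in config.negative_motif for o in e.positions},
    }
    prot_sites: list[SiteRecord] = []
    for p in sorted(chosen):
        label = POSITIVE if rng.random() < config.positive_fraction_of_k else NEGATIVE
        for off in range(-15, 16):
            if off == 0:
                continue
            q = p + off
            if q < 0 or q >= len(seq) or q in chosen:
                continue
            # Only offsets that deviate from the background are resampled:
            # effect-carrying offsets always, and (for positives) offsets
            # holding a lysine, which is redrawn from the lysine-free
            # background so the resulting distribution matches
            # position_distribution exactly. Leaving plain background
            # positions untouched keeps nearby sites' planted flanks intact.
            carries_effect = off in effect_offsets[label]
            strip_k = (
                label == POSITIVE and config.positive_motif and seq[q] == k_id
            )
            if carries_effect or strip_k:
                seq[q] = rng.choice(20, p=dist[(label, off)])
        if label == POSITIVE:
            score = float(rng.normal(90.0, 20.0))
            prob = float(rng.beta(9.0, 1.0))
        else:
            score, prob = None, None
        rec = SiteRecord(pid, p + 1, label, score, prob)
        prot_sites.append(rec)
        planted[(pid, p + 1)] = True

    # Crowded lysines (closer than the spacing to an enrolled site) are NOT
    # enrolled at all. Enrolling them as automatic negatives would leak
    # sequence information (lysine crowding) into the labels, and a null
    # configuration would no longer sit at AUC 0.5: enrollment must be
    # label-blind, so every enrolled site — positive or negative — is a
    # spaced lysine and the only label signal is the planted motif.
    prot_sites.sort(key=lambda s: s.position)
    sites.extend(prot_sites)
    return prot_sites


def _mutate_duplicate(rng, seq, prot_sites, dup_id, k_id, bg, mutation_rate: float = 0.05):
    """Copy a protein with light point mutation, preserving site 7-mers.

    Site centers and their +/-3 flanks are kept intact so aligned-counterpart
    detection across the cluster remains exercised; positives are carried
    over with probability 1/2 (downgraded to negative otherwise) so the
    duplicate usually has fewer positives than the original.
    """
    dup = seq.copy()
    protected = set()
    for s in prot_sites:
        for off in range(-3, 4):
            protected.add(s.position - 1 + off)
    for q in range(len(dup)):
        if q in protected or dup[q] == k_id:
            continue
        if rng.random() < mutation_rate:
            new = int(rng.choice(20, p=bg))
            if new != k_id:  # do not create new lysines in the copy
                dup[q] = new
    dup_sites = []
    for s in prot_sites:
        if s.label == POSITIVE and rng.random() < 0.5:
            dup_sites.append(SiteRecord(dup_id, s.position, POSITIVE, s.andromeda_score, s.localization_prob))
        else:
            dup_sites.append(SiteRecord(dup_id, s.position, NEGATIVE))
    return dup, dup_sites


def write_fixture(truth: SyntheticTruth, directory) -> dict[str, Path]:
    """Emit FASTA + site TSV (+ a config echo) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "proteins.fasta"
    table = directory / "sites.tsv"
    kio.write_fasta(truth.proteins, fasta)
    kio.write_site_table(truth.sites, table)
    meta = directory / "config.txt"
    with open(meta, "w") as fh:
        for k, v in vars(truth.config).items():
            fh.write(f"{k} = {v!r}\n")
    return {"fasta": fasta, "sites": table, "config": meta}
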