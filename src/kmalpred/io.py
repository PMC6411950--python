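"""Readers and writers for the plain-text dialects the pipeline exchanges.

Formats:

* proteins — standard FASTA (any wrap width; the record id is the first
  whitespace-delimited token of the header);
* site tables — TSV with header
  ``protein_id  position  label  andromeda_score  localization_prob``
  (the two score columns may be empty);
* window datasets — TSV with header ``protein_id  position  label  window``;
  round-trips bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .alphabet import canonicalize_sequence
from .records import LABEL_CODES, LABEL_NAMES, PeptideWindow, ProteinRecord, SiteRecord

PathLike = Union[str, Path]

SITE_COLUMNS = ["protein_id", "position", "label", "andromeda_score", "localization_prob"]
WINDOW_COLUMNS = ["protein_id", "position", "label", "window"]


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read proteins from FASTA; non-standard residues are folded to 'X'."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split()[0]
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, sequence=canonicalize_sequence(str(rec.seq))))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def _fmt_opt(value) -> str:
    return "" if value is None else repr(float(value))


def read_site_table(path: PathLike) -> list[SiteRecord]:
    sites = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SITE_COLUMNS[:3]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"site table {path} lacks columns {sorted(missing)}")
        for row in reader:
            score = row.get("andromeda_score") or None
            prob = row.get("localization_prob") or None
            sites.append(
                SiteRecord(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    label=LABEL_CODES[row["label"]],
                    andromeda_score=None if score is None else float(score),
                    localization_prob=None if prob is None else float(prob),
                )
            )
    return sites


def write_site_table(sites: Iterable[SiteRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS)
        for s in sites:
            writer.writerow(
                [
                    s.protein_id,
                    s.position,
                    LABEL_NAMES[s.label],
                    _fmt_opt(s.andromeda_score),
                    _fmt_opt(s.localization_prob),
                ]
            )


def read_window_table(path: PathLike) -> list[PeptideWindow]:
    windows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(WINDOW_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"window table {path} lacks columns {sorted(missing)}")
        for row in reader:
            windows.append(
                PeptideWindow(
                    sequence=row["window"],
                    label=LABEL_CODES[row["label"]],
                    protein_id=row["protein_id"],
                    center_position=int(row["position"]),
                )
            )
    return windows


def write_window_table(windows: Iterable[PeptideWindow], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(WINDOW_COLUMNS)
        for w in windows:
            writer.writerow([w.protein_id, w.center_position, LABEL_NAMES[w.label], w.sequence])
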