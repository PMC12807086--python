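"""Readers and writers for the on-disk formats of the methylation-calling pipeline.

All tabular formats are headerless, tab-separated text:

* **event table** — one row per translocation event:
  ``read_id  chrom  strand  ref_pos  ref_base  samples`` where *samples* is a
  comma-separated list of raw current values (one cell).
* **labels** — ``read_id  chrom  strand  ref_pos  label`` with label 1 =
  methylated, 0 = unmethylated.
* **predictions** — ``read_id  chrom  strand  ref_pos  prob  call`` with the
  methylation probability printed to 6 decimals and ``call = 1`` iff
  ``prob > 0.5``.
* **bedMethyl-style summary** — ``chrom  start  end  name  coverage  strand
  methylated_count  frequency_percent`` with half-open per-base intervals
  ``[pos, pos + 1)`` and the frequency printed as a percentage to 1 decimal.

Coordinates are 0-based throughout.  Reference genomes are standard
multi-record FASTA, read through Biopython.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, TYPE_CHECKING

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .summary import SiteSummary

VALID_BASES = frozenset("ACGT")
VALID_STRANDS = frozenset("+-")


class EventTableError(ValueError):
    """Malformed or invariant-violating row in an on-disk table."""


@dataclass
class Event:
    """One translocation event: a reference anchor plus its raw signal samples."""

    read_id: str
    chrom: str
    strand: str
    ref_pos: int
    ref_base: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.strand not in VALID_STRANDS:
            raise EventTableError(f"invalid strand {self.strand!r}")
        if self.ref_base not in VALID_BASES:
            raise EventTableError(f"invalid reference base {self.ref_base!r}")
        if self.ref_pos < 0:
            raise EventTableError(f"negative reference position {self.ref_pos}")
        if self.samples.size == 0:
            raise EventTableError("event has no signal samples")


@dataclass(frozen=True)
class LabeledSite:
    """Ground-truth methylation status of one site on one read."""

    read_id: str
    chrom: str
    strand: str
    ref_pos: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class ReadPrediction:
    """Per-read per-site methylation probability and hard call."""

    read_id: str
    chrom: str
    strand: str
    ref_pos: int
    prob: float
    call: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"probability {self.prob} outside [0, 1]")
        expected = 1 if self.prob > 0.5 else 0
        if self.call != expected:
            raise ValueError(
                f"call {self.call} inconsistent with prob {self.prob} "
                "(call = 1 iff prob > 0.5)"
            )


def read_event_table(path: str | os.PathLike) -> Dict[str, List[Event]]:
    """Read an event table, returning events grouped by read.

    Events within each read are sorted by reference position.  Raises
    :class:`EventTableError` naming the offending line on malformed rows.
    """
    by_read: Dict[str, List[Event]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise EventTableError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, chrom, strand, pos_s, base, samples_s = fields
            try:
                pos = int(pos_s)
                samples = np.array(samples_s.split(","), dtype=float)
                event = Event(read_id, chrom, strand, pos, base, samples)
            except (ValueError, EventTableError) as exc:
                raise EventTableError(f"{path}: line {lineno}: {exc}") from exc
            by_read.setdefault(read_id, []).append(event)
    for events in by_read.values():
        events.sort(key=lambda e: e.ref_pos)
    return by_read


def write_event_table(
    events_by_read: Mapping[str, Sequence[Event]], path: str | os.PathLike
) -> None:
    """Write events grouped by read; float samples use shortest round-trip repr."""
    with open(path, "w") as fh:
        for read_id in events_by_read:
            for e in events_by_read[read_id]:
                samples = ",".join(repr(float(s)) for s in e.samples)
                fh.write(
                    f"{e.read_id}\t{e.chrom}\t{e.strand}\t{e.ref_pos}\t"
                    f"{e.ref_base}\t{samples}\n"
                )


def read_labels(path: str | os.PathLike) -> List[LabeledSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise EventTableError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            try:
                sites.append(
                    LabeledSite(
                        fields[0], fields[1], fields[2], int(fields[3]), int(fields[4])
                    )
                )
            except ValueError as exc:
                raise EventTableError(f"{path}: line {lineno}: {exc}") from exc
    return sites


def write_labels(sites: Iterable[LabeledSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.read_id}\t{s.chrom}\t{s.strand}\t{s.ref_pos}\t{s.label}\n")


def read_predictions(path: str | os.PathLike) -> List[ReadPrediction]:
    preds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise EventTableError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(fields)}"
                )
            try:
                preds.append(
                    ReadPrediction(
                        fields[0],
                        fields[1],
                        fields[2],
                        int(fields[3]),
                        float(fields[4]),
                        int(fields[5]),
                    )
                )
            except ValueError as exc:
                raise EventTableError(f"{path}: line {lineno}: {exc}") from exc
    return preds


def write_predictions(
    preds: Iterable[ReadPrediction], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for p in preds:
            fh.write(
                f"{p.read_id}\t{p.chrom}\t{p.strand}\t{p.ref_pos}\t"
                f"{p.prob:.6f}\t{p.call}\n"
            )


def write_bedmethyl(summaries: Iterable["SiteSummary"], path: str | os.PathLike) -> None:
    """Write per-site summaries as bedMethyl-style lines sorted by (chrom, pos).

    Columns: chrom, start, end (= start + 1), name ("5mC"), coverage, strand,
    methylated_count, frequency as a percentage with 1 decimal place.
    """
    rows = sorted(summaries, key=lambda s: (s.chrom, s.pos, s.strand))
    with open(path, "w") as fh:
        for s in rows:
            if s.coverage < 1:
                raise ValueError(f"site {s.chrom}:{s.pos} has coverage < 1")
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t5mC\t{s.coverage}\t{s.strand}\t"
                f"{s.methylated_count}\t{100.0 * s.frequency:.1f}\n"
            )


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a multi-record FASTA into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
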