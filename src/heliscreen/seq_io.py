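"""Amplicon read handling: quality filtering, insert extraction,
translation, and library-membership filtering.

Reads are single-end amplicons carrying a constant-flanked variable insert
that encodes the displayed peptide. A read contributes a peptide when (i)
every base of the insert is at or above the Phred threshold, (ii) both
constant anchors occur exactly once, (iii) the insert length is 3x the
design's peptide length and free of N, and (iv) the translation matches
the library design.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .design import LibraryDesignSpec
from .genetics import reverse_complement, translate

__all__ = [
    "ReadRecord",
    "ReadStats",
    "read_fastq",
    "quality_filter",
    "extract_insert",
    "match_design",
    "reads_to_peptides",
    "write_fasta",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    dna: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.dna):
            raise ValueError(f"read {self.read_id}: {len(self.quals)} quals for {len(self.dna)} bases")
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 60):
            raise ValueError(f"read {self.read_id}: Phred scores outside [0, 60]")


@dataclass
class ReadStats:
    """Per-file accounting; total == kept + dropped at every stage."""

    total: int = 0
    low_quality: int = 0
    no_insert: int = 0
    non_member: int = 0
    spike: int = 0
    matched: int = 0
    notes: list[str] = field(default_factory=list)


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (gzip-transparent) as ReadRecords."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"])
            )


def _locate_insert(read: ReadRecord, design: LibraryDesignSpec) -> tuple[int, int] | None:
    """(start, end) of the insert on the read's given strand, or None.

    Both anchors must occur exactly once and the spanned insert must have
    length 3 x peptide length.
    """
    dna = read.dna
    f5, f3 = design.flank5_dna, design.flank3_dna
    if dna.count(f5) != 1 or dna.count(f3) != 1:
        return None
    start = dna.index(f5) + len(f5)
    end = dna.index(f3)
    if end < start or end - start != 3 * design.length:
        return None
    return start, end


def _oriented(read: ReadRecord, design: LibraryDesignSpec, try_revcomp: bool) -> tuple[ReadRecord, tuple[int, int]] | None:
    span = _locate_insert(read, design)
    if span is not None:
        return read, span
    if try_revcomp:
        rc = ReadRecord(read.read_id, reverse_complement(read.dna), read.quals[::-1])
        span = _locate_insert(rc, design)
        if span is not None:
            return rc, span
    return None


def quality_filter(
    reads: Iterable[ReadRecord],
    min_phred: int = 18,
    design: LibraryDesignSpec | None = None,
    stats: ReadStats | None = None,
    try_revcomp: bool = True,
) -> Iterator[ReadRecord]:
    """Drop reads with any base below ``min_phred``.

    With a design, only the insert region is checked (reads whose insert
    cannot be located pass through here and are rejected downstream);
    without one, every base must pass. Reads are dropped whole rather than
    trimmed so that downstream counts are exact.
    """
    if min_phred < 0:
        raise ValueError("min_phred must be >= 0")
    for read in reads:
        if design is not None:
            oriented = _oriented(read, design, try_revcomp)
            if oriented is None:
                yield read
                continue
            oread, (start, end) = oriented
            ok = all(q >= min_phred for q in oread.quals[start:end])
        else:
            ok = all(q >= min_phred for q in read.quals)
        if ok:
            yield read
        elif stats is not None:
            stats.low_quality += 1


def extract_insert(
    read: ReadRecord, design: LibraryDesignSpec, try_revcomp: bool = True
) -> str | None:
    """The insert DNA strictly between the constant anchors, or None.

    Anchor matching is exact (no mismatches); inserts containing N are
    rejected.
    """
    if not design.flank5_dna or not design.flank3_dna:
        raise ValueError("design flanks must be non-empty")
    oriented = _oriented(read, design, try_revcomp)
    if oriented is None:
        return None
    oread, (start, end) = oriented
    insert = oread.dna[start:end]
    if "N" in insert:
        return None
    return insert


def match_design(peptide: str, design: LibraryDesignSpec) -> bool:
    """True iff the peptide could have come from the library design."""
    return design.matches(peptide)


def reads_to_peptides(
    path: str | Path,
    design: LibraryDesignSpec,
    min_phred: int = 18,
    spike_dna: str | None = None,
    try_revcomp: bool = True,
) -> tuple[list[str], int, ReadStats]:
    """Full per-file pipeline: FASTQ -> (member peptides, spike count, stats).

    A read whose insert equals ``spike_dna`` is tallied as spike-in and
    never contributes a peptide.
    """
    stats = ReadStats()
    peptides: list[str] = []
    spike = 0

    def _counted(src: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
        for r in src:
            stats.total += 1
            yield r

    filtered = quality_filter(
        _counted(read_fastq(path)), min_phred, design=design, stats=stats, try_revcomp=try_revcomp
    )
    for read in filtered:
        insert = extract_insert(read, design, try_revcomp=try_revcomp)
        if insert is None:
            stats.no_insert += 1
            continue
        if spike_dna is not None and insert == spike_dna:
            stats.spike += 1
            spike += 1
            continue
        peptide = translate(insert)
        if match_design(peptide, design):
            stats.matched += 1
            peptides.append(peptide)
        else:
            stats.non_member += 1
    return peptides, spike, stats


def write_fasta(peptides: Iterable[str], path: str | Path) -> None:
    """Write accepted peptides as FASTA (ids pep1, pep2, ...)."""
    with open(path, "w") as out:
        for i, pep in enumerate(peptides, start=1):
            out.write(f">pep{i}\n{pep}\n")
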