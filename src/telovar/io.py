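"""Sequence read input/output and coverage bookkeeping.

Reads are the atomic unit of every downstream count: each one carries its
base string and per-base phred scores, and — when the library is paired —
a link to its mate so that telomere-adjacent foreign sequence can be
recovered from the non-telomeric mate of a telomeric read.

FASTQ is assumed Sanger/phred+33 (the encoding emitted by the Illumina
HiSeq platforms this pipeline targets); BAM/SAM qualities are taken as
stored by pysam. Alignment coordinates are never used — only sequences,
qualities, mapping flags and mate linkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "CoverageSummary",
    "ReadParseError",
    "stream_reads",
    "stream_read_pairs",
    "write_fastq",
    "read_fasta",
    "compute_coverage",
]

_VALID_BASES = frozenset("ACGTN")
MAX_PHRED = 93


class ReadParseError(ValueError):
    """A malformed record, reported with its position in the file."""

    def __init__(self, message: str, record_index: int | None = None):
        self.record_index = record_index
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read: bases, phred scores and optional mate linkage."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    is_mapped: bool = False
    mate_id: str | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != self.qualities.size:
            raise ReadParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {self.qualities.size}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Full invariant check (alphabet and phred range); O(length)."""
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ReadParseError(f"read {self.read_id!r}: invalid bases {bad}")
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > MAX_PHRED
        ):
            raise ReadParseError(
                f"read {self.read_id!r}: phred scores outside [0, {MAX_PHRED}]"
            )


@dataclass(frozen=True)
class CoverageSummary:
    """Mean sequencing depth used to normalize telomere repeat counts."""

    total_reads: int
    read_length: int
    genome_length: int
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.total_reads > 0 and self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive when reads exist")


def compute_coverage(
    total_reads: int, read_length: int, genome_length: int
) -> CoverageSummary:
    """Mean fold-coverage = total_reads x read_length / genome_length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be a positive integer")
    if total_reads <= 0 or read_length <= 0:
        raise ValueError("total_reads and read_length must be positive")
    return CoverageSummary(
        total_reads=total_reads,
        read_length=read_length,
        genome_length=genome_length,
        mean_coverage=total_reads * read_length / genome_length,
    )


def _decode_phred33(qual: str, read_id: str) -> np.ndarray:
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if scores.size and (scores.min() < 0 or scores.max() > MAX_PHRED):
        raise ReadParseError(f"read {read_id!r}: quality characters outside phred+33")
    return scores


def encode_phred33(scores: np.ndarray) -> str:
    return (np.asarray(scores, dtype=np.uint8) + 33).tobytes().decode("ascii")


def _iter_fastq(path: Path) -> Iterator[ReadRecord]:
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ReadParseError(str(exc), record_index=index) from exc
            read_id = title.split()[0]
            if len(seq) != len(qual):
                raise ReadParseError(
                    f"sequence/quality length mismatch in {read_id!r}",
                    record_index=index,
                )
            yield ReadRecord(
                read_id=read_id,
                sequence=seq.upper(),
                qualities=_decode_phred33(qual, read_id),
            )
            index += 1


def _iter_bam(path: Path) -> Iterator[ReadRecord]:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for index, rec in enumerate(bam.fetch(until_eof=True)):
            if rec.query_sequence is None or rec.query_qualities is None:
                raise ReadParseError(
                    f"missing sequence or qualities for {rec.query_name!r}",
                    record_index=index,
                )
            name = rec.query_name
            mate_id = None
            read_id = name
            if rec.is_paired:
                suffix = "/1" if rec.is_read1 else "/2"
                other = "/2" if rec.is_read1 else "/1"
                read_id = name + suffix
                mate_id = name + other
            yield ReadRecord(
                read_id=read_id,
                sequence=rec.query_sequence.upper(),
                qualities=np.asarray(rec.query_qualities, dtype=np.int16),
                is_mapped=not rec.is_unmapped,
                mate_id=mate_id,
            )


def stream_reads(path: str | Path, format: str | None = None) -> Iterator[ReadRecord]:
    """Yield every read in a FASTQ or BAM/SAM file exactly once.

    ``format`` is ``"fastq"`` or ``"bam"``; if omitted it is inferred from
    the file suffix (``.sam`` files go through the BAM reader).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bam" if suffix in {".bam", ".sam"} else "fastq"
    if format == "fastq":
        yield from _iter_fastq(path)
    elif format == "bam":
        yield from _iter_bam(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def stream_read_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Join two FASTQ mate files record-by-record, populating mate_id."""
    it1, it2 = _iter_fastq(Path(path1)), _iter_fastq(Path(path2))
    for index, (r1, r2) in enumerate(zip(it1, it2)):
        base1, base2 = _strip_mate_suffix(r1.read_id), _strip_mate_suffix(r2.read_id)
        if base1 != base2:
            raise ReadParseError(
                f"mate files out of sync: {r1.read_id!r} vs {r2.read_id!r}",
                record_index=index,
            )
        if not r1.read_id.endswith("/1"):
            r1.read_id = base1 + "/1"
        if not r2.read_id.endswith("/2"):
            r2.read_id = base2 + "/2"
        r1.mate_id, r2.mate_id = r2.read_id, r1.read_id
        yield r1, r2
    if next(it1, None) is not None or next(it2, None) is not None:
        raise ReadParseError("mate files have unequal record counts")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as 4-line phred+33 FASTQ; returns the record count."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            out.write(
                f"@{read.read_id}\n{read.sequence}\n+\n"
                f"{encode_phred33(read.qualities)}\n"
            )
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA target library as {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
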