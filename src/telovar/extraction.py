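"""Telomere read extraction under configurable repeat-motif criteria.

A read is called telomeric when it contains at least ``min_count``
non-overlapping occurrences of a degenerate hexamer motif (TNAGGG by
default, N matching any base), either anywhere in the read
(non-consecutive) or as a tandem in-frame run (consecutive). The
canonical analysis criterion is 6x non-consecutive TNAGGG; telomere
*content* estimation uses 4x consecutive TTAGGG. Both strands are
examined by default, since roughly half of all telomeric fragments
sequence from the C strand (CCCTAA).

Note that TNAGGG selection favours position-2 variant repeats
(TCAGGG/TGAGGG/TAAGGG all match the motif) and can under-represent
position-1 and position-3 variants in the extracted subset; reports that
use this criterion log that caveat rather than correcting for it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from .io import ReadRecord

__all__ = [
    "ExtractionCriterion",
    "ExtractionTally",
    "PRESETS",
    "reverse_complement",
    "motif_occurrences",
    "matches_criterion",
    "sequence_matches",
    "extract_telomeric",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EXTRACTION_BIAS_WARNING = (
    "TNAGGG extraction favours position-2 variant repeats and may "
    "under-represent position-1 and position-3 variants"
)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExtractionCriterion:
    """A degenerate hexamer, a minimum occurrence count, and a run flag."""

    motif: str = "TNAGGG"
    min_count: int = 6
    consecutive: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) != 6:
            raise ValueError(f"motif must be a hexamer, got {self.motif!r}")
        if not set(self.motif) <= set("ACGTN"):
            raise ValueError(f"motif alphabet is ACGTN, got {self.motif!r}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    @property
    def name(self) -> str:
        mode = "consecutive" if self.consecutive else "non-consecutive"
        return f"{self.min_count}x {mode} {self.motif}"


#: Named criteria: the standard variant-analysis criterion and the
#: telomere-content criterion.
PRESETS: dict[str, ExtractionCriterion] = {
    "survey6": ExtractionCriterion("TNAGGG", 6, consecutive=False),
    "content4": ExtractionCriterion("TTAGGG", 4, consecutive=True),
}


def _motif_pattern(motif: str) -> re.Pattern[str]:
    # N in the motif matches any real base, never an N in the read.
    return re.compile(motif.replace("N", "[ACGT]"))


def motif_occurrences(sequence: str, motif: str) -> list[int]:
    """0-based start offsets of non-overlapping matches, greedy left-to-right."""
    return [m.start() for m in _motif_pattern(motif).finditer(sequence)]


def _has_consecutive_run(offsets: list[int], k: int, unit_len: int = 6) -> bool:
    run = 1
    for prev, cur in zip(offsets, offsets[1:]):
        run = run + 1 if cur - prev == unit_len else 1
        if run >= k:
            return True
    return k <= 1 and bool(offsets)


def sequence_matches(sequence: str, criterion: ExtractionCriterion) -> bool:
    offsets = motif_occurrences(sequence, criterion.motif)
    if criterion.consecutive:
        return _has_consecutive_run(offsets, criterion.min_count)
    return len(offsets) >= criterion.min_count


def matches_criterion(
    read: ReadRecord, criterion: ExtractionCriterion, both_strands: bool = True
) -> bool:
    """Telomeric test for one read, optionally on either strand."""
    if sequence_matches(read.sequence, criterion):
        return True
    if both_strands:
        return sequence_matches(reverse_complement(read.sequence), criterion)
    return False


@dataclass(frozen=True)
class ExtractionTally:
    criterion: str
    total_reads: int
    telomeric_reads: int

    def normalized(self, mean_coverage: float) -> float:
        return self.telomeric_reads / mean_coverage


def extract_telomeric(
    reads: Iterable[ReadRecord],
    criterion: ExtractionCriterion,
    both_strands: bool = True,
) -> tuple[list[ReadRecord], ExtractionTally]:
    """Filter a read stream down to the telomeric subset, order preserved."""
    if criterion.motif == "TNAGGG":
        logger.warning(EXTRACTION_BIAS_WARNING)
    telomeric: list[ReadRecord] = []
    total = 0
    for read in reads:
        total += 1
        if matches_criterion(read, criterion, both_strands=both_strands):
            telomeric.append(read)
    tally = ExtractionTally(
        criterion=criterion.name, total_reads=total, telomeric_reads=len(telomeric)
    )
    return telomeric, tally
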