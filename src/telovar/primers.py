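"""Audit of amplification-competent qPCR primer sites in telomere reads.

The 2009 multiplexed telomere qPCR design relies on a deliberate 3'
mismatch in its reverse primer so that only forward-primer extension
products amplify. Variant repeats can restore a perfect match: any
telomeric stretch fitting TGTTAGGG(NTAGGG)4NTA (35 nt, N = any base) is
an amplification-competent reverse-primer site, and telomeres rich in
NTAGGG-compatible variants (notably GTAGGG) present more such sites —
inflating qPCR telomere-content estimates relative to sequence-based or
hybridization-based measures. This module counts those sites, for the
default pattern or any user-supplied degenerate pattern, so alternative
primer designs can be audited the same way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .extraction import reverse_complement
from .io import ReadRecord
from .repeats import orient_g_strand

__all__ = [
    "PrimerSiteCount",
    "DEFAULT_PRIMER_PATTERN",
    "expand_degenerate_pattern",
    "count_primer_sites",
]

#: Reverse-primer site of the 2009 multiplexed telomere qPCR assay:
#: TGTTAGGG followed by four NTAGGG units and NTA (8 + 4*6 + 3 = 35 nt).
DEFAULT_PRIMER_PATTERN = "TGTTAGGG(NTAGGG){4}NTA"

_REPEAT_GROUP = re.compile(r"\(([ACGTN]+)\)\{(\d+)\}")


def expand_degenerate_pattern(pattern: str) -> str:
    """Expand (X){n} repetition groups to a flat degenerate string."""
    flat = _REPEAT_GROUP.sub(lambda m: m.group(1) * int(m.group(2)), pattern)
    if not set(flat) <= set("ACGTN"):
        raise ValueError(f"pattern alphabet is ACGTN with (X){{n}} groups: {pattern!r}")
    return flat


def _compile(pattern: str) -> tuple[re.Pattern[str], int]:
    flat = expand_degenerate_pattern(pattern)
    return re.compile(flat.replace("N", "[ACGT]")), len(flat)


@dataclass(frozen=True)
class PrimerSiteCount:
    """Non-overlapping pattern-site counts over a telomeric read set."""

    pattern_name: str
    pattern_length: int
    sites_per_read: dict[str, int]
    total_sites: int
    n_reads: int

    def normalized(self, mean_coverage: float) -> float:
        return self.total_sites / mean_coverage


def count_primer_sites(
    reads: Iterable[ReadRecord],
    pattern: str = DEFAULT_PRIMER_PATTERN,
    orient: bool = True,
    both_strands: bool = False,
) -> PrimerSiteCount:
    """Count non-overlapping primer-site matches per G-strand-oriented read.

    The reverse primer anneals to the G-strand template, so scanning the
    oriented G strand is the default; ``both_strands`` adds the
    complement scan for unoriented audits.
    """
    regex, length = _compile(pattern)
    per_read: dict[str, int] = {}
    n_reads = 0
    for read in reads:
        n_reads += 1
        seq = orient_g_strand(read).sequence if orient else read.sequence
        count = len(regex.findall(seq))
        if both_strands:
            count += len(regex.findall(reverse_complement(seq)))
        per_read[read.read_id] = count
    return PrimerSiteCount(
        pattern_name=pattern,
        pattern_length=length,
        sites_per_read=per_read,
        total_sites=sum(per_read.values()),
        n_reads=n_reads,
    )
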