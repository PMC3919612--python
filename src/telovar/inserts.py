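"""Paired-end detection of foreign sequence interspersed in telomeres.

Cell lines carrying telomere-integrated foreign DNA (SV40 viral genomes,
selection-marker tags) yield read pairs in which one mate sits in the
repeat array and the other in the insert. Scanning the non-telomeric
mate of each such pair against a small FASTA library of candidate
targets therefore reveals telomere-embedded sequence without any genome
alignment.

Matching is exact-seed (default 20 nt) followed by greedy ungapped
extension tolerating isolated mismatches; targets are planted verbatim
in the biological cases of interest, so full local alignment adds
nothing at this scale.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .extraction import reverse_complement
from .io import ReadRecord

__all__ = ["InsertHit", "detect_telomere_inserts", "scan_read_for_targets"]

logger = logging.getLogger(__name__)

_MAX_MISMATCH_STREAK = 4


@dataclass(frozen=True)
class InsertHit:
    """One non-telomeric mate matching a candidate insert target."""

    telomeric_read_id: str
    mate_read_id: str
    target_name: str
    match_length: int
    match_identity: float
    strand: str


def _build_seed_index(
    targets: Mapping[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for name, seq in targets.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((name, i))
    return index


def _extend_one_way(read: str, target: str, r0: int, t0: int, step: int) -> tuple[int, int]:
    """Greedy ungapped extension in one direction from just outside a seed.

    Walks until a mismatch streak, then trims back to the last matching
    base; returns (span, matches) over the retained span.
    """
    span = matches = 0
    best_span = best_matches = 0
    streak = 0
    i, j = r0, t0
    while 0 <= i < len(read) and 0 <= j < len(target) and streak < _MAX_MISMATCH_STREAK:
        span += 1
        if read[i] == target[j]:
            matches += 1
            streak = 0
            best_span, best_matches = span, matches
        else:
            streak += 1
        i += step
        j += step
    return best_span, best_matches


def _extend(read: str, target: str, r0: int, t0: int, k: int) -> tuple[int, float]:
    """Extend an exact k-mer seed both ways; returns (length, identity)."""
    right_span, right_matches = _extend_one_way(read, target, r0 + k, t0 + k, +1)
    left_span, left_matches = _extend_one_way(read, target, r0 - 1, t0 - 1, -1)
    length = k + right_span + left_span
    identity = (k + right_matches + left_matches) / length
    return length, identity


def scan_read_for_targets(
    sequence: str,
    index: Mapping[str, list[tuple[str, int]]],
    targets: Mapping[str, str],
    min_seed: int,
    min_identity: float,
) -> tuple[str, int, float, str] | None:
    """Best (target, length, identity, strand) hit for one read, or None."""
    best: tuple[str, int, float, str] | None = None
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        i = 0
        while i <= len(seq) - min_seed:
            hits = index.get(seq[i : i + min_seed])
            if hits:
                name, pos = hits[0]
                length, identity = _extend(seq, targets[name], i, pos, min_seed)
                if identity >= min_identity and (best is None or length > best[1]):
                    best = (name, length, identity, strand)
                i += max(length - min_seed, 1)
            else:
                i += 1
    return best


def detect_telomere_inserts(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    telomeric_ids: set[str],
    targets: Mapping[str, str],
    min_seed: int = 20,
    min_identity: float = 0.9,
) -> list[InsertHit]:
    """Scan the non-telomeric mates of half-telomeric pairs for targets.

    Pairs with both mates telomeric (fully inside the repeat array) or
    neither telomeric are skipped; unmated telomeric reads are logged by
    the caller, not an error here.
    """
    if not targets:
        raise ValueError("target library is empty")
    index = _build_seed_index(targets, min_seed)
    hits: list[InsertHit] = []
    for r1, r2 in pairs:
        tel1, tel2 = r1.read_id in telomeric_ids, r2.read_id in telomeric_ids
        if tel1 == tel2:
            continue
        telomeric, mate = (r1, r2) if tel1 else (r2, r1)
        found = scan_read_for_targets(
            mate.sequence, index, targets, min_seed, min_identity
        )
        if found is not None:
            name, length, identity, strand = found
            hits.append(
                InsertHit(
                    telomeric_read_id=telomeric.read_id,
                    mate_read_id=mate.read_id,
                    target_name=name,
                    match_length=length,
                    match_identity=identity,
                    strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.telomeric_read_id, h.target_name))
    return hits
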