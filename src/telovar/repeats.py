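"""Repeat-unit tokenization, classification and per-sample profiling.

Extracted telomeric reads are oriented to the G strand and cut into
repeat units by a greedy, GGG-anchored left-to-right scan:

* the 7-mer TTAAGGG is recognised first (the one naturally occurring
  7-mer variant);
* any hexamer whose positions 4-6 are GGG is emitted as a unit — this
  covers the canonical TTAGGG and every variant confined to positions
  1-3, reflecting the near-invariance of the GGG motif in real
  telomeres;
* hexamers with an intact TTA head but an altered tail (TTANNN) are
  emitted so position-4-6 variants are representable;
* everything else advances one base and accrues to ``other_bases``
  (read-end fragments, degenerate or subtelomeric sequence).

Each unit receives exactly one label. Single-mismatch variants are
grouped by the altered position (pos1: GTAGGG/ATAGGG/CTAGGG; pos2:
TCAGGG/TGAGGG/TAAGGG; pos3: TTCGGG/TTGGGG/TTTGGG); GCAGGG, a double
mismatch diagnostic of mutant-template telomerase, is tracked by name.
Profiles accumulate class counts, named-variant counts, the 4x6
position-nucleotide matrix, and counts normalized to genome coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import motif_occurrences, reverse_complement
from .io import CoverageSummary, ReadRecord

__all__ = [
    "RepeatUnit",
    "RepeatProfile",
    "CANONICAL",
    "NAMED_VARIANTS",
    "POSITION_CLASSES",
    "classify_unit",
    "tokenize_read",
    "orient_g_strand",
    "position_matrix",
    "build_profile",
]

CANONICAL = "TTAGGG"
SEVENMER = "TTAAGGG"

#: Variant repeats reported by name, grouped by altered hexamer position.
POSITION_CLASSES: dict[str, tuple[str, ...]] = {
    "pos1_variant": ("GTAGGG", "ATAGGG", "CTAGGG"),
    "pos2_variant": ("TCAGGG", "TGAGGG", "TAAGGG"),
    "pos3_variant": ("TTCGGG", "TTGGGG", "TTTGGG"),
}

NAMED_VARIANTS: tuple[str, ...] = (
    "TCAGGG",
    "TGAGGG",
    "TAAGGG",
    "GTAGGG",
    "ATAGGG",
    "CTAGGG",
    "TTCGGG",
    "TTGGGG",
    "TTTGGG",
    "TTAAGGG",
    "GCAGGG",
)

LABELS: tuple[str, ...] = (
    "canonical",
    "pos1_variant",
    "pos2_variant",
    "pos3_variant",
    "pos456_variant",
    "sevenmer_TTAAGGG",
    "other",
)

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_ORDER = "ACGT"


@dataclass(slots=True)
class RepeatUnit:
    """One tokenized repeat unit within a G-strand-oriented read."""

    unit_seq: str
    offset: int
    mean_quality: float
    label: str
    variant_key: str | None = None


def classify_unit(unit_seq: str) -> tuple[str, str | None]:
    """Label a 6- or 7-nt unit; total and deterministic.

    Returns ``(label, variant_key)`` where ``variant_key`` is the unit
    sequence for named single-position variants, the 7-mer, and the
    GCAGGG double variant, else ``None``.
    """
    n = len(unit_seq)
    if n == 7:
        if unit_seq == SEVENMER:
            return "sevenmer_TTAAGGG", SEVENMER
        return "other", None
    if n != 6:
        raise ValueError(f"repeat unit must be 6 or 7 nt, got {unit_seq!r}")
    if unit_seq == CANONICAL:
        return "canonical", None
    if "N" in unit_seq:
        return "other", None
    mismatches = [i for i in range(6) if unit_seq[i] != CANONICAL[i]]
    if len(mismatches) == 1:
        pos = mismatches[0]
        if pos <= 2:
            return f"pos{pos + 1}_variant", unit_seq
        return "pos456_variant", unit_seq
    if unit_seq == "GCAGGG":
        # double mismatch (positions 1+2) but diagnostic, tracked by name
        return "other", "GCAGGG"
    return "other", None


def tokenize_read(
    sequence: str, qualities: np.ndarray | None = None
) -> tuple[list[RepeatUnit], int]:
    """Greedy GGG-anchored segmentation of a G-strand sequence.

    Returns the unit list plus the count of bases assigned to no unit.
    """
    units: list[RepeatUnit] = []
    other_bases = 0
    i = 0
    n = len(sequence)
    while i + 6 <= n:
        if i + 7 <= n and sequence.startswith(SEVENMER, i):
            width = 7
        else:
            window = sequence[i : i + 6]
            if window.endswith("GGG") and "N" not in window:
                width = 6
            elif window.startswith("TTA") and "N" not in window:
                width = 6
            else:
                other_bases += 1
                i += 1
                continue
        unit_seq = sequence[i : i + width]
        mean_q = float(np.mean(qualities[i : i + width])) if qualities is not None else float("nan")
        label, key = classify_unit(unit_seq)
        units.append(RepeatUnit(unit_seq, i, mean_q, label, key))
        i += width
    other_bases += n - i
    return units, other_bases


def orient_g_strand(read: ReadRecord, motif: str = "TNAGGG") -> ReadRecord:
    """Return the read oriented so the G-rich strand is read out.

    The orientation with more non-overlapping motif hits wins; ties keep
    the original. Qualities are reversed in step with the sequence.
    """
    forward = len(motif_occurrences(read.sequence, motif))
    rc = reverse_complement(read.sequence)
    reverse = len(motif_occurrences(rc, motif))
    if reverse > forward:
        return ReadRecord(
            read_id=read.read_id,
            sequence=rc,
            qualities=read.qualities[::-1].copy(),
            is_mapped=read.is_mapped,
            mate_id=read.mate_id,
        )
    return read


def position_matrix(units: list[RepeatUnit]) -> np.ndarray:
    """4x6 count of each nucleotide at each hexamer position (rows ACGT)."""
    matrix = np.zeros((4, 6), dtype=np.int64)
    for unit in units:
        if len(unit.unit_seq) != 6:
            raise ValueError("position_matrix takes hexamer units only")
        for pos, base in enumerate(unit.unit_seq):
            if base in _BASE_ROW:
                matrix[_BASE_ROW[base], pos] += 1
    return matrix


@dataclass
class RepeatProfile:
    """Per-sample repeat tallies with coverage-normalized counts."""

    class_counts: Counter = field(default_factory=Counter)
    variant_counts: Counter = field(default_factory=Counter)
    position_matrix: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 6), dtype=np.int64)
    )
    other_bases: int = 0
    n_hexamer_units: int = 0
    n_sevenmer_units: int = 0
    n_reads: int = 0
    total_bases: int = 0
    quality_excluded: int = 0
    mean_coverage: float = 1.0
    unit_mean_qualities: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float32)
    )

    @property
    def total_units(self) -> int:
        return self.n_hexamer_units + self.n_sevenmer_units

    def count(self, key: str) -> int:
        """Raw count for a class label, position class or named variant."""
        if key in LABELS:
            return self.class_counts[key]
        if key in ("pos1", "pos2", "pos3"):
            return self.class_counts[f"{key}_variant"]
        return self.variant_counts[key]

    def normalized(self, key: str) -> float:
        return self.count(key) / self.mean_coverage

    def proportion(self, key: str) -> float:
        return self.count(key) / self.total_units if self.total_units else 0.0

    @property
    def total_variant_units(self) -> int:
        return self.total_units - self.class_counts["canonical"]

    @property
    def variant_to_canonical_ratio(self) -> float:
        canonical = self.class_counts["canonical"]
        return self.total_variant_units / canonical if canonical else float("inf")

    def class_table(self) -> pd.DataFrame:
        """Tidy table of class and named-variant counts (raw, normalized, %)."""
        rows = []
        for label in LABELS:
            rows.append(("class", label, self.class_counts[label]))
        for variant in NAMED_VARIANTS:
            rows.append(("variant", variant, self.variant_counts[variant]))
        frame = pd.DataFrame(rows, columns=["kind", "key", "count"])
        frame["normalized"] = frame["count"] / self.mean_coverage
        total = self.total_units or 1
        frame["percentage"] = 100.0 * frame["count"] / total
        return frame

    def position_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.position_matrix,
            index=list(BASE_ORDER),
            columns=[f"pos{i}" for i in range(1, 7)],
        )


def build_profile(
    reads: list[ReadRecord],
    coverage: CoverageSummary | float,
    min_unit_quality: float | None = None,
    orient: bool = True,
) -> RepeatProfile:
    """Aggregate tokenized repeat units over a set of telomeric reads.

    Quality filtering is off by default: the full unit distribution is
    reported and the per-unit quality histogram retained so accuracy can
    be assessed rather than silently enforced. When ``min_unit_quality``
    is set, units below it are excluded from the class counts and tallied
    under ``quality_excluded``.
    """
    mean_coverage = (
        coverage.mean_coverage if isinstance(coverage, CoverageSummary) else float(coverage)
    )
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    profile = RepeatProfile(mean_coverage=mean_coverage)
    qualities: list[float] = []
    for read in reads:
        if orient:
            read = orient_g_strand(read)
        units, other = tokenize_read(read.sequence, read.qualities)
        profile.n_reads += 1
        profile.total_bases += read.length
        profile.other_bases += other
        for unit in units:
            qualities.append(unit.mean_quality)
            if (
                min_unit_quality is not None
                and np.isfinite(unit.mean_quality)
                and unit.mean_quality < min_unit_quality
            ):
                profile.quality_excluded += 1
                continue
            profile.class_counts[unit.label] += 1
            if unit.variant_key is not None:
                profile.variant_counts[unit.variant_key] += 1
            if len(unit.unit_seq) == 6:
                profile.n_hexamer_units += 1
                for pos, base in enumerate(unit.unit_seq):
                    if base in _BASE_ROW:
                        profile.position_matrix[_BASE_ROW[base], pos] += 1
            else:
                profile.n_sevenmer_units += 1
    profile.unit_mean_qualities = np.asarray(qualities, dtype=np.float32)
    return profile
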