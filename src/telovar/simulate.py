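"""Synthetic telomere architectures and error-injected sequencing reads.

Three telomere-maintenance architectures are emulated, each producing
unit-labelled repeat arrays with ground truth retained:

* **mortal** — a variant-rich proximal block (TCAGGG/TGAGGG/TTGGGG, the
  repeats documented in proximal human telomeres) followed by a distal
  region of canonical repeats interrupted by short GTAGGG clusters (the
  distally located variant, found in blocks among canonical repeats).
* **telomerase** — a mortal array extended distally by a processive
  polymerase that misincorporates at hexamer positions 1 and 3 (never
  position 2) at small per-unit rates, producing the position-biased
  variant signature of telomerase-extended telomeres.
* **alt** — recombination-mediated growth: the array first erodes to a
  crisis length (proximal block intact), then grows by repeatedly
  copying windows of its own units — proximal variant blocks and any
  integrated foreign sequence included — into random positions. Variant
  content spreads stochastically, amplifying different variants in
  different clones while leaving the overall variant:canonical balance
  near the mortal baseline.

Reads are 100 nt by default, sampled from either strand of the arrays
or from a decoy genome in proportion to telomere content, optionally
paired at a fixed fragment size, with per-base miscalls and phred
scores from a rounded-Gaussian quality model. Every source of
randomness flows from the spec's seed, so identical specs reproduce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CoverageSummary, ReadRecord, compute_coverage

__all__ = [
    "SyntheticTelomereSpec",
    "TelomereArray",
    "SyntheticSample",
    "simulate_telomere",
    "sample_reads",
    "inject_errors",
    "simulate_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALT_BASE = {  # the three possible miscalls per true base
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}
_CANONICAL = "TTAGGG"


@dataclass
class SyntheticTelomereSpec:
    """Generative parameters for one simulated sample.

    Length parameters are in repeat *units* (6 nt each); rates are
    per-unit or per-base probabilities as noted.
    """

    mode: str = "mortal"  # mortal | telomerase | alt
    name: str = "sim"
    n_telomeres: int = 8
    # proximal block: ordered variant-rich region at the subtelomeric end
    proximal_units: int = 50
    proximal_composition: dict[str, float] = field(
        default_factory=lambda: {"TCAGGG": 0.25, "TGAGGG": 0.20, "TTGGGG": 0.10}
    )
    # distal region (mortal core): canonical with sparse GTAGGG clusters
    distal_length_units: tuple[float, float] = (400.0, 60.0)  # mean, sd
    distal_cluster_rate: float = 0.015  # per-unit probability a GTAGGG block starts
    distal_cluster_len: tuple[int, int] = (2, 4)  # inclusive block-length range
    distal_cluster_variant: str = "GTAGGG"
    # telomerase mode: extension with position-biased misincorporation
    extension_units: int = 600
    misincorporation_rates: dict[int, float] = field(
        default_factory=lambda: {1: 0.005, 3: 0.003}
    )
    # alt mode: erosion to crisis then window-copy growth
    alt_crisis_distal_units: int = 320
    alt_template_window: int = 10
    alt_target_units: int = 1600
    # optional iid composition override (parameter-recovery experiments)
    unit_composition: dict[str, float] | None = None
    # foreign insert
    insert_seq: str | None = None
    insert_prob: float = 0.0  # per-telomere probability of carrying the insert
    # read geometry and error model
    n_reads: int = 4000
    read_length: int = 100
    paired: bool = False
    fragment_size: int = 350
    genome_length: int = 1_000_000
    error_rate: float = 0.001  # per-base miscall probability
    quality_mean: float = 34.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"mortal", "telomerase", "alt"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.read_length < 36:
            raise ValueError("read_length must be >= 36")
        probs = [self.error_rate, self.insert_prob, *self.proximal_composition.values()]
        if self.unit_composition:
            probs += list(self.unit_composition.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TelomereArray:
    """One simulated repeat array: ordered (label, sequence) elements.

    ``label`` is the repeat unit itself for repeat elements and
    ``"insert"`` for foreign sequence.
    """

    index: int
    elements: list[tuple[str, str]]

    def sequence(self) -> str:
        return "".join(seq for _, seq in self.elements)

    @property
    def n_units(self) -> int:
        return sum(1 for label, _ in self.elements if label != "insert")

    def unit_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label, _ in self.elements:
            if label != "insert":
                counts[label] = counts.get(label, 0) + 1
        return counts

    @property
    def has_insert(self) -> bool:
        return any(label == "insert" for label, _ in self.elements)


def _draw_units(rng: np.random.Generator, n: int, composition: dict[str, float]) -> list[str]:
    """n iid units from {variant: prob}; remaining mass is canonical."""
    variants = list(composition)
    probs = [composition[v] for v in variants]
    rest = 1.0 - sum(probs)
    if rest < -1e-9:
        raise ValueError("composition probabilities exceed 1")
    choices = rng.choice(len(variants) + 1, size=n, p=probs + [max(rest, 0.0)])
    return [variants[c] if c < len(variants) else _CANONICAL for c in choices]


def _mortal_core(
    spec: SyntheticTelomereSpec, rng: np.random.Generator, distal_units: int
) -> list[str]:
    units = _draw_units(rng, spec.proximal_units, spec.proximal_composition)
    lo, hi = spec.distal_cluster_len
    i = 0
    while i < distal_units:
        if rng.random() < spec.distal_cluster_rate:
            block = int(rng.integers(lo, hi + 1))
            take = min(block, distal_units - i)
            units.extend([spec.distal_cluster_variant] * take)
            i += take
        else:
            units.append(_CANONICAL)
            i += 1
    return units


def _misincorporate(unit: str, rng: np.random.Generator, rates: dict[int, float]) -> str:
    for pos, rate in rates.items():
        if rate > 0 and rng.random() < rate:
            true_base = unit[pos - 1]
            wrong = _ALT_BASE[true_base][rng.integers(0, 3)]
            unit = unit[: pos - 1] + wrong + unit[pos:]
    return unit


def simulate_telomere(
    spec: SyntheticTelomereSpec,
    telomere_index: int,
    rng: np.random.Generator | None = None,
) -> TelomereArray:
    """Build one unit-labelled repeat array under the spec's architecture."""
    if rng is None:
        rng = np.random.default_rng((spec.seed, telomere_index))

    if spec.unit_composition is not None:
        n = max(1, round(rng.normal(*spec.distal_length_units)))
        units = _draw_units(rng, n, spec.unit_composition)
        return TelomereArray(telomere_index, [(u, u) for u in units])

    if spec.mode == "alt":
        distal = spec.alt_crisis_distal_units
    else:
        distal = max(spec.proximal_units, round(rng.normal(*spec.distal_length_units)))
    units = _mortal_core(spec, rng, distal)
    elements: list[tuple[str, str]] = [(u, u) for u in units]

    if spec.insert_seq and rng.random() < spec.insert_prob:
        at = int(rng.integers(spec.proximal_units, len(elements) + 1))
        elements.insert(at, ("insert", spec.insert_seq))

    if spec.mode == "telomerase":
        for _ in range(spec.extension_units):
            unit = _misincorporate(_CANONICAL, rng, spec.misincorporation_rates)
            elements.append((unit, unit))
    elif spec.mode == "alt":
        window = spec.alt_template_window
        array = TelomereArray(telomere_index, elements)
        while array.n_units < spec.alt_target_units:
            donor = int(rng.integers(0, max(len(elements) - window, 0) + 1))
            copied = elements[donor : donor + window]
            at = int(rng.integers(0, len(elements) + 1))
            elements[at:at] = copied
    return TelomereArray(telomere_index, elements)


def inject_errors(
    read: ReadRecord,
    spec: SyntheticTelomereSpec,
    rng: np.random.Generator,
) -> tuple[ReadRecord, list[int]]:
    """Independently miscall each base with the spec's error rate.

    A miscall replaces the base with one of the three alternatives,
    uniformly. Returns the (possibly modified) read and the 0-based
    positions of injected errors.
    """
    if spec.error_rate <= 0:
        return read, []
    hits = np.flatnonzero(rng.random(read.length) < spec.error_rate)
    if hits.size == 0:
        return read, []
    seq = list(read.sequence)
    for pos in hits:
        true_base = seq[pos]
        if true_base in _ALT_BASE:
            seq[pos] = _ALT_BASE[true_base][rng.integers(0, 3)]
    return (
        ReadRecord(
            read_id=read.read_id,
            sequence="".join(seq),
            qualities=read.qualities,
            is_mapped=read.is_mapped,
            mate_id=read.mate_id,
        ),
        hits.tolist(),
    )


def _draw_qualities(
    spec: SyntheticTelomereSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    q = np.rint(rng.normal(spec.quality_mean, spec.quality_sd, size=n))
    return np.clip(q, 2, 40).astype(np.int16)


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def sample_reads(
    arrays: list[TelomereArray],
    spec: SyntheticTelomereSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw error-injected reads from the arrays plus decoy genome.

    Each read (or fragment, in paired mode) is telomeric with
    probability total-telomere-bases / genome_length and otherwise
    comes from a fixed random decoy sequence, so telomeric read counts
    scale with telomere content exactly as in whole-genome sequencing.
    The truth table records source, coordinates, strand, telomere
    status and injected-error count per read.
    """
    if not arrays:
        raise ValueError("no telomere arrays supplied")
    if rng is None:
        rng = np.random.default_rng((spec.seed, 10_000))
    span = spec.fragment_size if spec.paired else spec.read_length
    seqs = [a.sequence() for a in arrays]
    eligible = [i for i, s in enumerate(seqs) if len(s) >= span]
    if not eligible:
        raise ValueError(f"no array can accommodate a {span}-nt fragment")
    skipped = len(seqs) - len(eligible)
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "%d arrays shorter than the %d-nt fragment span were excluded", skipped, span
        )
    tel_bases = sum(len(seqs[i]) for i in eligible)
    p_tel = min(1.0, tel_bases / spec.genome_length)
    lengths = np.array([len(seqs[i]) for i in eligible], dtype=float)
    source_p = lengths / lengths.sum()

    decoy_len = max(spec.fragment_size * 4, 20_000)
    decoy = _BASES[rng.integers(0, 4, size=decoy_len)].tobytes().decode("ascii")

    reads: list[ReadRecord] = []
    rows: list[tuple] = []

    for i in range(spec.n_reads):
        telomeric = rng.random() < p_tel
        if telomeric:
            src = eligible[int(rng.choice(len(eligible), p=source_p))]
            template = seqs[src]
        else:
            src, template = -1, decoy
        start = int(rng.integers(0, len(template) - span + 1))
        fragment = template[start : start + span]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = _reverse_complement(fragment)

        base_id = f"{spec.name}_{i:06d}"
        if spec.paired:
            mates = [
                (base_id + "/1", fragment[: spec.read_length], base_id + "/2"),
                (
                    base_id + "/2",
                    _reverse_complement(fragment)[: spec.read_length],
                    base_id + "/1",
                ),
            ]
        else:
            mates = [(base_id, fragment, None)]
        for read_id, seq, mate_id in mates:
            read = ReadRecord(
                read_id=read_id,
                sequence=seq,
                qualities=_draw_qualities(spec, rng, len(seq)),
                mate_id=mate_id,
            )
            read, errors = inject_errors(read, spec, rng)
            reads.append(read)
            rows.append((read_id, telomeric, src, start, strand, len(errors)))

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "is_telomeric", "array_index", "fragment_start", "strand", "n_errors"],
    )
    return reads, truth


@dataclass
class SyntheticSample:
    """A simulated sample: arrays, reads, truth table and coverage."""

    spec: SyntheticTelomereSpec
    arrays: list[TelomereArray]
    reads: list[ReadRecord]
    truth: pd.DataFrame
    coverage: CoverageSummary

    def truth_unit_counts(self) -> dict[str, int]:
        """Ground-truth repeat-unit counts summed over all arrays."""
        totals: dict[str, int] = {}
        for array in self.arrays:
            for unit, n in array.unit_counts().items():
                totals[unit] = totals.get(unit, 0) + n
        return totals


def simulate_sample(spec: SyntheticTelomereSpec) -> SyntheticSample:
    """Arrays + reads + truth for one sample, fully seed-determined."""
    rng = spec.rng()
    arrays = [simulate_telomere(spec, i, rng) for i in range(spec.n_telomeres)]
    reads, truth = sample_reads(arrays, spec, rng)
    total_reads = spec.n_reads * (2 if spec.paired else 1)
    coverage = compute_coverage(total_reads, spec.read_length, spec.genome_length)
    return SyntheticSample(spec=spec, arrays=arrays, reads=reads, truth=truth, coverage=coverage)


def write_sample(sample: SyntheticSample, outdir) -> dict[str, str]:
    """Write FASTQ (+ mate file when paired), truth TSV and spec YAML."""
    import yaml
    from pathlib import Path

    from .io import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    name = sample.spec.name
    if sample.spec.paired:
        r1 = [r for r in sample.reads if r.read_id.endswith("/1")]
        r2 = [r for r in sample.reads if r.read_id.endswith("/2")]
        paths["fastq_1"] = str(outdir / f"{name}_1.fastq")
        paths["fastq_2"] = str(outdir / f"{name}_2.fastq")
        write_fastq(r1, paths["fastq_1"])
        write_fastq(r2, paths["fastq_2"])
    else:
        paths["fastq"] = str(outdir / f"{name}.fastq")
        write_fastq(sample.reads, paths["fastq"])
    paths["truth"] = str(outdir / f"{name}_truth.tsv")
    sample.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = str(outdir / f"{name}_spec.yaml")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(sample.spec.to_dict(), fh, sort_keys=False)
    return paths
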