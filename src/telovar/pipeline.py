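"""Pipeline orchestration: extract -> orient -> profile -> stats -> audits.

Single entry point used by the command line and the analysis drivers.
Every stage writes its own TSV (single header line, stable column
order), a summary table ties read counts to the active criterion, and a
MANIFEST records completion so partial output is never mistaken for a
finished run. All randomness and parameters are logged; reruns of the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import extraction, inserts, primers, stats
from .extraction import ExtractionCriterion, PRESETS
from .io import (
    CoverageSummary,
    compute_coverage,
    read_fasta,
    stream_read_pairs,
    stream_reads,
)
from .repeats import RepeatProfile, build_profile

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_samples"]

logger = logging.getLogger(__name__)

#: Variant keys reported by default in excess tests: position classes
#: first (the headline comparison), then each named variant.
DEFAULT_TEST_KEYS: tuple[str, ...] = ("pos1", "pos2", "pos3") + tuple(
    v for v in stats.NAMED_VARIANTS if v != "TTAAGGG"
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    reads: str
    reads_mate: str | None = None
    format: str | None = None  # fastq | bam; inferred from suffix when None
    sample_name: str = "sample"
    # extraction criterion
    motif: str = "TNAGGG"
    min_count: int = 6
    consecutive: bool = False
    both_strands: bool = True
    preset: str | None = None
    # normalization
    genome_length: int = 3_000_000_000
    coverage: float | None = None  # overrides computation when given
    # statistics
    q_assumed: float = 30.0
    substitution_model: str = "specific"
    excluded_variants: list[str] = field(default_factory=list)
    baseline_reads: str | None = None
    # audits
    targets_fasta: str | None = None
    min_seed: int = 20
    min_identity: float = 0.9
    primer_pattern: str = primers.DEFAULT_PRIMER_PATTERN
    # output
    outdir: str = "telovar_out"
    seed: int = 0
    log_level: str = "INFO"
    plots: bool = False

    def criterion(self) -> ExtractionCriterion:
        if self.preset:
            return PRESETS[self.preset]
        return ExtractionCriterion(self.motif, self.min_count, self.consecutive)

    def validate(self) -> None:
        for label, path in [
            ("reads", self.reads),
            ("reads_mate", self.reads_mate),
            ("baseline_reads", self.baseline_reads),
            ("targets_fasta", self.targets_fasta),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path}")
        self.criterion()  # raises on invalid motif parameters

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    coverage: CoverageSummary | float
    tally: extraction.ExtractionTally
    profile: RepeatProfile
    quality: stats.QualityDistribution | None
    primer_sites: primers.PrimerSiteCount | None
    insert_hits: list[inserts.InsertHit] | None
    excess_tests: pd.DataFrame | None
    outputs: dict[str, str]

    @property
    def mean_coverage(self) -> float:
        if isinstance(self.coverage, CoverageSummary):
            return self.coverage.mean_coverage
        return self.coverage


def _profile_sample(
    reads_path: str,
    mate_path: str | None,
    fmt: str | None,
    criterion: ExtractionCriterion,
    both_strands: bool,
    mean_coverage: float,
) -> tuple[list, list, extraction.ExtractionTally, RepeatProfile]:
    """Stream, extract and profile one sample; returns pairs for audits."""
    pairs: list = []
    if mate_path is not None:
        pair_list = list(stream_read_pairs(reads_path, mate_path))
        all_reads = [r for pair in pair_list for r in pair]
        pairs = pair_list
    else:
        all_reads = list(stream_reads(reads_path, fmt))
    telomeric, tally = extraction.extract_telomeric(
        all_reads, criterion, both_strands=both_strands
    )
    profile = build_profile(telomeric, mean_coverage)
    return telomeric, pairs, tally, profile


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline for one sample and write all tables."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest_path = outdir / "MANIFEST"
    manifest_path.write_text("status\tINCOMPLETE\n")
    logger.info("run config: %s", dataclasses.asdict(config))

    try:
        criterion = config.criterion()
        all_reads_count = sum(1 for _ in stream_reads(config.reads, config.format))
        if config.reads_mate:
            all_reads_count *= 2
        if config.coverage is not None:
            coverage: CoverageSummary | float = config.coverage
            mean_coverage = config.coverage
        else:
            first = next(stream_reads(config.reads, config.format))
            coverage = compute_coverage(
                all_reads_count, first.length, config.genome_length
            )
            mean_coverage = coverage.mean_coverage

        telomeric, pairs, tally, profile = _profile_sample(
            config.reads,
            config.reads_mate,
            config.format,
            criterion,
            config.both_strands,
            mean_coverage,
        )

        # extraction tally
        tally_frame = pd.DataFrame(
            [
                {
                    "sample": config.sample_name,
                    "criterion": tally.criterion,
                    "total_reads": tally.total_reads,
                    "telomeric_reads": tally.telomeric_reads,
                    "telomeric_per_coverage": tally.normalized(mean_coverage),
                }
            ]
        )
        outputs["extraction"] = str(outdir / "extraction_tally.tsv")
        tally_frame.to_csv(outputs["extraction"], sep="\t", index=False)

        # profile tables
        outputs["profile_classes"] = str(outdir / "profile_classes.tsv")
        profile.class_table().to_csv(outputs["profile_classes"], sep="\t", index=False)
        outputs["position_matrix"] = str(outdir / "position_matrix.tsv")
        profile.position_table().to_csv(outputs["position_matrix"], sep="\t")

        # unit quality distribution
        quality = None
        if profile.unit_mean_qualities.size:
            quality = stats.quality_distribution(profile.unit_mean_qualities)
            qframe = pd.DataFrame(
                {
                    "threshold": quality.thresholds,
                    "fraction_at_or_above": quality.fraction_at_or_above,
                }
            )
            outputs["unit_quality"] = str(outdir / "unit_quality.tsv")
            qframe.to_csv(outputs["unit_quality"], sep="\t", index=False)

        # variant excess vs baseline
        excess_frame = None
        if config.baseline_reads:
            _, _, _, baseline_profile = _profile_sample(
                config.baseline_reads,
                None,
                config.format,
                criterion,
                config.both_strands,
                mean_coverage,
            )
            excess_frame = excess_table(
                baseline_profile,
                profile,
                q_assumed=config.q_assumed,
                substitution_model=config.substitution_model,
                excluded=config.excluded_variants,
            )
            outputs["variant_excess"] = str(outdir / "variant_excess.tsv")
            excess_frame.to_csv(outputs["variant_excess"], sep="\t", index=False)

        # primer sites
        primer_count = primers.count_primer_sites(telomeric, config.primer_pattern)
        outputs["primer_sites"] = str(outdir / "primer_sites.tsv")
        pd.DataFrame(
            [
                {
                    "sample": config.sample_name,
                    "pattern": primer_count.pattern_name,
                    "total_sites": primer_count.total_sites,
                    "normalized_sites": primer_count.normalized(mean_coverage),
                    "n_reads": primer_count.n_reads,
                }
            ]
        ).to_csv(outputs["primer_sites"], sep="\t", index=False)

        # telomere-insert detection (paired data + target library only)
        hits = None
        if config.targets_fasta and pairs:
            telomeric_ids = {r.read_id for r in telomeric}
            hits = inserts.detect_telomere_inserts(
                pairs,
                telomeric_ids,
                read_fasta(config.targets_fasta),
                min_seed=config.min_seed,
                min_identity=config.min_identity,
            )
            outputs["insert_hits"] = str(outdir / "insert_hits.tsv")
            pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
                outputs["insert_hits"], sep="\t", index=False
            )

        # summary (sample, total reads, telomere reads under active criterion)
        outputs["summary"] = str(outdir / "summary.tsv")
        pd.DataFrame(
            [
                {
                    "sample": config.sample_name,
                    "criterion": tally.criterion,
                    "total_reads": tally.total_reads,
                    "telomere_reads": tally.telomeric_reads,
                    "mean_coverage": mean_coverage,
                    "telomere_reads_per_coverage": tally.normalized(mean_coverage),
                    "hexamer_units": profile.n_hexamer_units,
                    "canonical_pct": 100 * profile.proportion("canonical"),
                }
            ]
        ).to_csv(outputs["summary"], sep="\t", index=False)

        if config.plots:
            _write_plots(profile, outdir, outputs)

        manifest_path.write_text(
            "status\tCOMPLETE\n"
            + "".join(f"{k}\t{v}\n" for k, v in sorted(outputs.items()))
        )
    except Exception:
        logger.exception("pipeline failed; partial outputs retained")
        raise
    return PipelineResult(
        config=config,
        coverage=coverage,
        tally=tally,
        profile=profile,
        quality=quality,
        primer_sites=primer_count,
        insert_hits=hits,
        excess_tests=excess_frame,
        outputs=outputs,
    )


def excess_table(
    baseline: RepeatProfile,
    extended: RepeatProfile,
    q_assumed: float = 30.0,
    substitution_model: str = "specific",
    excluded: list[str] | None = None,
    keys: tuple[str, ...] = DEFAULT_TEST_KEYS,
) -> pd.DataFrame:
    """Variant-excess tests for every reported key, one row per key.

    ``excluded`` lists variants engineered into the extended sample
    (e.g. TCAGGG in a mutant-template line), which are skipped rather
    than flagged.
    """
    excluded = set(excluded or ())
    rows = []
    for key in keys:
        if key in excluded:
            continue
        test = stats.variant_excess_test(
            baseline, extended, key, q_assumed=q_assumed, substitution_model=substitution_model
        )
        rows.append(
            {
                "variant": key,
                "baseline_normalized": test.baseline_count,
                "extended_normalized": test.extended_count,
                "observed_units": test.observed_units,
                "expected_units": test.expected_units,
                "n_units": test.n_units,
                "p_value": test.p_value,
                "significant_p_lt_0.001": test.significant,
            }
        )
    return pd.DataFrame(rows)


def compare_samples(
    profiles: dict[str, RepeatProfile],
    pairing: dict[str, list[str]],
    q_assumed: float = 30.0,
    substitution_model: str = "specific",
    excluded: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Matched baseline-vs-extended deltas plus excess tests per pair.

    ``pairing`` maps each baseline sample to its extended derivatives;
    ``excluded`` optionally maps an extended sample to engineered
    variants to skip.
    """
    missing = [
        name
        for name in list(pairing) + [e for v in pairing.values() for e in v]
        if name not in profiles
    ]
    if missing:
        raise KeyError(f"pairing references absent samples: {sorted(set(missing))}")
    frames = []
    for baseline_name, extended_names in pairing.items():
        for extended_name in extended_names:
            frame = excess_table(
                profiles[baseline_name],
                profiles[extended_name],
                q_assumed=q_assumed,
                substitution_model=substitution_model,
                excluded=(excluded or {}).get(extended_name),
            )
            frame.insert(0, "baseline", baseline_name)
            frame.insert(1, "extended", extended_name)
            frame["delta_normalized"] = (
                frame["extended_normalized"] - frame["baseline_normalized"]
            )
            base, ext = profiles[baseline_name], profiles[extended_name]
            frame["canonical_delta_normalized"] = ext.normalized(
                "canonical"
            ) - base.normalized("canonical")
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _write_plots(profile: RepeatProfile, outdir: Path, outputs: dict[str, str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = profile.class_table()
    classes = table[table.kind == "class"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(classes.key, classes.percentage)
    ax.set_ylabel("% of repeat units")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    path = outdir / "profile_classes.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    outputs["profile_plot"] = str(path)
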