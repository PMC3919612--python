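# Methods

## Read extraction

A read is telomeric when it contains at least `min_count` occurrences of
a degenerate hexamer motif. Occurrences are found greedily left to right
without overlap; `N` in the motif matches any of ACGT (never `N` in the
read). Two presets mirror common practice:

- `survey6` — 6× TNAGGG anywhere in the read (default). Sensitive to
  position-2 variants (all of which are TNAGGG) but blind to position-1
  and position-3 variants, which do not match the motif; the extractor
  logs a warning to surface this bias.
- `content4` — 4× consecutive TTAGGG, a stricter canonical-content
  criterion.

By default both the read and its reverse complement are tested, so
C-strand (CCCTAA-type) reads are retained.

## Tokenization and unit classification

Reads are first oriented to the G-strand (whichever orientation has
more TNAGGG hits wins; ties keep the original). A greedy scan walks the
sequence: at each offset it accepts the 7-mer TTAAGGG, else a hexamer
whose last three bases are GGG, else a hexamer starting TTA, else it
advances one base (counted as "other"). A trailing fragment shorter
than a unit is "other". This gives exact base conservation —
6·hexamers + 7·sevenmers + other = read length — which the test suite
checks both as an invariant and against a dynamic-programming oracle
(the greedy scan recovers ≥95% of planted units at a 1% error rate).

Hexamer units are classified by comparison with TTAGGG: exact match is
canonical; a single substitution at position 1, 2 or 3 is a pos1/pos2/
pos3 variant (nine named variants: GTAGGG/ATAGGG/CTAGGG, TCAGGG/TGAGGG/
TAAGGG, TTCGGG/TTGGGG/TTTGGG); the double variant GCAGGG is tracked by
name; anything else is "other".

## Normalization

Counts are divided by mean coverage, `total_reads × read_length /
genome_length`, so unit counts estimate per-genome telomere content and
are comparable across samples of different depth.

## Error-null test

For a variant (or position class) in an extended sample versus a
matched baseline, the expected count inherits the baseline's variant
proportion scaled to the extended sample's unit total; the observed
excess over that expectation is referred to an exact one-sided binomial
upper tail with n = the extended sample's canonical unit count and
per-unit miscall probability p₀ derived from an assumed phred score
(default Q30, p_err = 10⁻³). Under the `specific` model (default) a
single named variant costs p_err/3 (one particular wrong base); a
position class aggregates three variants and costs the full p_err. The
`any` model charges p_err in both cases. Excesses below a 10⁻⁹
tolerance (float dust when observed equals expected) give p = 1. At
p < 10⁻³ the suite measures ≤0.2% false positives over 1,000 error-only
replicates and >90% power against a 0.005/unit planted position-1 rate
at ~10⁴ units.

## Insert detection

Only read pairs with exactly one telomeric mate are scanned. The
non-telomeric mate is matched against target sequences via an exact
20-mer seed index, then extended ungapped in both directions, stopping
at a streak of 4 mismatches and trimming to the last match; hits
require ≥90% identity. Both strands are scanned.

## Primer-site audit

The degenerate site TGTTAGGG(NTAGGG)₄NTA (35 nt) is counted
non-overlapping on the oriented G-strand. Because GTAGGG and other
NTAGGG-form variants satisfy the degenerate positions, variant-rich
telomeres present at least as many sites as canonical-only telomeres of
equal content — the mechanism by which variant repeats can inflate
qPCR-based content estimates.

## Synthetic data generator

Telomere arrays are built per architecture:

- **mortal** — a proximal variant-rich block (default 50 units with
  25% TCAGGG, 20% TGAGGG, 10% TTGGGG) followed by a distal canonical
  block (Gaussian length, default 400 ± 60 units) carrying sparse
  GTAGGG clusters (rate 0.015/unit, length 2–4).
- **telomerase** — the mortal core plus `extension_units` (default 600)
  appended canonical units with per-unit misincorporation at position 1
  (0.005) and position 3 (0.003), never position 2. Defaults are chosen
  so the extension signal is detectable at modest depth while variant
  proportions stay realistic (≈1% of extension units).
- **alt** — the core eroded to a crisis state (distal block cut to 320
  units), then grown by recombination copying: 10-unit windows from a
  uniformly chosen donor position are inserted at uniform positions
  until the array reaches 1,600 units. Copying preserves the crisis
  composition in expectation, so the variant:canonical ratio is
  preserved while absolute content is amplified.

An optional `unit_composition` draws units i.i.d. instead — used for
parameter-recovery experiments where an exact planted proportion is
needed. A foreign insert sequence can be planted with a given
probability (and is itself amplified by ALT copying).

Reads are sampled WGS-style: each fragment is telomeric with
probability telomere_bases/genome_length (non-telomeric fragments come
from a random decoy sequence), placed uniformly within an array, on a
uniform strand; paired mode emits both fragment ends. Base-call errors
are i.i.d. per base (default 10⁻³, the Q30 benchmark) with the wrong
base uniform over the three alternatives; qualities are rounded
Gaussians (default 34 ± 3, clipped to [2, 40]). Every sample carries a
per-read truth table and per-array unit counts.

All randomness flows from `numpy.random.default_rng` seeded with
`(spec.seed, stream_index)` tuples; identical specs reproduce
byte-identical FASTQ output.

## Numerical choices

- Exact binomial tails via `scipy.stats.binom.sf` (no normal
  approximation; excess counts are often single digits).
- Integer phred arrays (`int16`); phred+33 encoding on FASTQ I/O.
- Greedy regex-based motif matching (`re.finditer` semantics),
  validated against exhaustive window-scan oracles in the tests.

## Limitations

- The error model is i.i.d. per base; real platforms have
  context-dependent and position-dependent error, so the Q30 null is a
  convention, not a measurement — `q_assumed` should be set from the
  run's actual quality profile.
- TNAGGG extraction under-represents position-1/3 variant-rich reads;
  comparisons are only valid between samples extracted with the same
  criterion.
- Read-level profiles of short arrays under-cover array edges (the
  variant-rich proximal block); truth-level baselines are used where
  the generative composition itself is the quantity of interest.
- The ALT model is a single-mechanism caricature (uniform-window
  copying after a fixed crisis erosion); it reproduces the
  ratio-preservation and amplification signatures but not clone-level
  heterogeneity.
- Subtelomeric sequence, degraded/chimeric reads and alignment-based
  workflows are out of scope; BAM input is read unaligned.
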