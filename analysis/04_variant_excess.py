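"""Test variant excesses in the telomerase strain against base-call error.

Builds a matched pair — a mortal parent and a telomerase derivative with
identical parameters apart from extension, both without distal variant
clusters so every position-1/3 unit in the derivative is attributable to
misincorporation — and runs the exact binomial error-null test for each
variant class and named variant.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import write_table

from telovar.extraction import ExtractionCriterion, extract_telomeric
from telovar.pipeline import excess_table
from telovar.repeats import build_profile
from telovar.simulate import SyntheticTelomereSpec, simulate_sample


def profile_for(spec):
    sample = simulate_sample(spec)
    telomeric, _ = extract_telomeric(sample.reads, ExtractionCriterion())
    return build_profile(telomeric, sample.coverage)


def main() -> None:
    common = dict(
        distal_cluster_rate=0.0, n_reads=4000, genome_length=150_000
    )
    parent = profile_for(SyntheticTelomereSpec(
        mode="mortal", name="parent", seed=201, **common
    ))
    extended = profile_for(SyntheticTelomereSpec(
        mode="telomerase", name="extended", extension_units=1200, seed=202,
        **common
    ))
    frame = excess_table(parent, extended)
    frame.insert(0, "comparison", "extended_vs_parent")
    write_table(frame, "variant_excess.tsv")


if __name__ == "__main__":
    main()
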