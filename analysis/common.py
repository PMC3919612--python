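"""Shared cohort definition for the numbered analysis scripts.

Three synthetic strains model the three telomere-maintenance
architectures: a mortal parent, a telomerase-immortalized derivative and
a recombination-driven (ALT) derivative. Scripts re-simulate on demand —
generation takes seconds and keeps every table reproducible from code.
"""

from __future__ import annotations

from pathlib import Path

from telovar.simulate import SyntheticTelomereSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

COHORT = {
    "mortal": SyntheticTelomereSpec(
        mode="mortal", name="mortal", n_reads=4000, seed=101,
        genome_length=150_000,
    ),
    "telomerase": SyntheticTelomereSpec(
        mode="telomerase", name="telomerase", n_reads=4000, seed=102,
        genome_length=150_000,
    ),
    "alt": SyntheticTelomereSpec(
        mode="alt", name="alt", n_reads=4000, seed=103,
        genome_length=150_000,
    ),
}


def write_table(frame, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {path} ({len(frame)} rows)")
    return path
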