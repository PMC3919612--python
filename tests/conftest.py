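"""Shared fixtures: small synthetic samples reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from telovar.io import ReadRecord
from telovar.simulate import SyntheticTelomereSpec, simulate_sample


def make_read(sequence: str, read_id: str = "r", q: int = 35) -> ReadRecord:
    return ReadRecord(read_id, sequence, np.full(len(sequence), q, dtype=np.int16))


@pytest.fixture(scope="session")
def mortal_sample():
    """Small mortal sample with sequencing error, used as a demo corpus."""
    return simulate_sample(
        SyntheticTelomereSpec(
            mode="mortal", name="mortal", n_reads=2000, seed=11, genome_length=200_000
        )
    )


@pytest.fixture(scope="session")
def telomerase_sample():
    return simulate_sample(
        SyntheticTelomereSpec(
            mode="telomerase",
            name="telomerase",
            n_reads=2000,
            seed=12,
            genome_length=200_000,
        )
    )


@pytest.fixture(scope="session")
def alt_sample():
    return simulate_sample(
        SyntheticTelomereSpec(
            mode="alt", name="alt", n_reads=2000, seed=13, genome_length=200_000
        )
    )


@pytest.fixture(scope="session")
def demo_reads(mortal_sample, telomerase_sample, alt_sample):
    """Pooled demo read list across the three architectures."""
    return (
        mortal_sample.reads + telomerase_sample.reads + alt_sample.reads
    )
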