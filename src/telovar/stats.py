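"""Phred-score computations and the sequencing-error null test.

The central statistical question: when an extended-telomere sample shows
more of some variant repeat than its matched baseline, could the excess
be nothing but base-call error? Under the null, every canonical hexamer
in the extended sample is independently misread as the queried variant
with probability p0 derived from an assumed phred score (Q30 by default,
the platform benchmark: 1 miscall in 1000). The observed excess over the
baseline-implied expectation is then referred to an exact one-sided
binomial upper tail.

Two substitution conventions are exposed: ``specific`` (default) charges
p0 = P_err / 3 per single named variant, since producing one particular
variant requires one particular wrong base; ``any`` charges the full
P_err. Position classes (pos1/pos2/pos3) aggregate three single-base
variants, so under ``specific`` their p0 is the full per-base P_err.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .repeats import NAMED_VARIANTS, RepeatProfile

__all__ = [
    "QualityDistribution",
    "VariantExcessTest",
    "phred_to_error_prob",
    "error_prob_to_phred",
    "quality_distribution",
    "variant_excess_test",
]

DEFAULT_THRESHOLDS: tuple[int, ...] = (40, 30, 20, 10, 0)
_POSITION_KEYS = {"pos1": 3, "pos2": 3, "pos3": 3}


def phred_to_error_prob(q: float) -> float:
    """P(base call wrong) = 10^(-Q/10); Q30 -> 1/1000, Q20 -> 1/100."""
    if q < 0:
        raise ValueError("phred scores are non-negative")
    return 10.0 ** (-q / 10.0)


def error_prob_to_phred(p: float) -> float:
    if not 0 < p <= 1:
        raise ValueError("error probability must be in (0, 1]")
    return -10.0 * math.log10(p)


@dataclass(frozen=True)
class QualityDistribution:
    """Fraction of repeat units at or above each mean-phred threshold."""

    thresholds: tuple[int, ...]
    fraction_at_or_above: tuple[float, ...]

    def __post_init__(self) -> None:
        fracs = self.fraction_at_or_above
        if any(a > b + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("fractions must be non-decreasing as thresholds drop")


def quality_distribution(
    unit_mean_qualities: Sequence[float] | np.ndarray,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> QualityDistribution:
    """Per-repeat-unit mean quality distribution (thresholds descending)."""
    quals = np.asarray(unit_mean_qualities, dtype=float)
    quals = quals[np.isfinite(quals)]
    if quals.size == 0:
        raise ValueError("no repeat units with defined quality")
    fractions = tuple(float(np.mean(quals >= t)) for t in thresholds)
    return QualityDistribution(tuple(thresholds), fractions)


@dataclass(frozen=True)
class VariantExcessTest:
    """One-sided exact binomial test of variant excess against miscall error."""

    variant_key: str
    baseline_count: float
    extended_count: float
    observed_units: int
    expected_units: float
    n_units: int
    per_unit_error: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 1e-3


def _profile_count(profile: RepeatProfile, key: str) -> int:
    if key in _POSITION_KEYS or key.endswith("_variant"):
        return profile.count(key)
    if key in NAMED_VARIANTS or (len(key) in (6, 7) and set(key) <= set("ACGT")):
        return profile.variant_counts[key]
    raise KeyError(f"unknown variant key {key!r}")


def variant_excess_test(
    baseline: RepeatProfile,
    extended: RepeatProfile,
    variant_key: str,
    q_assumed: float = 30.0,
    substitution_model: str = "specific",
) -> VariantExcessTest:
    """Test whether extra variant units in ``extended`` exceed error.

    ``variant_key`` is a named variant (e.g. ``"GTAGGG"``) or a position
    class (``"pos1"``/``"pos2"``/``"pos3"``). The expected count in the
    extended sample inherits the baseline sample's variant proportion, so
    the test addresses the *increase*, not the absolute amount.
    """
    if substitution_model not in {"any", "specific"}:
        raise ValueError("substitution_model must be 'any' or 'specific'")
    p_err = phred_to_error_prob(q_assumed)
    n_alternatives = _POSITION_KEYS.get(variant_key, 1)
    if substitution_model == "specific":
        p0 = min(p_err / 3.0 * n_alternatives, p_err)
    else:
        p0 = p_err

    observed = _profile_count(extended, variant_key)
    baseline_units = baseline.n_hexamer_units
    baseline_prop = (
        _profile_count(baseline, variant_key) / baseline_units if baseline_units else 0.0
    )
    expected = baseline_prop * extended.n_hexamer_units
    n_canonical = extended.class_counts["canonical"]

    # tolerance guards against float dust when expected == observed exactly
    excess = observed - expected
    if excess <= 1e-9 or n_canonical == 0:
        p_value = 1.0
    else:
        k = math.ceil(excess - 1e-9)
        p_value = float(binom.sf(k - 1, n_canonical, p0))
    return VariantExcessTest(
        variant_key=variant_key,
        baseline_count=_profile_count(baseline, variant_key) / baseline.mean_coverage,
        extended_count=observed / extended.mean_coverage,
        observed_units=observed,
        expected_units=expected,
        n_units=extended.n_hexamer_units,
        per_unit_error=p0,
        p_value=p_value,
    )
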