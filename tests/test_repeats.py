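"""Tokenization, classification, orientation and profile construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telovar.extraction import reverse_complement
from telovar.io import ReadRecord
from telovar.repeats import (
    CANONICAL,
    build_profile,
    classify_unit,
    orient_g_strand,
    position_matrix,
    tokenize_read,
)
from telovar.simulate import SyntheticTelomereSpec, simulate_sample

from conftest import make_read


class TestClassifyUnit:
    @pytest.mark.parametrize(
        "unit,label,key",
        [
            ("TTAGGG", "canonical", None),
            ("TCAGGG", "pos2_variant", "TCAGGG"),
            ("TGAGGG", "pos2_variant", "TGAGGG"),
            ("TAAGGG", "pos2_variant", "TAAGGG"),
            ("GTAGGG", "pos1_variant", "GTAGGG"),
            ("ATAGGG", "pos1_variant", "ATAGGG"),
            ("CTAGGG", "pos1_variant", "CTAGGG"),
            ("TTCGGG", "pos3_variant", "TTCGGG"),
            ("TTGGGG", "pos3_variant", "TTGGGG"),
            ("TTTGGG", "pos3_variant", "TTTGGG"),
            ("TTAAGG", "pos456_variant", "TTAAGG"),
            ("TTAGGC", "pos456_variant", "TTAGGC"),
            ("TTAAGGG", "sevenmer_TTAAGGG", "TTAAGGG"),
            ("GCAGGG", "other", "GCAGGG"),  # double mismatch, tracked by name
            ("AAAAAA", "other", None),
            ("TNAGGG", "other", None),
        ],
    )
    def test_inventory(self, unit, label, key):
        assert classify_unit(unit) == (label, key)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            classify_unit("TTAGG")
        with pytest.raises(ValueError):
            classify_unit("TTAGGGTT")

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=6, max_size=7))
    def test_total_and_deterministic(self, unit):
        """Every 6/7-mer receives exactly one label, reproducibly."""
        label, key = classify_unit(unit)
        assert label in {
            "canonical",
            "pos1_variant",
            "pos2_variant",
            "pos3_variant",
            "pos456_variant",
            "sevenmer_TTAAGGG",
            "other",
        }
        assert classify_unit(unit) == (label, key)
        if label == "canonical":
            assert unit == "TTAGGG"
        if label == "sevenmer_TTAAGGG":
            assert unit == "TTAAGGG"
        if label.startswith("pos") and label != "pos456_variant":
            pos = int(label[3]) - 1
            assert unit.endswith("GGG") and unit[pos] != CANONICAL[pos]


class TestTokenize:
    def test_pure_canonical_in_frame(self):
        units, other = tokenize_read("TTAGGG" * 16 + "TTAG")
        assert len(units) == 16
        assert all(u.label == "canonical" for u in units)
        assert other == 4

    def test_gtaggg_interspersion(self):
        units, other = tokenize_read("TTAGGGGTAGGGGTAGGGTTAGGG")
        assert [u.unit_seq for u in units] == ["TTAGGG", "GTAGGG", "GTAGGG", "TTAGGG"]
        assert other == 0

    def test_sevenmer_recognised_before_hexamers(self):
        units, other = tokenize_read("TTAGGG" + "TTAAGGG" + "TTAGGG")
        assert [u.unit_seq for u in units] == ["TTAGGG", "TTAAGGG", "TTAGGG"]
        assert other == 0

    def test_offsets_and_mean_quality(self):
        quals = np.arange(12)
        units, _ = tokenize_read("TTAGGGTCAGGG", quals)
        assert [u.offset for u in units] == [0, 6]
        assert units[0].mean_quality == pytest.approx(np.mean(quals[:6]))
        assert units[1].mean_quality == pytest.approx(np.mean(quals[6:]))

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=150))
    def test_base_conservation(self, sequence):
        """6 x hexamers + 7 x sevenmers + other_bases == sequence length."""
        units, other = tokenize_read(sequence)
        assert sum(len(u.unit_seq) for u in units) + other == len(sequence)

    def test_greedy_near_optimal_on_mutated_arrays(self):
        """Greedy segmentation recovers >=95% of planted units at 1% error.

        Oracle: exhaustive DP maximizing the number of units over all
        segmentations of short (<=60 nt) mutated arrays.
        """

        def dp_max_units(seq: str) -> int:
            n = len(seq)
            best = [0] * (n + 1)
            for i in range(n - 1, -1, -1):
                best[i] = best[i + 1]
                if i + 7 <= n and seq[i : i + 7] == "TTAAGGG":
                    best[i] = max(best[i], 1 + best[i + 7])
                if i + 6 <= n:
                    w = seq[i : i + 6]
                    if ("N" not in w) and (w.endswith("GGG") or w.startswith("TTA")):
                        best[i] = max(best[i], 1 + best[i + 6])
            return best[0]

        rng = np.random.default_rng(0)
        alphabet = "ACGT"
        planted_total = 0
        greedy_total = 0
        for _ in range(300):
            n_units = int(rng.integers(5, 11))
            units = rng.choice(
                ["TTAGGG", "TCAGGG", "GTAGGG", "TTGGGG"], size=n_units, p=[0.8, 0.1, 0.07, 0.03]
            )
            seq = list("".join(units))
            for j in range(len(seq)):  # 1% per-base mutation
                if rng.random() < 0.01:
                    seq[j] = alphabet[rng.integers(0, 4)]
            seq = "".join(seq)
            units_found, _ = tokenize_read(seq)
            greedy_total += len(units_found)
            planted_total += n_units
            assert len(units_found) <= dp_max_units(seq)
        assert greedy_total >= 0.95 * planted_total


class TestOrientation:
    def test_c_strand_read_flipped(self):
        read = make_read("CCCTAA" * 5)
        oriented = orient_g_strand(read)
        assert oriented.sequence == "TTAGGG" * 5

    def test_g_strand_read_unchanged(self):
        read = make_read("TTAGGG" * 5)
        assert orient_g_strand(read) is read

    def test_qualities_reversed_with_sequence(self):
        quals = np.arange(12)
        read = ReadRecord("r", "CCCTAA" * 2, quals)
        oriented = orient_g_strand(read)
        assert np.array_equal(oriented.qualities, quals[::-1])

    def test_matches_generator_strand_truth(self, mortal_sample):
        """Orientation recovers the source strand for >=99% of telomeric reads."""
        truth = mortal_sample.truth.set_index("read_id")
        telomeric = [
            r for r in mortal_sample.reads if truth.loc[r.read_id, "is_telomeric"]
        ]
        assert len(telomeric) > 20
        correct = 0
        for read in telomeric:
            oriented = orient_g_strand(read)
            flipped = oriented.sequence != read.sequence
            # '+' fragments read the G strand already; '-' need flipping
            expected_flip = truth.loc[read.read_id, "strand"] == "-"
            correct += flipped == expected_flip
        assert correct / len(telomeric) >= 0.99


class TestPositionMatrix:
    def test_canonical_columns(self):
        units, _ = tokenize_read("TTAGGG" * 7)
        matrix = position_matrix(units)
        # rows A,C,G,T; canonical is TTAGGG
        assert matrix[3, 0] == 7 and matrix[3, 1] == 7 and matrix[0, 2] == 7
        assert (matrix[2, 3:] == 7).all()

    def test_mixed_units(self):
        units, _ = tokenize_read("TTAGGGTCAGGG")
        matrix = position_matrix(units)
        assert matrix[3, 1] == 1 and matrix[1, 1] == 1  # position 2: one T, one C

    def test_against_direct_tally(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        seqs = [
            "".join(bases[i] for i in rng.integers(0, 4, size=3)) + "GGG"
            for _ in range(200)
        ]
        units, _ = tokenize_read("".join(seqs))
        matrix = position_matrix(units)
        expected = np.zeros((4, 6), dtype=int)
        for u in units:
            for pos, base in enumerate(u.unit_seq):
                expected["ACGT".index(base), pos] += 1
        assert np.array_equal(matrix, expected)
        assert (matrix.sum(axis=0) == len(units)).all()


class TestBuildProfile:
    def test_recovers_planted_composition(self):
        """Error-free profile recovers iid composition within 3x binomial SE."""
        composition = {"GTAGGG": 0.07, "TCAGGG": 0.05}
        spec = SyntheticTelomereSpec(
            unit_composition=composition,
            distal_length_units=(1300.0, 10.0),
            n_telomeres=8,
            n_reads=4000,
            error_rate=0.0,
            seed=21,
            genome_length=70_000,
        )
        sample = simulate_sample(spec)
        from telovar.extraction import ExtractionCriterion, extract_telomeric

        telomeric, _ = extract_telomeric(sample.reads, ExtractionCriterion())
        profile = build_profile(telomeric, sample.coverage)
        # binomial SE on the scale of the planted array (the generative draw)
        n_planted = sum(sample.truth_unit_counts().values())
        assert n_planted >= 10_000
        for variant, p in composition.items():
            se = (p * (1 - p) / n_planted) ** 0.5
            assert abs(profile.proportion(variant) - p) <= 3 * se
        p_can = 1 - sum(composition.values())
        se = (p_can * (1 - p_can) / n_planted) ** 0.5
        assert abs(profile.proportion("canonical") - p_can) <= 3 * se

    def test_normalization_contract(self, mortal_sample):
        telomeric = [
            r
            for r in mortal_sample.reads
            if mortal_sample.truth.set_index("read_id").loc[r.read_id, "is_telomeric"]
        ]
        p1 = build_profile(telomeric, 1.0)
        p2 = build_profile(telomeric, 2.0)
        for key in ("canonical", "pos1", "pos2", "GTAGGG"):
            assert p2.normalized(key) == pytest.approx(p1.normalized(key) / 2)

    def test_strand_symmetric_after_orientation(self, mortal_sample):
        truth = mortal_sample.truth.set_index("read_id")
        telomeric = [
            r for r in mortal_sample.reads if truth.loc[r.read_id, "is_telomeric"]
        ]
        flipped = [
            ReadRecord(r.read_id, reverse_complement(r.sequence), r.qualities[::-1].copy())
            for r in telomeric
        ]
        p1 = build_profile(telomeric, 1.0)
        p2 = build_profile(flipped, 1.0)
        assert p1.class_counts == p2.class_counts
        assert p1.variant_counts == p2.variant_counts
        assert np.array_equal(p1.position_matrix, p2.position_matrix)

    def test_conservation_and_column_sums(self, mortal_sample, telomerase_sample):
        for sample in (mortal_sample, telomerase_sample):
            profile = build_profile(sample.reads, sample.coverage)
            assert (
                6 * profile.n_hexamer_units
                + 7 * profile.n_sevenmer_units
                + profile.other_bases
                == profile.total_bases
            )
            assert (profile.position_matrix.sum(axis=0) == profile.n_hexamer_units).all()

    def test_zero_coverage_fatal(self):
        with pytest.raises(ValueError):
            build_profile([], 0.0)
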