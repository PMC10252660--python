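"""Scar statistics: definition-forced examples, invariances, and exact
agreement with the per-bp brute-force oracle."""

import numpy as np
import pytest

from scarface.genome import Segment, SegmentProfile
from scarface.scars import (
    default_catalogue,
    gi_parameter_vector,
    hrd_loh_score,
    loh_events,
    lst_score,
    ntai_score,
    percent_genome_altered,
    scar_scores,
)

from _oracle import (
    oracle_event_count,
    oracle_hrd_loh,
    oracle_lst,
    oracle_ntai,
    oracle_pct_genome,
    random_profile,
)

MB = 1_000_000
KB = 1_000


def profile(layout, segs, sid="t"):
    return SegmentProfile(sid, list(segs)).validate(layout)


class TestLohEvents:
    def test_empty_profile(self, layout_mb):
        assert loh_events(profile(layout_mb, []), layout_mb) == 0

    def test_single_long_run(self, layout_mb):
        p = profile(layout_mb, [Segment("chr1", 1, 20 * MB, 2, 0)])
        assert loh_events(p, layout_mb, 15 * MB) == 1

    def test_adjacent_segments_merge_into_one_run(self, layout_mb):
        # 8 Mb + 9 Mb contiguous LOH segments form a single 17 Mb run
        p = profile(
            layout_mb,
            [
                Segment("chr1", 1, 8 * MB, 2, 0),
                Segment("chr1", 8 * MB + 1, 17 * MB, 1, 0),
            ],
        )
        assert loh_events(p, layout_mb, 15 * MB) == 1

    def test_adding_qualifying_run_increments_count(self, layout_mb):
        base = [Segment("chr1", 1, 20 * MB, 2, 0)]
        extra = Segment("chr2", 1, 20 * MB, 2, 0)
        p0 = profile(layout_mb, base)
        p1 = profile(layout_mb, base + [extra], "t2")
        assert loh_events(p1, layout_mb) == loh_events(p0, layout_mb) + 1

    def test_homozygous_deletion_is_not_loh(self, layout_mb):
        p = profile(layout_mb, [Segment("chr1", 1, 20 * MB, 0, 0)])
        assert loh_events(p, layout_mb) == 0
        assert oracle_event_count(p, layout_mb, "loss", 15 * MB) == 1


class TestPercentGenomeAltered:
    def test_no_events(self, layout_mb):
        p = profile(layout_mb, [Segment("chr1", 1, 100 * MB, 2, 1)])
        assert percent_genome_altered(p, layout_mb, "loh") == 0.0

    def test_arithmetic_forced_fraction(self, layout_mb):
        # one 24 Mb LOH run in a 240 Mb genome
        p = profile(layout_mb, [Segment("chr1", 1, 24 * MB, 2, 0)])
        assert percent_genome_altered(p, layout_mb, "loh", 15 * MB) == pytest.approx(0.10)


class TestHrdLoh:
    def test_whole_chromosome_run_excluded(self, layout_mb):
        p = profile(layout_mb, [Segment("chr3", 1, 60 * MB, 2, 0)])
        assert hrd_loh_score(p, layout_mb) == 0
        assert loh_events(p, layout_mb) == 1  # the plain count still sees it

    def test_long_partial_run_counts(self, layout_mb):
        p = profile(layout_mb, [Segment("chr1", 1, 20 * MB, 2, 0)])
        assert hrd_loh_score(p, layout_mb) == 1


class TestLst:
    def test_two_large_segments_different_state(self, layout_mb):
        p = profile(
            layout_mb,
            [
                Segment("chr1", 1, 12 * MB, 2, 1),
                Segment("chr1", 12 * MB + 1, 24 * MB, 3, 1),
            ],
        )
        assert lst_score(p, layout_mb) == 1

    def test_small_interloper_smoothed_away(self, layout_mb):
        p = profile(
            layout_mb,
            [
                Segment("chr1", 1, 12 * MB, 2, 1),
                Segment("chr1", 12 * MB + 1, 14 * MB, 4, 1),
                Segment("chr1", 14 * MB + 1, 26 * MB, 3, 1),
            ],
        )
        assert lst_score(p, layout_mb) == 1

    def test_uniform_genome_has_no_transitions(self, layout_mb):
        segs = [Segment(c.name, 1, c.length, 2, 1) for c in layout_mb]
        assert lst_score(profile(layout_mb, segs), layout_mb) == 0


class TestNtai:
    def test_telomeric_run_counts(self, layout_mb):
        p = profile(
            layout_mb,
            [
                Segment("chr1", 1, 20 * MB, 3, 1),
                Segment("chr1", 20 * MB + 1, 100 * MB, 2, 1),
            ],
        )
        assert ntai_score(p, layout_mb) == 1

    def test_centromere_crossing_run_excluded(self, layout_mb):
        p = profile(layout_mb, [Segment("chr1", 40 * MB, 55 * MB, 3, 1)])
        assert ntai_score(p, layout_mb) == 0


class TestScarScores:
    def test_empty_profile_all_zero(self, layout_mb):
        s = scar_scores(profile(layout_mb, []), layout_mb)
        assert (s.hrd_loh, s.lst, s.ntai, s.hrd_sum) == (0, 0, 0, 0)

    def test_worked_fixture_one_event_per_type(self, worked_profile, layout_mb):
        s = scar_scores(worked_profile, layout_mb)
        assert (s.hrd_loh, s.lst, s.ntai, s.hrd_sum) == (1, 1, 1, 3)

    def test_hrd_sum_additivity_on_random_profiles(self, layout_kb, rng):
        for _ in range(25):
            p = random_profile(rng, layout_kb)
            s = scar_scores(p, layout_kb, 15 * KB, 10 * KB, 3 * KB, KB)
            assert s.hrd_sum == s.hrd_loh + s.lst + s.ntai


class TestGiParameterVector:
    def test_default_catalogue_has_28_named_values(self, worked_profile, layout_mb):
        v = gi_parameter_vector(worked_profile, layout_mb)
        assert len(v) == 28
        assert set(default_catalogue().ids) == set(v)

    def test_single_segment_diploid_genome_all_zero(self, layout_mb):
        segs = [Segment(c.name, 1, c.length, 2, 1) for c in layout_mb]
        v = gi_parameter_vector(profile(layout_mb, segs), layout_mb)
        assert all(x == 0 for x in v.values())

    def test_catalogue_permutation_gives_same_values(self, worked_profile, layout_mb):
        cat = default_catalogue()
        permuted = type(cat)(tuple(reversed(cat.entries)), cat.include_scar_scores)
        v1 = gi_parameter_vector(worked_profile, layout_mb, cat)
        v2 = gi_parameter_vector(worked_profile, layout_mb, permuted)
        assert v1 == {k: v2[k] for k in v1}

    def test_counts_integer_percentages_bounded(self, layout_kb, rng):
        for _ in range(10):
            v = gi_parameter_vector(random_profile(rng, layout_kb), layout_kb, scale=KB)
            for k, x in v.items():
                if "pct" in k:
                    assert 0.0 <= x <= 1.0
                else:
                    assert x >= 0 and x == int(x)


class TestInvariances:
    def test_segment_input_order_never_matters(self, layout_mb, worked_profile, rng):
        segs = list(worked_profile.segments)
        rng.shuffle(segs)
        p = SegmentProfile("shuffled", segs).validate(layout_mb)
        assert scar_scores(p, layout_mb) == scar_scores(worked_profile, layout_mb)

    def test_splitting_segments_never_changes_scores(self, layout_kb, rng):
        """Splitting any segment into two adjacent pieces with identical
        allele state is a no-op for every scar value."""
        cat_kwargs = dict(scale=KB)
        for _ in range(20):
            p = random_profile(rng, layout_kb)
            split_segs = []
            for seg in p.segments:
                if seg.length > 1 and rng.random() < 0.5:
                    cut = int(rng.integers(seg.start, seg.end))
                    split_segs.append(Segment(seg.chrom, seg.start, cut, seg.total_cn, seg.minor_cn))
                    split_segs.append(Segment(seg.chrom, cut + 1, seg.end, seg.total_cn, seg.minor_cn))
                else:
                    split_segs.append(seg)
            q = SegmentProfile("split", split_segs).validate(layout_kb)
            assert gi_parameter_vector(q, layout_kb, **cat_kwargs) == gi_parameter_vector(
                p, layout_kb, **cat_kwargs
            )


class TestOracleAgreement:
    """Segment-based statistics equal the per-bp brute-force sweep."""

    def test_all_statistics_match_oracle_on_random_profiles(self, layout_kb, rng):
        for _ in range(60):
            p = random_profile(rng, layout_kb)
            assert loh_events(p, layout_kb, 15 * KB) == oracle_event_count(
                p, layout_kb, "loh", 15 * KB
            )
            assert hrd_loh_score(p, layout_kb, 15 * KB) == oracle_hrd_loh(p, layout_kb, 15 * KB)
            assert lst_score(p, layout_kb, 10 * KB, 3 * KB) == oracle_lst(
                p, layout_kb, 10 * KB, 3 * KB
            )
            assert ntai_score(p, layout_kb, KB) == oracle_ntai(p, layout_kb, KB)
            for cls in ("loh", "loss", "gain", "allelic_imbalance"):
                assert percent_genome_altered(p, layout_kb, cls, 10 * KB) == pytest.approx(
                    oracle_pct_genome(p, layout_kb, cls, 10 * KB), abs=0
                )
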