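"""Independent brute-force oracles for the scar statistics.

Everything here works on literal per-base-pair state arrays: each
chromosome becomes three arrays (total CN, minor CN, covered) indexed by
base pair, event states are evaluated per bp, and runs are read off the
boolean arrays.  Nothing is shared with the segment-based implementation
under test.  Intended for the kilobase-scaled mini-genome, where a
per-bp sweep is cheap.
"""

from __future__ import annotations

import numpy as np

from scarface.genome import GenomeLayout, Segment, SegmentProfile


def bp_arrays(profile: SegmentProfile, chrom_name: str, length: int):
    total = np.full(length, -1, dtype=np.int16)
    minor = np.full(length, -1, dtype=np.int16)
    for seg in profile.segments:
        if seg.chrom == chrom_name:
            total[seg.start - 1 : seg.end] = seg.total_cn
            minor[seg.start - 1 : seg.end] = seg.minor_cn
    covered = total >= 0
    return total, minor, covered


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 1-based closed (start, end) intervals."""
    padded = np.r_[False, mask, False].astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _state_mask(total, minor, covered, event_class: str) -> np.ndarray:
    if event_class == "loh":
        return covered & (minor == 0) & (total >= 1)
    if event_class == "loss":
        return covered & (total < 2)
    if event_class == "gain":
        return covered & (total > 2)
    if event_class == "allelic_imbalance":
        return covered & (minor != total - minor)
    raise ValueError(event_class)


def oracle_event_count(
    profile: SegmentProfile, layout: GenomeLayout, event_class: str, min_length: int
) -> int:
    n = 0
    for chrom in layout:
        t, m, c = bp_arrays(profile, chrom.name, chrom.length)
        for s, e in _mask_runs(_state_mask(t, m, c, event_class)):
            if e - s + 1 > min_length:
                n += 1
    return n


def oracle_pct_genome(
    profile: SegmentProfile, layout: GenomeLayout, event_class: str, min_length: int
) -> float:
    bp = 0
    for chrom in layout:
        t, m, c = bp_arrays(profile, chrom.name, chrom.length)
        for s, e in _mask_runs(_state_mask(t, m, c, event_class)):
            if e - s + 1 > min_length:
                bp += e - s + 1
    return bp / layout.total_length


def oracle_hrd_loh(profile: SegmentProfile, layout: GenomeLayout, min_length: int) -> int:
    n = 0
    for chrom in layout:
        t, m, c = bp_arrays(profile, chrom.name, chrom.length)
        for s, e in _mask_runs(_state_mask(t, m, c, "loh")):
            if e - s + 1 > min_length and not (s == 1 and e == chrom.length):
                n += 1
    return n


def oracle_ntai(profile: SegmentProfile, layout: GenomeLayout, min_length: int) -> int:
    n = 0
    for chrom in layout:
        t, m, c = bp_arrays(profile, chrom.name, chrom.length)
        for s, e in _mask_runs(_state_mask(t, m, c, "allelic_imbalance")):
            telomeric = s == 1 or e == chrom.length
            overlaps_cen = s <= chrom.cen_end and e >= chrom.cen_start
            if telomeric and not overlaps_cen and e - s + 1 > min_length:
                n += 1
    return n


def oracle_lst(
    profile: SegmentProfile, layout: GenomeLayout, min_flank: int, smooth_below: int
) -> int:
    count = 0
    for chrom in layout:
        t, m, c = bp_arrays(profile, chrom.name, chrom.length)
        mid = chrom.cen_mid
        for lo, hi in ((0, mid), (mid, chrom.length)):  # 0-based half-open arm slices
            count += _lst_from_arrays(
                t[lo:hi], m[lo:hi], c[lo:hi], min_flank, smooth_below
            )
    return count


def _lst_from_arrays(total, minor, covered, min_flank: int, smooth_below: int) -> int:
    # constant-state covered runs straight off the bp arrays
    state = np.where(covered, total.astype(np.int64) * 1000 + minor, -1)
    runs: list[list[int]] = []  # [start, end, total, minor], 0-based closed
    change = np.r_[0, np.flatnonzero(np.diff(state)) + 1, state.size]
    for s, e in zip(change, change[1:]):
        if state[s] >= 0:
            runs.append([int(s), int(e) - 1, int(total[s]), int(minor[s])])
    # smoothing: delete shortest sub-threshold run, merging equal-state neighbours
    while len(runs) > 1:
        lengths = [r[1] - r[0] + 1 for r in runs]
        j = int(np.argmin(lengths))
        if lengths[j] >= smooth_below:
            break
        del runs[j]
        i = j - 1
        if 0 <= i < len(runs) - 1 and runs[i][2:] == runs[i + 1][2:]:
            runs[i] = [runs[i][0], runs[i + 1][1], runs[i][2], runs[i][3]]
            del runs[i + 1]
    n = 0
    for a, b in zip(runs, runs[1:]):
        gap = b[0] - a[1] - 1
        if (
            a[2:] != b[2:]
            and a[1] - a[0] + 1 >= min_flank
            and b[1] - b[0] + 1 >= min_flank
            and gap < smooth_below
        ):
            n += 1
    return n


# ---------------------------------------------------------------------------
# random profile generator for oracle comparisons

def random_profile(
    rng: np.random.Generator,
    layout: GenomeLayout,
    max_breaks: int = 12,
    p_gap: float = 0.15,
    sample_id: str = "rand",
) -> SegmentProfile:
    """Arbitrary valid profile: random breakpoints, CN states in 0..4
    (including homozygous deletions), occasional uncovered gaps."""
    segments = []
    for chrom in layout:
        k = int(rng.integers(0, max_breaks + 1))
        cuts = np.unique(rng.integers(1, chrom.length, size=k)) if k else np.array([], int)
        bounds = [1, *[int(x) + 1 for x in cuts], chrom.length + 1]
        for lo, hi in zip(bounds, bounds[1:]):
            if rng.random() < p_gap:
                continue
            total = int(rng.integers(0, 5))
            minor = int(rng.integers(0, total // 2 + 1))
            segments.append(Segment(chrom.name, lo, hi - 1, total, minor))
    return SegmentProfile(sample_id, segments).validate(layout)
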