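"""Genomic-scar statistics from allele-specific copy-number segments.

Homologous recombination deficiency (HRD) leaves persistent copy-number
footprints — "genomic scars" — that this module counts from a
:class:`~scarface.genome.SegmentProfile`:

* **HRD-LOH** — loss-of-heterozygosity runs longer than 15 Mb that do not
  span an entire chromosome (Abkevich-style count).
* **LST** — large-scale state transitions: chromosome-arm breakpoints
  between two segments each at least 10 Mb long, after smoothing away
  segments shorter than 3 Mb (Popova-style count).
* **ntAI** — allelic-imbalance runs that reach a telomere without
  crossing the centromere (Birkbak-style count).
* **HRD sum** — the sum of the three, the combined HRD score.

Beyond the three canonical scores, :func:`gi_parameter_vector` evaluates a
configurable catalogue of genomic-instability (GI) parameters — counts and
percent-of-genome statistics per event class (LOH / loss / gain / allelic
imbalance) at several length thresholds — yielding the 28-value GI layer
used by the response classifier.

Event-state conventions (on a segment with total copy number ``t`` and
minor-allele copy number ``m``):

* LOH: ``m == 0`` and ``t >= 1`` (homozygous deletions are *loss*, not LOH)
* loss: ``t < 2``;  gain: ``t > 2``
* allelic imbalance: ``m != t - m``

Runs are maximal stretches of contiguous segments (no base-pair gap)
sharing the event state; run length is measured after merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from .genome import GenomeLayout, Segment, SegmentProfile, merge_adjacent_equal

MB = 1_000_000

EVENT_CLASSES: dict[str, Callable[[Segment], bool]] = {
    "loh": lambda s: s.minor_cn == 0 and s.total_cn >= 1,
    "loss": lambda s: s.total_cn < 2,
    "gain": lambda s: s.total_cn > 2,
    "allelic_imbalance": lambda s: s.minor_cn != s.total_cn - s.minor_cn,
}


@dataclass(frozen=True)
class ScarScores:
    """The three canonical HRD scar counts and their sum."""

    hrd_loh: int
    lst: int
    ntai: int

    @property
    def hrd_sum(self) -> int:
        return self.hrd_loh + self.lst + self.ntai


@dataclass(frozen=True)
class CatalogueEntry:
    id: str
    event_class: str  # key of EVENT_CLASSES
    statistic: str  # "count" | "pct_genome"
    min_length: int  # bp

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.statistic not in ("count", "pct_genome"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class ScarCatalogue:
    """An ordered catalogue of GI parameters to evaluate per sample.

    ``include_scar_scores`` appends the hrd_loh/lst/ntai/hrd_sum quartet.
    """

    entries: tuple[CatalogueEntry, ...]
    include_scar_scores: bool = True

    def __post_init__(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate catalogue ids")

    @property
    def ids(self) -> list[str]:
        ids = [e.id for e in self.entries]
        if self.include_scar_scores:
            ids += ["hrd_loh", "lst", "ntai", "hrd_sum"]
        return ids


def default_catalogue(scale: int = MB) -> ScarCatalogue:
    """The default 28-parameter GI catalogue.

    {count, pct_genome} x {LOH, loss, gain, allelic imbalance} x
    {>3, >10, >15 Mb} = 24 entries, plus the four scar scores.  ``scale``
    is bp per Mb and exists so the kilobase-scaled test genome can reuse
    the catalogue with proportional thresholds.
    """
    entries = []
    for cls in ("loh", "loss", "gain", "allelic_imbalance"):
        for stat in ("count", "pct_genome"):
            for thr in (3, 10, 15):
                entries.append(
                    CatalogueEntry(f"{cls}_{stat}_gt{thr}mb", cls, stat, thr * scale)
                )
    return ScarCatalogue(tuple(entries), include_scar_scores=True)


# ---------------------------------------------------------------------------
# run extraction

def event_runs(
    profile: SegmentProfile, chrom: str, predicate: Callable[[Segment], bool]
) -> list[tuple[int, int]]:
    """Maximal (start, end) runs of contiguous segments satisfying *predicate*.

    Contiguity means no base-pair gap between consecutive qualifying
    segments; a gap (or a non-qualifying segment) breaks the run.
    """
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    for seg in profile.by_chromosome(chrom):
        if predicate(seg):
            if cur is not None and seg.start == cur[1] + 1:
                cur = (cur[0], seg.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (seg.start, seg.end)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    return runs


def _run_length(run: tuple[int, int]) -> int:
    return run[1] - run[0] + 1


# ---------------------------------------------------------------------------
# catalogue statistics

def loh_events(
    profile: SegmentProfile, layout: GenomeLayout, min_length: int = 15 * MB
) -> int:
    """Number of LOH runs strictly longer than *min_length*."""
    return _class_event_count(profile, layout, "loh", min_length)


def _class_event_count(
    profile: SegmentProfile, layout: GenomeLayout, event_class: str, min_length: int
) -> int:
    pred = EVENT_CLASSES[event_class]
    return sum(
        1
        for chrom in layout
        for run in event_runs(profile, chrom.name, pred)
        if _run_length(run) > min_length
    )


def percent_genome_altered(
    profile: SegmentProfile,
    layout: GenomeLayout,
    event_class: str,
    min_length: int = 15 * MB,
) -> float:
    """Fraction of the genome covered by qualifying runs (in [0, 1])."""
    pred = EVENT_CLASSES[event_class]
    covered = sum(
        _run_length(run)
        for chrom in layout
        for run in event_runs(profile, chrom.name, pred)
        if _run_length(run) > min_length
    )
    return covered / layout.total_length


# ---------------------------------------------------------------------------
# canonical scar scores

def hrd_loh_score(
    profile: SegmentProfile, layout: GenomeLayout, min_length: int = 15 * MB
) -> int:
    """LOH runs > *min_length* that do not span an entire chromosome."""
    count = 0
    for chrom in layout:
        for run in event_runs(profile, chrom.name, EVENT_CLASSES["loh"]):
            whole = run[0] == 1 and run[1] == chrom.length
            if _run_length(run) > min_length and not whole:
                count += 1
    return count


def lst_score(
    profile: SegmentProfile,
    layout: GenomeLayout,
    min_flank: int = 10 * MB,
    smooth_below: int = 3 * MB,
) -> int:
    """Large-scale transitions.

    Per chromosome arm (split at the centromere midpoint; segments
    overlapping the midpoint are truncated at the split): segments shorter
    than *smooth_below* are removed, smallest first, re-merging flanking
    segments with equal allele state across the vacated gap; a breakpoint
    between two consecutive remaining segments of different state counts
    when both are at least *min_flank* long and their gap is smaller than
    *smooth_below*.
    """
    count = 0
    for chrom in layout:
        mid = chrom.cen_mid
        arms: tuple[list[Segment], list[Segment]] = ([], [])
        for seg in profile.by_chromosome(chrom.name):
            if seg.end <= mid:
                arms[0].append(seg)
            elif seg.start > mid:
                arms[1].append(seg)
            else:  # straddles the split: truncate into both arms
                arms[0].append(Segment(seg.chrom, seg.start, mid, seg.total_cn, seg.minor_cn))
                arms[1].append(Segment(seg.chrom, mid + 1, seg.end, seg.total_cn, seg.minor_cn))
        for arm in arms:
            count += _lst_on_arm(arm, min_flank, smooth_below)
    return count


def _lst_on_arm(segments: list[Segment], min_flank: int, smooth_below: int) -> int:
    segs = _smooth(merge_adjacent_equal(segments), smooth_below)
    count = 0
    for left, right in zip(segs, segs[1:]):
        gap = right.start - left.end - 1
        if (
            (left.total_cn, left.minor_cn) != (right.total_cn, right.minor_cn)
            and left.length >= min_flank
            and right.length >= min_flank
            and gap < smooth_below
        ):
            count += 1
    return count


def _smooth(segments: list[Segment], smooth_below: int) -> list[Segment]:
    """Drop sub-threshold segments (smallest first), merging equal-state
    neighbours across the vacated gap."""
    segs = list(segments)
    while len(segs) > 1:
        shortest = min(range(len(segs)), key=lambda i: (segs[i].length, i))
        if segs[shortest].length >= smooth_below:
            break
        del segs[shortest]
        i = shortest - 1
        if 0 <= i < len(segs) - 1:
            a, b = segs[i], segs[i + 1]
            if (a.total_cn, a.minor_cn) == (b.total_cn, b.minor_cn):
                segs[i : i + 2] = [Segment(a.chrom, a.start, b.end, a.total_cn, a.minor_cn)]
    return segs


def ntai_score(
    profile: SegmentProfile, layout: GenomeLayout, min_length: int = MB
) -> int:
    """Telomeric allelic imbalances.

    Counts allelic-imbalance runs longer than *min_length* that touch a
    chromosome end (start at bp 1 or end at the chromosome length) and do
    not overlap the centromere interval.
    """
    count = 0
    pred = EVENT_CLASSES["allelic_imbalance"]
    for chrom in layout:
        for run in event_runs(profile, chrom.name, pred):
            telomeric = run[0] == 1 or run[1] == chrom.length
            crosses_cen = run[0] <= chrom.cen_end and run[1] >= chrom.cen_start
            if telomeric and not crosses_cen and _run_length(run) > min_length:
                count += 1
    return count


def scar_scores(
    profile: SegmentProfile,
    layout: GenomeLayout,
    loh_min: int = 15 * MB,
    lst_min_flank: int = 10 * MB,
    lst_smooth: int = 3 * MB,
    ntai_min: int = MB,
) -> ScarScores:
    """The canonical HRD scar triple (and, via the property, their sum)."""
    return ScarScores(
        hrd_loh=hrd_loh_score(profile, layout, loh_min),
        lst=lst_score(profile, layout, lst_min_flank, lst_smooth),
        ntai=ntai_score(profile, layout, ntai_min),
    )


def gi_parameter_vector(
    profile: SegmentProfile,
    layout: GenomeLayout,
    catalogue: ScarCatalogue | None = None,
    scale: int = MB,
) -> dict[str, float]:
    """Evaluate the GI parameter catalogue for one sample.

    Returns an ordered mapping with exactly the catalogue's ids.  ``scale``
    (bp per Mb) propagates to the canonical scar-score thresholds so the
    vector stays meaningful on rescaled test genomes.
    """
    if catalogue is None:
        catalogue = default_catalogue(scale)
    out: dict[str, float] = {}
    for entry in catalogue.entries:
        if entry.statistic == "count":
            out[entry.id] = float(
                _class_event_count(profile, layout, entry.event_class, entry.min_length)
            )
        else:
            out[entry.id] = percent_genome_altered(
                profile, layout, entry.event_class, entry.min_length
            )
    if catalogue.include_scar_scores:
        ss = scar_scores(
            profile, layout,
            loh_min=15 * scale, lst_min_flank=10 * scale,
            lst_smooth=3 * scale, ntai_min=scale,
        )
        out["hrd_loh"] = float(ss.hrd_loh)
        out["lst"] = float(ss.lst)
        out["ntai"] = float(ss.ntai)
        out["hrd_sum"] = float(ss.hrd_sum)
    return out


def gi_matrix(
    profiles: Iterable[SegmentProfile],
    layout: GenomeLayout,
    catalogue: ScarCatalogue | None = None,
    scale: int = MB,
):
    """GI parameter vectors for many samples as a FeatureMatrix."""
    import pandas as pd

    from .io import FeatureMatrix

    cols = {
        p.sample_id: gi_parameter_vector(p, layout, catalogue, scale) for p in profiles
    }
    return FeatureMatrix(pd.DataFrame(cols))
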