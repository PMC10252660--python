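"""Genome layout and allele-specific copy-number segment containers.

Coordinates are 1-based, fully closed intervals (SEG convention), so a
segment spanning ``[start, end]`` has length ``end - start + 1`` base
pairs.  All scar statistics in :mod:`scarface.scars` inherit this
convention, which makes length thresholds such as ">15 Mb" unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file or record violates its documented contract."""


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with its centromere interval (1-based, closed)."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FormatError(f"chromosome {self.name}: non-positive length {self.length}")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise FormatError(
                f"chromosome {self.name}: centromere [{self.cen_start}, {self.cen_end}] "
                f"not strictly inside (0, {self.length})"
            )

    @property
    def cen_mid(self) -> int:
        """Midpoint of the centromere interval; the arm split point."""
        return (self.cen_start + self.cen_end) // 2


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes defining arms and telomeres for scar statistics."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names in layout")

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def mini_genome(scale: int = 1_000_000) -> GenomeLayout:
    """The 3-chromosome test genome (240 Mb total at the default scale).

    Chromosomes of 100/80/60 Mb with centromeres at 45-50, 38-40 and
    28-30 Mb.  ``scale`` rescales every coordinate; the scar statistics
    are coordinate-scale-free, so a kilobase-scaled copy (``scale=1000``)
    supports exhaustive per-base-pair oracles in tests.
    """
    mk = lambda name, ln, cs, ce: Chromosome(name, ln * scale, cs * scale, ce * scale)
    return GenomeLayout(
        (
            mk("chr1", 100, 45, 50),
            mk("chr2", 80, 38, 40),
            mk("chr3", 60, 28, 30),
        )
    )


@dataclass(frozen=True)
class Segment:
    """An allele-specific copy-number segment.

    ``total_cn`` is the total copy number, ``minor_cn`` the copy number of
    the minor (less abundant) parental allele; by construction
    ``minor_cn <= total_cn - minor_cn``.
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise FormatError(f"segment {self.chrom}:{self.start}-{self.end}: negative copy number")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise FormatError(
                f"segment {self.chrom}:{self.start}-{self.end}: minor_cn {self.minor_cn} "
                f"exceeds the major allele (total {self.total_cn}); swap alleles first"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn


@dataclass
class SegmentProfile:
    """One sample's segments, sorted and non-overlapping per chromosome."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def validate(self, layout: GenomeLayout) -> "SegmentProfile":
        """Sort segments and enforce the profile invariants against *layout*."""
        self.segments.sort(key=lambda s: (_chrom_order(layout, s.chrom), s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if seg.chrom not in layout:
                raise FormatError(
                    f"sample {self.sample_id}: unknown chromosome {seg.chrom!r}"
                )
            chrom = layout[seg.chrom]
            if seg.start < 1 or seg.end > chrom.length:
                raise FormatError(
                    f"sample {self.sample_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"outside chromosome bounds [1, {chrom.length}]"
                )
            if prev is not None and prev.chrom == seg.chrom and seg.start <= prev.end:
                raise FormatError(
                    f"sample {self.sample_id}: overlapping segments on {seg.chrom}: "
                    f"[{prev.start}, {prev.end}] and [{seg.start}, {seg.end}]"
                )
            prev = seg
        return self

    def by_chromosome(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]


def _chrom_order(layout: GenomeLayout, name: str) -> int:
    for i, c in enumerate(layout):
        if c.name == name:
            return i
    return len(layout)


def normalize_minor_allele(
    chrom: str, start: int, end: int, total_cn: int, minor_cn: int
) -> Segment:
    """Build a segment, swapping the allele labels if ``minor_cn`` is the major.

    Upstream callers disagree on A/B allele order; a "minor" copy number
    larger than half the total is silently corrected with a logged warning.
    """
    if minor_cn > total_cn - minor_cn:
        logger.warning(
            "segment %s:%d-%d: minor_cn %d > major allele; swapping allele labels",
            chrom, start, end, minor_cn,
        )
        minor_cn = total_cn - minor_cn
    return Segment(chrom, start, end, total_cn, minor_cn)


def merge_adjacent_equal(segments: Iterable[Segment]) -> list[Segment]:
    """Merge contiguous segments with identical (total_cn, minor_cn) state.

    Segments must already be sorted within chromosome; only runs with no
    base-pair gap (``next.start == prev.end + 1``) merge.
    """
    out: list[Segment] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and out[-1].end + 1 == seg.start
            and out[-1].total_cn == seg.total_cn
            and out[-1].minor_cn == seg.minor_cn
        ):
            prev = out.pop()
            seg = Segment(seg.chrom, prev.start, seg.end, seg.total_cn, seg.minor_cn)
        out.append(seg)
    return out
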