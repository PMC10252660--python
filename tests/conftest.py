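import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scarface.genome import Segment, SegmentProfile, mini_genome

MB = 1_000_000
KB = 1_000


@pytest.fixture(scope="session")
def layout_mb():
    """3-chromosome mini-genome at megabase scale (240 Mb total)."""
    return mini_genome()


@pytest.fixture(scope="session")
def layout_kb():
    """Kilobase-scaled mini-genome (240 kb) for per-bp oracle sweeps."""
    return mini_genome(scale=KB)


@pytest.fixture(scope="session")
def worked_profile(layout_mb):
    """Hand-engineered profile with exactly one qualifying event per scar
    type: one HRD-LOH run (chr1), one LST breakpoint (chr2), one
    telomeric AI run (chr3)."""
    segs = [
        Segment("chr1", 1, 58 * MB, 2, 1),
        Segment("chr1", 58 * MB + 1, 61 * MB, 3, 1),
        Segment("chr1", 61 * MB + 1, 77 * MB, 2, 0),  # 16 Mb interior LOH
        Segment("chr1", 77 * MB + 1, 80 * MB, 3, 1),
        Segment("chr1", 80 * MB + 1, 100 * MB, 2, 1),
        Segment("chr2", 1, 20 * MB, 2, 1),
        Segment("chr2", 20 * MB + 1, 38 * MB, 3, 1),  # 20|18 Mb transition
        Segment("chr2", 38 * MB + 1, 80 * MB, 2, 1),
        Segment("chr3", 1, 10 * MB, 2, 0),
        Segment("chr3", 10 * MB + 1, 13 * MB, 1, 0),  # 13 Mb telomeric AI (LOH run < 15 Mb)
        Segment("chr3", 13 * MB + 1, 60 * MB, 2, 1),
    ]
    return SegmentProfile("worked", segs).validate(layout_mb)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
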