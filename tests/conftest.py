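import numpy as np
import pandas as pd
import pytest

from wgdtx.segments import Segment, SegmentProfile


def make_profile(segs, purity=0.8, sample_id="S"):
    """Profile from (chrom, start, end, major, minor) tuples."""
    return SegmentProfile(
        sample_id, tuple(Segment(*s) for s in segs), purity
    )


@pytest.fixture
def diploid_profile():
    return make_profile(
        [("1", 1, 50_000_000, 1, 1), ("2", 1, 40_000_000, 1, 1)]
    )


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "3"],
            "start": [100, 2_000_000, 500, 10],
            "end": [10_099, 2_010_000, 10_499, 2_009],
            "gene_id": ["gA", "gB", "gC", "gD"],
        }
    )


def brute_force_mcn_fraction(profile):
    """Per-basepair scan oracle for the MCN>=2 fraction."""
    qual = 0
    total = 0
    for seg in profile.segments:
        for _bp in range(seg.start, seg.end + 1):
            total += 1
            if seg.major_cn >= 2:
                qual += 1
    return qual / total


@pytest.fixture
def rng():
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(20240718)
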