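import numpy as np
import pandas as pd
import pytest

import hrdscan as h
from hrdscan.simulate import ASCNProfile

MB = 1_000_000


@pytest.fixture(scope="session")
def hg19():
    return h.GenomeBuild.hg19()


@pytest.fixture(scope="session")
def toy_build():
    """4 equal chromosomes of 120 Mb, centromere [58, 62) Mb (whole-Mb bounds)."""
    return h.make_toy_build(4, 120e6, 0.5, cen_width=4 * MB)


@pytest.fixture(scope="session")
def one_chrom_build():
    """Single 100 Mb chromosome with centromere [48.5, 51.5) Mb."""
    return h.make_toy_build(1, 100e6, 0.5)


def profile_from_segments(segments, sample_id="t") -> ASCNProfile:
    """Build a profile from (chrom, start, end, maj, min) tuples."""
    return ASCNProfile(
        sample_id,
        pd.DataFrame(segments, columns=["chrom", "start", "end", "cn_major", "cn_minor"]),
    )


def tile_chromosome(build, chrom, states, sample_id="t"):
    """Tile one chromosome with (end_bp, maj, min) state changes; other
    chromosomes of the build are filled (1, 1)."""
    rows = []
    cursor = 0
    for end, maj, mino in states:
        rows.append((chrom, cursor, end, maj, mino))
        cursor = end
    c = build[chrom]
    if cursor < c.length:
        rows.append((chrom, cursor, c.length, 1, 1))
    for other in build:
        if other.name != chrom:
            rows.append((other.name, 0, other.length, 1, 1))
    return profile_from_segments(rows, sample_id)


STATE_POOL = [(1, 1), (1, 1), (1, 0), (2, 1), (2, 0), (2, 2), (3, 1), (0, 0), (3, 0)]


def random_profile(build, rng, max_breaks=6, sample_id="r") -> ASCNProfile:
    """Random Mb-aligned profile with states from a mixed pool."""
    rows = []
    for c in build:
        k = int(rng.integers(0, max_breaks + 1))
        n_mb = c.length // MB
        cuts = np.sort(rng.choice(np.arange(1, n_mb), size=k, replace=False)) * MB
        bounds = [0, *cuts.tolist(), c.length]
        prev = None
        for s, e in zip(bounds, bounds[1:]):
            state = STATE_POOL[int(rng.integers(len(STATE_POOL)))]
            while state == prev:  # keep segments genuinely distinct
                state = STATE_POOL[int(rng.integers(len(STATE_POOL)))]
            rows.append((c.name, s, e, *state))
            prev = state
    return profile_from_segments(rows, sample_id)
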