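"""Genomic-scar metrics: LOH, TAI, LST and their HRD sum.

The three counts are computed from a sample's allele-specific copy-number
profile (integer major/minor copies per segment) against a genome build:

* **LOH** — number of regions with loss of one parental allele
  (``cn_minor == 0`` with ``cn_major >= 1``) longer than 15 Mb but shorter
  than the whole chromosome.  Adjacent segments sharing the LOH state are
  merged before measuring, so a (1,0) run abutting a (2,0) run counts once.
* **TAI** — number of allelically imbalanced regions
  (``cn_major != cn_minor``, merged the same way) that extend to one of the
  subtelomeres (chromosome terminus) but do not cross the centromere.  A
  region spanning the whole chromosome necessarily crosses the centromere
  and never counts.
* **LST** — number of copy-number breakpoints between adjacent regions of at
  least 10 Mb, counted per chromosome arm after a smoothing step that
  iteratively removes regions shorter than 3 Mb (flanks with identical state
  merge across the gap; unequal flanks split the gap evenly).

The aggregate HRD score is the plain sum LOH + TAI + LST, dichotomized at a
clinical cut-off of 42 (inclusive).

Length thresholds follow the definitions literally: LOH strictly > 15 Mb
("longer than"), LST flanks >= 10 Mb ("at least"), smoothing removes < 3 Mb
("shorter than").  All three are configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBuild

__all__ = [
    "ScarScores",
    "score_loh",
    "score_tai",
    "score_lst",
    "score_sample",
    "classify_hrd",
    "LOH_MIN_MB",
    "LST_FLANK_MB",
    "LST_FILTER_MB",
    "HRD_CUTOFF",
]

LOH_MIN_MB = 15.0
LST_FLANK_MB = 10.0
LST_FILTER_MB = 3.0
HRD_CUTOFF = 42

_MB = 1e6


@dataclass(frozen=True)
class ScarScores:
    """The (LOH, TAI, LST, HRD-sum) quadruple for one sample."""

    sample_id: str
    loh: int
    tai: int
    lst: int

    @property
    def hrd_sum(self) -> int:
        return self.loh + self.tai + self.lst


def _chrom_arrays(profile, chrom: str):
    grp = profile.frame[profile.frame["chrom"] == chrom]
    return (
        grp["start"].to_numpy(dtype=np.int64),
        grp["end"].to_numpy(dtype=np.int64),
        grp["cn_major"].to_numpy(dtype=np.int64),
        grp["cn_minor"].to_numpy(dtype=np.int64),
    )


def _merge_state_runs(start, end, state) -> list[tuple[int, int]]:
    """Merge maximal runs of consecutive state-true segments into intervals.

    Segments tile the chromosome, so consecutive rows are always adjacent.
    """
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(state)
    while i < n:
        if state[i]:
            j = i
            while j + 1 < n and state[j + 1]:
                j += 1
            runs.append((int(start[i]), int(end[j])))
            i = j + 1
        else:
            i += 1
    return runs


def score_loh(profile, build: GenomeBuild, min_mb: float = LOH_MIN_MB) -> int:
    """Count merged LOH regions strictly longer than ``min_mb`` Mb but
    strictly shorter than their chromosome."""
    count = 0
    for chrom in profile.frame["chrom"].unique():
        start, end, maj, mino = _chrom_arrays(profile, chrom)
        state = (mino == 0) & (maj >= 1)
        chrom_len = build[str(chrom)].length
        for s, e in _merge_state_runs(start, end, state):
            length = e - s
            if length > min_mb * _MB and length < chrom_len:
                count += 1
    return count


def score_tai(profile, build: GenomeBuild, tai_min_mb: float = 0.0) -> int:
    """Count merged allelic-imbalance regions reaching a chromosome terminus
    without overlapping the centromere.

    ``tai_min_mb`` adds an optional minimum-length floor (default 0: the
    definition states none).
    """
    count = 0
    for chrom in profile.frame["chrom"].unique():
        c = build[str(chrom)]
        start, end, maj, mino = _chrom_arrays(profile, chrom)
        state = maj != mino
        for s, e in _merge_state_runs(start, end, state):
            touches_terminus = s == 0 or e == c.length
            overlaps_cen = s < c.cen_end and e > c.cen_start
            whole = s == 0 and e == c.length
            if (
                touches_terminus
                and not overlaps_cen
                and not whole
                and (e - s) >= tai_min_mb * _MB
            ):
                count += 1
    return count


def _merge_equal(segs: list[list]) -> list[list]:
    """Merge adjacent segments with identical (major, minor) state."""
    out: list[list] = []
    for seg in segs:
        if out and out[-1][2] == seg[2] and out[-1][3] == seg[3]:
            out[-1][1] = seg[1]
        else:
            out.append(list(seg))
    return out


def _smooth_arm(segs: list[list], filter_bp: float) -> list[list]:
    """Iteratively delete segments shorter than ``filter_bp``.

    The shortest qualifying segment is removed first (leftmost on ties).  If
    the flanking segments then share a state they merge across the gap;
    otherwise each is extended to the integer midpoint of the deleted
    interval.  An edge segment's single neighbour absorbs the whole gap.
    Repeats until nothing is shorter than the floor or one segment remains.
    """
    segs = _merge_equal(segs)
    while len(segs) > 1:
        lengths = [s[1] - s[0] for s in segs]
        candidates = [i for i, ln in enumerate(lengths) if ln < filter_bp]
        if not candidates:
            break
        idx = min(candidates, key=lambda i: (lengths[i], i))
        s, e = segs[idx][0], segs[idx][1]
        if idx == 0:
            segs[1][0] = s
            del segs[0]
        elif idx == len(segs) - 1:
            segs[-2][1] = e
            del segs[-1]
        else:
            left, right = segs[idx - 1], segs[idx + 1]
            if left[2] == right[2] and left[3] == right[3]:
                left[1] = right[1]
                del segs[idx : idx + 2]
            else:
                mid = (s + e) // 2
                left[1] = mid
                right[0] = mid
                del segs[idx]
        segs = _merge_equal(segs)
    return segs


def _arm_segments(profile, chrom: str, arm_start: int, arm_end: int) -> list[list]:
    start, end, maj, mino = _chrom_arrays(profile, chrom)
    segs: list[list] = []
    for s, e, a, b in zip(start, end, maj, mino):
        s2, e2 = max(int(s), arm_start), min(int(e), arm_end)
        if s2 < e2:
            segs.append([s2, e2, int(a), int(b)])
    return segs


def score_lst(
    profile,
    build: GenomeBuild,
    flank_mb: float = LST_FLANK_MB,
    filter_mb: float = LST_FILTER_MB,
) -> int:
    """Count large-scale state transitions per chromosome arm.

    Segments are split at the centromere (a state change across the
    centromere is never a breakpoint); after smoothing away sub-``filter_mb``
    segments, a breakpoint counts when both flanking segments are at least
    ``flank_mb`` long and differ in (major, minor) state.
    """
    count = 0
    for chrom in profile.frame["chrom"].unique():
        c = build[str(chrom)]
        for arm_start, arm_end, _arm in c.arms:
            segs = _arm_segments(profile, str(chrom), arm_start, arm_end)
            if len(segs) < 2:
                continue
            segs = _smooth_arm(segs, filter_mb * _MB)
            for left, right in zip(segs, segs[1:]):
                if (left[2], left[3]) == (right[2], right[3]):
                    continue  # defensive; smoothing merges equal neighbours
                if (
                    left[1] - left[0] >= flank_mb * _MB
                    and right[1] - right[0] >= flank_mb * _MB
                ):
                    count += 1
    return count


def score_sample(
    profile,
    build: GenomeBuild,
    loh_min_mb: float = LOH_MIN_MB,
    tai_min_mb: float = 0.0,
    lst_flank_mb: float = LST_FLANK_MB,
    lst_filter_mb: float = LST_FILTER_MB,
) -> ScarScores:
    """All three scar metrics for one profile; ``hrd_sum`` is their sum."""
    return ScarScores(
        sample_id=profile.sample_id,
        loh=score_loh(profile, build, min_mb=loh_min_mb),
        tai=score_tai(profile, build, tai_min_mb=tai_min_mb),
        lst=score_lst(profile, build, flank_mb=lst_flank_mb, filter_mb=lst_filter_mb),
    )


def classify_hrd(scores: ScarScores, cutoff: int = HRD_CUTOFF) -> str:
    """Dichotomize the HRD sum: ``"positive"`` iff ``hrd_sum >= cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return "positive" if scores.hrd_sum >= cutoff else "negative"
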