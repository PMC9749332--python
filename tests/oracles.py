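"""Independent brute-force oracles used only by the test suite.

Scar oracles paint per-bin state vectors (bin size divides every coordinate
used in the tests) and count runs/breakpoints directly; the segmentation
oracle recomputes the optimal partition with directly accumulated segment
costs; the ranking oracles count pairs / integrate precision-recall steps
explicitly.  None of them share code with the package implementations.
"""

from __future__ import annotations

import numpy as np

MB = 1_000_000
RES = 500_000  # bin size, bp


def paint_chromosome(profile, chrom, length):
    """Per-bin (major, minor) state vectors for one chromosome."""
    n_bins = length // RES
    maj = np.full(n_bins, -1, dtype=int)
    mino = np.full(n_bins, -1, dtype=int)
    grp = profile.frame[profile.frame["chrom"] == chrom]
    for row in grp.itertuples():
        b0, b1 = int(row.start) // RES, int(row.end) // RES
        maj[b0:b1] = row.cn_major
        mino[b0:b1] = row.cn_minor
    assert (maj >= 0).all(), "profile does not tile the chromosome"
    return maj, mino


def _runs(mask):
    """(start_bin, end_bin) of maximal True runs."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j + 1))
            i = j + 2
        else:
            i += 1
    return out


def loh_oracle(profile, build, min_mb=15):
    count = 0
    for c in build:
        maj, mino = paint_chromosome(profile, c.name, c.length)
        for b0, b1 in _runs((mino == 0) & (maj >= 1)):
            length = (b1 - b0) * RES
            if length > min_mb * MB and length < c.length:
                count += 1
    return count


def tai_oracle(profile, build):
    count = 0
    for c in build:
        maj, mino = paint_chromosome(profile, c.name, c.length)
        n_bins = len(maj)
        cen0, cen1 = c.cen_start // RES, c.cen_end // RES
        for b0, b1 in _runs(maj != mino):
            telomeric = b0 == 0 or b1 == n_bins
            crosses_cen = b0 < cen1 and b1 > cen0
            whole = b0 == 0 and b1 == n_bins
            if telomeric and not crosses_cen and not whole:
                count += 1
    return count


def lst_oracle(profile, build, flank_mb=10, filter_mb=3):
    count = 0
    for c in build:
        maj, mino = paint_chromosome(profile, c.name, c.length)
        for a0, a1 in ((0, c.cen_start), (c.cen_end, c.length)):
            # run-length encode the arm's bin vector into bp segments
            segs = []
            for b in range(a0 // RES, a1 // RES):
                state = (int(maj[b]), int(mino[b]))
                if segs and segs[-1][2] == state:
                    segs[-1][1] += RES
                else:
                    segs.append([b * RES, (b + 1) * RES, state])
            count += _lst_arm(segs, flank_mb * MB, filter_mb * MB)
    return count


def _lst_arm(segs, flank_bp, filter_bp):
    segs = [list(s) for s in segs]
    while True:
        # merge adjacent equal states
        merged = []
        for s in segs:
            if merged and merged[-1][2] == s[2]:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        segs = merged
        if len(segs) <= 1:
            break
        shortest = None
        for i, s in enumerate(segs):
            if s[1] - s[0] < filter_bp:
                if shortest is None or s[1] - s[0] < segs[shortest][1] - segs[shortest][0]:
                    shortest = i
        if shortest is None:
            break
        s = segs.pop(shortest)
        if shortest == 0:
            segs[0][0] = s[0]
        elif shortest == len(segs):
            segs[-1][1] = s[1]
        else:
            left, right = segs[shortest - 1], segs[shortest]
            if left[2] == right[2]:
                left[1] = right[1]
            else:
                mid = (s[0] + s[1]) // 2
                left[1] = mid
                right[0] = mid
    n = 0
    for left, right in zip(segs, segs[1:]):
        if left[2] != right[2] and left[1] - left[0] >= flank_bp and right[1] - right[0] >= flank_bp:
            n += 1
    return n


# ---------------------------------------------------------------------------
# segmentation oracle: optimal partition with directly accumulated costs

def naive_optimal_partition(lrr, folded, het, penalty):
    """Changepoint start indices minimizing SSE + penalty * changepoints.

    Scalar backward accumulation of segment costs; no shared code with the
    package's cumulative-sum kernel.
    """
    n = len(lrr)
    best = [0.0] * (n + 1)
    prev = [0] * (n + 1)
    best[0] = -penalty
    for j in range(1, n + 1):
        s1 = s2 = 0.0
        hb1 = hb2 = 0.0
        hn = 0
        best_v, best_i = None, 0
        for i in range(j - 1, -1, -1):
            x = lrr[i]
            s1 += x
            s2 += x * x
            m = j - i
            cost = s2 - s1 * s1 / m
            if het[i]:
                f = folded[i]
                hb1 += f
                hb2 += f * f
                hn += 1
            if hn > 0:
                cost += hb2 - hb1 * hb1 / hn
            v = best[i] + penalty + max(cost, 0.0)
            if best_v is None or v < best_v:
                best_v, best_i = v, i
        best[j] = best_v
        prev[j] = best_i
    starts = []
    j = n
    while j > 0:
        starts.append(prev[j])
        j = prev[j]
    return starts[::-1]


def enumerate_optimal_partition(lrr, folded, het, penalty):
    """Full enumeration over all changepoint subsets (tiny n only)."""
    from itertools import combinations

    n = len(lrr)

    def seg_cost(i, j):
        x = lrr[i:j]
        c = float(((x - x.mean()) ** 2).sum())
        hb = folded[i:j][het[i:j]]
        if len(hb):
            c += float(((hb - hb.mean()) ** 2).sum())
        return c

    best_v, best_starts = None, None
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            v = penalty * k
            for i, j in zip(bounds, bounds[1:]):
                v += seg_cost(i, j)
            if best_v is None or v < best_v - 1e-12:
                best_v, best_starts = v, bounds[:-1]
    return list(best_starts)


# ---------------------------------------------------------------------------
# ranking oracles

def auroc_pairs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                num += 1.0
            elif x == y:
                num += 0.5
    return num / (len(pos) * len(neg))


def average_precision_steps(scores, labels):
    """Step integration: mean precision at the rank of each positive
    (descending score order; assumes tie-free scores)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores)
    lab = labels[order]
    precisions = []
    tp = 0
    for k, is_pos in enumerate(lab, start=1):
        if is_pos:
            tp += 1
            precisions.append(tp / k)
    return float(np.mean(precisions))
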