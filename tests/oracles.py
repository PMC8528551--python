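"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and explicit arithmetic so
it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_smooth_once(x, width):
    """Centered renormalized moving average via explicit loops."""
    half = width // 2
    out = []
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out


def brute_extract_events(
    times,
    salience,
    smooth_dur=1.5,
    rt_offset=1.0,
    window=4.0,
    keep_frac=0.5,
    min_separation=0.5,
):
    """Reference salient-event extraction: triple boxcar, slope maxima,
    reaction-time offset, slope-scaled strength, top-fraction pruning.

    Returns a list of (onset, slope_peak, strength) sorted by onset.
    """
    times = list(map(float, times))
    dt = times[1] - times[0]
    width = max(int(round(smooth_dur / dt)), 1)
    if width % 2 == 0:
        width += 1
    x = list(map(float, salience))
    for _ in range(3):
        x = brute_smooth_once(x, width)
    slope = [(x[i] - x[i - 1]) / dt for i in range(1, len(x))]
    stimes = times[1:]

    # strict local maxima with leftmost-plateau rule, positive values only
    cands = []
    i = 1
    while i < len(slope) - 1:
        if slope[i] > slope[i - 1]:
            j = i
            while j + 1 < len(slope) and slope[j + 1] == slope[i]:
                j += 1
            if j < len(slope) - 1 and slope[j + 1] < slope[i]:
                if slope[i] > 1e-12:  # same numerical positivity floor
                    cands.append(i)
            i = j + 1
        else:
            i += 1

    # greedy thinning: tallest first, earlier index wins ties
    order = sorted(cands, key=lambda k: (-slope[k], k))
    kept = []
    for k in order:
        if all(abs(stimes[k] - stimes[j]) >= min_separation for j in kept):
            kept.append(k)
    kept.sort()

    pos = sorted(v for v in slope if v > 0)
    if pos:
        # linear-interpolated 75th percentile, matching numpy's default
        rank = 0.75 * (len(pos) - 1)
        lo = int(math.floor(rank))
        hi = min(lo + 1, len(pos) - 1)
        p75 = pos[lo] + (rank - lo) * (pos[hi] - pos[lo])
    else:
        p75 = 0.0

    events = []
    for k in kept:
        onset = max(stimes[k] - rt_offset, 0.0)
        best = 0.0
        found = False
        for t, v in zip(times, x):
            if onset < t < onset + window:
                found = True
                if v > best:
                    best = v
        peak_sal = best if found else 0.0
        events.append((onset, slope[k], slope[k] + peak_sal * p75))

    n_keep = math.ceil(keep_frac * len(events))
    ranked = sorted(events, key=lambda e: (-e[2], e[0]))[:n_keep]
    return sorted(ranked, key=lambda e: e[0])


def brute_auroc_mannwhitney(scores, labels):
    """AUROC as the normalized Mann-Whitney U statistic with tie credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_spectral_shape(y, freqs):
    """Direct evaluation of the four printed spectral-shape formulas."""
    y = [float(v) for v in y]
    f = [float(v) for v in freqs]
    psum = sum(v * v for v in y)
    msum = sum(y)
    br = sum(fi * vi * vi for fi, vi in zip(f, y)) / psum
    bw = sum(abs(fi - br) * vi for fi, vi in zip(f, y)) / msum
    ir = sum((y[k + 1] - y[k]) ** 2 for k in range(len(y) - 1)) / psum
    if min(y) <= 0:
        fl = 0.0
    else:
        fl = math.exp(sum(math.log(v) for v in y) / len(y)) / (msum / len(y))
    return br, bw, ir, fl


def brute_fisher_direction(X, y):
    """Closed-form Fisher direction from explicit class statistics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    s0 = (X0 - mu0).T @ (X0 - mu0)
    s1 = (X1 - mu1).T @ (X1 - mu1)
    sw = (s0 + s1) / (n0 + n1 - 2)
    return np.linalg.solve(sw, mu1 - mu0)
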