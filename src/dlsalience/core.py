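"""Shared numerical primitives: boxcar smoothing, slope-peak picking, ROC sweep.

These are deliberately small, explicit routines: the event definition used
throughout the package (triple moving average -> first-order difference ->
local maxima) is the analysis contract, so it lives in one place and both the
behavioral and the acoustic change-detection paths call the same code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation.

    Near the boundaries the window is clipped to the available samples and the
    weights renormalized, so a constant series stays exactly constant and the
    output range never exceeds the input range.
    """
    x = np.asarray(x, dtype=float)
    if width < 1:
        raise ValueError("boxcar width must be >= 1")
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def triple_boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Three passes of the centered boxcar (the standard smoothing here)."""
    out = np.asarray(x, dtype=float)
    for _ in range(3):
        out = boxcar_smooth(out, width)
    return out


def smoothing_width(duration_s: float, dt: float) -> int:
    """Odd sample count closest to ``duration_s`` at grid step ``dt``."""
    width = max(int(round(duration_s / dt)), 1)
    if width % 2 == 0:
        width += 1
    return width


def slope_series(smoothed: np.ndarray, dt: float) -> np.ndarray:
    """First-order difference scaled to units of 1/s.

    ``slope[i]`` corresponds to the step into sample ``i + 1`` and is stamped
    at the time of sample ``i + 1``.
    """
    return np.diff(np.asarray(smoothed, dtype=float)) / dt


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus resolve to their left edge.

    A run of equal values counts as one peak if the value immediately before
    the run and immediately after it are both strictly lower.  Boundary runs
    are never peaks.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    peaks = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def select_peaks(
    values: np.ndarray,
    times: np.ndarray,
    min_separation: float = 0.5,
    min_height: float = 0.0,
) -> np.ndarray:
    """Positive local maxima thinned to a minimum temporal separation.

    Candidates are ranked by height (ties broken toward the earlier peak) and
    kept greedily if no stronger peak within ``min_separation`` seconds has
    been kept already.  Returned indices are sorted by time.
    """
    idx = local_maxima(values)
    idx = idx[values[idx] > min_height]
    if idx.size == 0:
        return idx
    order = idx[np.lexsort((idx, -values[idx]))]
    kept: list[int] = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_separation for j in kept):
            kept.append(i)
    return np.asarray(sorted(kept), dtype=int)


def greedy_match(a: np.ndarray, b: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """One-to-one nearest-first matching of two sorted onset lists.

    All candidate pairs within ``tol`` are ranked by absolute time difference
    and consumed greedily; each element of either list is matched at most once.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cand = [
        (abs(a[i] - b[j]), i, j)
        for i in range(a.size)
        for j in range(b.size)
        if abs(a[i] - b[j]) <= tol
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


@dataclass
class RocResult:
    """ROC curve from a descending threshold sweep plus its trapezoidal area."""

    thresholds: np.ndarray
    hit_rate: np.ndarray
    fa_rate: np.ndarray
    auroc: float


def sweep_roc(scores: np.ndarray, labels: np.ndarray, n_thresholds: int = 201) -> RocResult:
    """ROC by sweeping ``n_thresholds`` levels across the score range.

    A sample counts as a detection when its score exceeds the threshold
    strictly; the sweep is augmented with sentinel points so the curve always
    spans (0, 0) to (1, 1).  Ties in the scores fall between consecutive
    thresholds and are traversed by the trapezoid, which is equivalent to
    averaging over the tie group.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("labels must contain both classes")
    lo, hi = scores.min(), scores.max()
    span = hi - lo if hi > lo else 1.0
    thresholds = np.linspace(hi + 1e-9 * span, lo - 1e-9 * span, n_thresholds)
    hit = np.array([(pos > th).mean() for th in thresholds])
    fa = np.array([(neg > th).mean() for th in thresholds])
    auroc = float(np.trapezoid(hit, fa))
    return RocResult(thresholds=thresholds, hit_rate=hit, fa_rate=fa, auroc=auroc)
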