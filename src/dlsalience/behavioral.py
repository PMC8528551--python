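"""From attention traces to behavioral salience, salient events and agreement.

The central object is the average behavioral salience of a scene: the
fraction of listeners attending to it at each instant, pooled over subjects
and opposing scenes.  Salient events are peaks in the slope of that curve
(after triple moving-average smoothing), shifted back by a nominal 1 s
reaction time.  The module also provides the quality-control filter on
switching rates, subject-wise F-scores and reaction times against pooled
events, and the interobserver ROC analysis with its shuffled-chance
benchmark.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .synth import LEFT, RIGHT, ResponseTrace

__all__ = [
    "SalienceCurve",
    "SalientEvent",
    "AgreementResult",
    "QcResult",
    "map_response",
    "average_salience",
    "qc_filter",
    "extract_events",
    "extract_events_dataset",
    "reaction_times",
    "subject_fscore",
    "interobserver_auroc",
    "shuffled_chance_auroc",
    "curve_correlation",
    "toward_switch_times",
]


@dataclass
class SalienceCurve:
    """Average behavioral salience of one scene on a uniform time grid."""

    scene_id: str
    times: np.ndarray
    salience: np.ndarray
    n_subjects: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)


@dataclass(frozen=True)
class SalientEvent:
    """One extracted salient event: onset (s), slope-peak height, strength."""

    onset: float
    slope_peak: float
    strength: float


@dataclass
class AgreementResult:
    """Precision/recall/F-score, or an ROC-based agreement summary."""

    subject_id: str | None = None
    precision: float | None = None
    recall: float | None = None
    fscore: float | None = None
    auroc: float | None = None
    roc: core.RocResult | None = None
    hits: int = 0
    false_alarms: int = 0
    misses: int = 0


@dataclass
class QcResult:
    kept: list[ResponseTrace]
    flagged: list[ResponseTrace]
    excluded_subjects: list[str]
    rates: pd.DataFrame  # subject_id, trial_index, rate, flagged, excluded


def map_response(trace: ResponseTrace, scene: str) -> np.ndarray:
    """Binary attention indicator for one scene of a trial.

    ``scene`` is "left"/"right" or a scene id present in the trial.  The
    value is 1 where the cursor is on that scene's side and 0 elsewhere
    (center and the opposite scene are both counted as not listening).
    """
    if scene == "left" or scene == trace.left_scene_id:
        target = LEFT
    elif scene == "right" or scene == trace.right_scene_id:
        target = RIGHT
    else:
        raise ValueError(f"scene {scene!r} is not part of this trial")
    return (trace.labels == target).astype(float)


def toward_switch_times(times: np.ndarray, mapped: np.ndarray) -> np.ndarray:
    """Times at which a mapped binary series turns on (a switch toward the scene)."""
    mapped = np.asarray(mapped)
    idx = np.flatnonzero((mapped[1:] == 1) & (mapped[:-1] == 0)) + 1
    return np.asarray(times)[idx]


def average_salience(
    mapped_series: list[np.ndarray],
    dt: float = 0.1,
    scene_id: str = "",
) -> SalienceCurve:
    """Mean of mapped binary responses on the common time grid.

    Series of unequal length are truncated to the shortest one (with a
    warning); all series are assumed to share the grid step ``dt``.
    """
    if not mapped_series:
        raise ValueError("need at least one response to average")
    lengths = {len(s) for s in mapped_series}
    n = min(lengths)
    if len(lengths) > 1:
        warnings.warn("responses of unequal length; truncating to common support")
    stack = np.vstack([np.asarray(s, dtype=float)[:n] for s in mapped_series])
    return SalienceCurve(
        scene_id=scene_id,
        times=np.arange(n) * dt,
        salience=stack.mean(axis=0),
        n_subjects=np.full(n, stack.shape[0], dtype=int),
    )


def salience_by_scene(
    traces: list[ResponseTrace], dt: float = 0.1
) -> dict[str, SalienceCurve]:
    """Average behavioral salience for every scene appearing in the traces."""
    mapped: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        mapped.setdefault(tr.left_scene_id, []).append(map_response(tr, "left"))
        mapped.setdefault(tr.right_scene_id, []).append(map_response(tr, "right"))
    return {
        sid: average_salience(series, dt=dt, scene_id=sid)
        for sid, series in sorted(mapped.items())
    }


def qc_filter(
    traces: list[ResponseTrace],
    low: float = 0.025,
    high: float = 1.0,
    subject_frac: float = 0.5,
) -> QcResult:
    """Flag trials with outlier switching rates and drop outlier subjects.

    A trial is flagged when its switching rate falls outside [low, high]
    switches per second; a subject with more than ``subject_frac`` of their
    trials flagged is excluded entirely (all their trials removed).
    """
    rows = []
    for tr in traces:
        rate = tr.switching_rate()
        rows.append(
            {
                "subject_id": tr.subject_id,
                "trial_index": tr.trial_index,
                "rate": rate,
                "flagged": bool(rate < low or rate > high),
            }
        )
    table = pd.DataFrame(rows)
    excluded: list[str] = []
    if not table.empty:
        frac = table.groupby("subject_id")["flagged"].mean()
        excluded = sorted(frac.index[frac > subject_frac])
    table["excluded"] = table["subject_id"].isin(excluded) if not table.empty else []
    kept, flagged = [], []
    for tr, row in zip(traces, rows):
        if row["flagged"]:
            flagged.append(tr)
        if not row["flagged"] and tr.subject_id not in excluded:
            kept.append(tr)
    return QcResult(kept=kept, flagged=flagged, excluded_subjects=excluded, rates=table)


# ---------------------------------------------------------------------------
# salient event extraction
# ---------------------------------------------------------------------------


def _raw_events(
    curve: SalienceCurve,
    smooth_dur: float,
    rt_offset: float,
    window: float,
    min_separation: float,
) -> list[SalientEvent]:
    """All slope-peak events of one curve, before any strength pruning."""
    s = np.asarray(curve.salience, dtype=float)
    dt = curve.dt
    width = core.smoothing_width(smooth_dur, dt)
    if s.size < width + 2:
        raise ValueError("curve shorter than the smoothing support")
    smoothed = core.triple_boxcar(s, width)
    slope = core.slope_series(smoothed, dt)
    slope_times = curve.times[1:]
    # positivity at numerical precision: exactly-flat stretches of the curve
    # otherwise sprout 1e-16 "peaks" from convolution round-off
    peaks = core.select_peaks(
        slope, slope_times, min_separation=min_separation, min_height=1e-12
    )
    positive = slope[slope > 0]
    p75 = float(np.percentile(positive, 75)) if positive.size else 0.0
    events = []
    for j in peaks:
        onset = max(slope_times[j] - rt_offset, 0.0)
        in_win = (curve.times > onset) & (curve.times < onset + window)
        peak_sal = float(smoothed[in_win].max()) if in_win.any() else 0.0
        events.append(
            SalientEvent(
                onset=float(onset),
                slope_peak=float(slope[j]),
                strength=float(slope[j] + peak_sal * p75),
            )
        )
    return events


def _prune(events: list[SalientEvent], keep_frac: float) -> list[SalientEvent]:
    if not events or keep_frac >= 1.0:
        return sorted(events, key=lambda e: e.onset)
    n_keep = math.ceil(keep_frac * len(events))
    ranked = sorted(events, key=lambda e: (-e.strength, e.onset))
    return sorted(ranked[:n_keep], key=lambda e: e.onset)


def extract_events(
    curve: SalienceCurve,
    smooth_dur: float = 1.5,
    rt_offset: float = 1.0,
    window: float = 4.0,
    keep_frac: float = 0.5,
    min_separation: float = 0.5,
) -> list[SalientEvent]:
    """Salient events of one scene from its average behavioral salience.

    Pipeline: three 1.5 s moving averages, first-order difference, positive
    local slope maxima (0.5 s minimum separation), onset = peak time minus
    the 1 s reaction-time offset (clipped at zero).  Each event's strength is
    the slope-peak height plus the maximum salience within 4 s after onset
    scaled by the 75th percentile of the scene's positive slope values; the
    top ``keep_frac`` of events by strength survive.
    """
    return _prune(
        _raw_events(curve, smooth_dur, rt_offset, window, min_separation), keep_frac
    )


def extract_events_dataset(
    curves: dict[str, SalienceCurve],
    smooth_dur: float = 1.5,
    rt_offset: float = 1.0,
    window: float = 4.0,
    keep_frac: float = 0.5,
    min_separation: float = 0.5,
    pruning: str = "global",
) -> dict[str, list[SalientEvent]]:
    """Events for a whole scene set.

    With ``pruning="global"`` (the default) the strength ranking and the
    top-``keep_frac`` cut are applied to the pooled event list across scenes,
    so scenes with weak behavioral structure can legitimately end up with no
    events; ``pruning="per_scene"`` applies the cut within each scene.
    Strengths themselves are always per-scene quantities.
    """
    if pruning not in ("global", "per_scene"):
        raise ValueError("pruning must be 'global' or 'per_scene'")
    raw = {
        sid: _raw_events(curve, smooth_dur, rt_offset, window, min_separation)
        for sid, curve in curves.items()
    }
    if pruning == "per_scene":
        return {sid: _prune(ev, keep_frac) for sid, ev in raw.items()}
    pooled = [(ev.strength, sid, ev) for sid, evs in raw.items() for ev in evs]
    n_keep = math.ceil(keep_frac * len(pooled))
    pooled.sort(key=lambda item: (-item[0], item[1], item[2].onset))
    kept = pooled[:n_keep]
    out: dict[str, list[SalientEvent]] = {sid: [] for sid in curves}
    for _, sid, ev in kept:
        out[sid].append(ev)
    return {sid: sorted(evs, key=lambda e: e.onset) for sid, evs in out.items()}


# ---------------------------------------------------------------------------
# per-subject agreement
# ---------------------------------------------------------------------------


def reaction_times(
    trace: ResponseTrace,
    scene: str,
    reference_events: list[SalientEvent] | list[float],
    window: tuple[float, float] = (0.5, 1.5),
) -> list[float]:
    """Latencies of toward-scene switches following reference event onsets.

    A subject responded to an event if they first moved toward the scene
    between ``window[0]`` and ``window[1]`` seconds after its onset; events
    with no switch inside the window contribute no reaction time.
    """
    onsets = [e.onset if isinstance(e, SalientEvent) else float(e) for e in reference_events]
    switches = toward_switch_times(trace.times, map_response(trace, scene))
    rts = []
    for onset in onsets:
        in_win = switches[(switches >= onset + window[0]) & (switches <= onset + window[1])]
        if in_win.size:
            rts.append(float(in_win[0] - onset))
    return rts


def subject_fscore(
    subject_onsets: np.ndarray,
    reference_onsets: np.ndarray,
    tol: float = 1.0,
    floor: float = 1e-6,
    subject_id: str | None = None,
) -> AgreementResult:
    """Detection F-score of a subject's switches against reference events.

    Matches within ``tol`` seconds are hits (greedy nearest-first one-to-one
    matching); unmatched detections are false positives and unmatched
    references false negatives.  Precision and recall are floored before the
    harmonic mean so empty sets give an F-score near zero instead of NaN.
    """
    subject_onsets = np.asarray(subject_onsets, dtype=float)
    reference_onsets = np.asarray(reference_onsets, dtype=float)
    hits = len(core.greedy_match(subject_onsets, reference_onsets, tol))
    fp = subject_onsets.size - hits
    fn = reference_onsets.size - hits
    precision = max(hits / (hits + fp) if hits + fp else 0.0, floor)
    recall = max(hits / (hits + fn) if hits + fn else 0.0, floor)
    fscore = 2 * precision * recall / (precision + recall)
    return AgreementResult(
        subject_id=subject_id,
        precision=precision,
        recall=recall,
        fscore=fscore,
        hits=hits,
        false_alarms=fp,
        misses=fn,
    )


# ---------------------------------------------------------------------------
# interobserver agreement (ROC over 1 s segments)
# ---------------------------------------------------------------------------


def segment_starts(duration: float, seg_len: float = 1.0, hop: float = 0.25) -> np.ndarray:
    """Start times of 1 s segments with 75% overlap covering [0, duration]."""
    n = int(np.floor((duration - seg_len) / hop + 1e-9)) + 1
    return np.arange(max(n, 0)) * hop


def label_segments(starts: np.ndarray, onsets: np.ndarray, seg_len: float = 1.0) -> np.ndarray:
    """Binary segment labels: 1 iff an onset falls in [start, start + seg_len)."""
    onsets = np.sort(np.asarray(onsets, dtype=float))
    lo = np.searchsorted(onsets, starts, side="left")
    hi = np.searchsorted(onsets, starts + seg_len, side="left")
    return (hi > lo).astype(int)


def _switch_fraction(
    starts: np.ndarray, switch_lists: list[np.ndarray], seg_len: float
) -> np.ndarray:
    """Percentage of subjects with a toward-scene switch inside each segment."""
    counts = np.zeros(starts.size)
    for sw in switch_lists:
        sw = np.sort(np.asarray(sw, dtype=float))
        lo = np.searchsorted(sw, starts, side="left")
        hi = np.searchsorted(sw, starts + seg_len, side="left")
        counts += hi > lo
    return 100.0 * counts / max(len(switch_lists), 1)


def interobserver_auroc(
    responses_by_scene: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    events_by_scene: dict[str, list[SalientEvent]] | dict[str, np.ndarray],
    seg_len: float = 1.0,
    hop: float = 0.25,
    rt_offset: float = 1.0,
    n_thresholds: int = 201,
) -> AgreementResult:
    """Agreement between individual switch times and pooled salient events.

    ``responses_by_scene`` maps scene id to a list of ``(times, mapped)``
    pairs (one per subject response to that scene).  Scenes are divided into
    ``seg_len`` segments with ``1 - hop/seg_len`` overlap; the detection
    signal per segment is the percentage of subjects with a toward-scene
    switch inside it, and the label marks segments containing a pooled event
    onset.  Event onsets live in stimulus time (the extraction subtracts the
    nominal reaction time), so individual switches are shifted back by the
    same ``rt_offset`` before binning; without this the detection signal
    would be systematically one segment late relative to the labels.  The
    ROC is swept over the detection signal; scenes without events contribute
    only negative segments.
    """
    signals, labels = [], []
    for sid, responses in sorted(responses_by_scene.items()):
        if not responses:
            continue
        times = responses[0][0]
        duration = float(times[-1] - times[0] + times[1] - times[0])
        starts = segment_starts(duration, seg_len, hop)
        events = events_by_scene.get(sid, [])
        onsets = np.asarray(
            [e.onset if isinstance(e, SalientEvent) else float(e) for e in events]
        )
        labels.append(label_segments(starts, onsets, seg_len))
        switch_lists = [toward_switch_times(t, m) - rt_offset for t, m in responses]
        signals.append(_switch_fraction(starts, switch_lists, seg_len))
    signal = np.concatenate(signals)
    label = np.concatenate(labels)
    roc = core.sweep_roc(signal, label, n_thresholds=n_thresholds)
    return AgreementResult(auroc=roc.auroc, roc=roc)


def shuffled_chance_auroc(
    responses_by_scene: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    subsample_sizes: list[int],
    reps: int = 50,
    seed: int = 0,
    dt: float = 0.1,
    exclude_own: bool = True,
    **event_kw,
) -> pd.DataFrame:
    """Chance-level interobserver AUROC from shuffled response pools.

    For every (subsample size, repetition): each scene receives ``size``
    mapped responses drawn without replacement from the pooled responses of
    all subjects and scenes, and a chance event set is extracted from the
    average salience of that shuffled data.  The detection analysis is then
    performed exactly as in :func:`interobserver_auroc` — ``size`` of the
    scene's own responses against the events — so the resulting AUROC
    measures the agreement expected when events bear no relation to the
    behavior.  With ``exclude_own`` (default) a scene's own responses are
    left out of its shuffle pool; at small scene counts their residual
    alignment with the true events would otherwise leak real agreement into
    the benchmark.  Returns a tidy frame with columns size, rep, auroc.
    """
    rng = np.random.default_rng(seed)
    scene_of = []
    pool = []
    for sid, responses in sorted(responses_by_scene.items()):
        for _, mapped in responses:
            pool.append(np.asarray(mapped, dtype=float))
            scene_of.append(sid)
    n_min = min(s.size for s in pool)
    pool = [s[:n_min] for s in pool]
    scene_of = np.asarray(scene_of)
    rows = []
    for size in subsample_sizes:
        for rep in range(reps):
            curves: dict[str, SalienceCurve] = {}
            subsampled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
            for sid, responses in sorted(responses_by_scene.items()):
                if size > len(responses):
                    raise ValueError(
                        f"subsample size {size} exceeds the {len(responses)} "
                        f"responses of scene {sid!r}"
                    )
                allowed = (
                    np.flatnonzero(scene_of != sid) if exclude_own else np.arange(len(pool))
                )
                if size > allowed.size:
                    raise ValueError(f"subsample size {size} exceeds the shuffle pool")
                take = rng.choice(allowed, size=size, replace=False)
                curves[sid] = average_salience(
                    [pool[i] for i in take], dt=dt, scene_id=sid
                )
                keep = rng.choice(len(responses), size=size, replace=False)
                subsampled[sid] = [responses[i] for i in keep]
            events = extract_events_dataset(curves, **event_kw)
            res = interobserver_auroc(subsampled, events)
            rows.append({"size": size, "rep": rep, "auroc": res.auroc})
    return pd.DataFrame(rows)


def curve_correlation(curve_a: SalienceCurve, curve_b: SalienceCurve) -> float:
    """Sample Pearson correlation of two salience curves on their overlap.

    Returns NaN when either curve has zero variance over the common support.
    """
    n = min(curve_a.salience.size, curve_b.salience.size)
    a = curve_a.salience[:n]
    b = curve_b.salience[:n]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
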