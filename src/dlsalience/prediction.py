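"""Acoustic prediction of behaviorally defined salient events.

Each acoustic feature nominates its own candidate events (peaks in the slope
of the z-scored series, using the same triple moving-average smoothing as the
behavioral extraction).  Scenes are split into 1 s segments with 0.75 s
overlap; a segment is positive when a reference event onset falls inside it,
and each feature's prediction for a segment is whether it nominated an onset
there.  The eleven binary predictions are combined by Fisher linear
discriminant analysis, evaluated by a threshold-sweep ROC under scene-level
cross-validation, with learning curves over the amount of training audio and
cross-cohort train/test grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .behavioral import SalientEvent, label_segments, segment_starts
from .core import RocResult
from .features import FEATURE_NAMES, FeatureMatrix

__all__ = [
    "LdaModel",
    "RocResult",
    "detect_feature_events",
    "detect_all_feature_events",
    "build_segments",
    "fit_lda",
    "roc_auroc",
    "crossval",
    "augmentation_curve",
    "cross_cohort_eval",
]

PRED_COLUMNS = [f"pred_{name}" for name in FEATURE_NAMES]


def detect_feature_events(
    series: np.ndarray,
    hop: float = 0.064,
    smooth_dur: float = 1.5,
    prominence: float = 0.1,
    min_separation: float = 0.5,
) -> np.ndarray:
    """Candidate event onsets of one z-scored feature series.

    Triple 1.5 s boxcar, first-order difference, positive slope maxima above
    ``prominence`` (in z-units per second) with 0.5 s minimum separation.
    Returns onset times in seconds.
    """
    series = np.asarray(series, dtype=float)
    width = core.smoothing_width(smooth_dur, hop)
    if series.size < width + 2:
        raise ValueError("series shorter than the smoothing support")
    smoothed = core.triple_boxcar(series, width)
    slope = core.slope_series(smoothed, hop)
    times = (np.arange(series.size) * hop)[1:]
    idx = core.select_peaks(slope, times, min_separation=min_separation, min_height=prominence)
    return times[idx]


def detect_all_feature_events(matrix: FeatureMatrix, **kw) -> dict[str, np.ndarray]:
    """Per-feature candidate onsets for one scene's feature matrix."""
    return {
        name: detect_feature_events(matrix.data[name].to_numpy(), hop=matrix.hop, **kw)
        for name in FEATURE_NAMES
    }


def build_segments(
    scene_id: str,
    duration: float,
    reference_events: list[SalientEvent] | np.ndarray,
    feature_onsets: dict[str, np.ndarray],
    seg_len: float = 1.0,
    hop: float = 0.25,
) -> pd.DataFrame:
    """Segment table of one scene: label plus eleven binary predictions.

    Segments are ``seg_len`` seconds at ``hop`` spacing; membership of any
    onset uses the half-open rule [start, start + seg_len).
    """
    starts = segment_starts(duration, seg_len, hop)
    onsets = np.asarray(
        [e.onset if isinstance(e, SalientEvent) else float(e) for e in reference_events]
    )
    table = pd.DataFrame({"scene_id": scene_id, "start": starts})
    table["label"] = label_segments(starts, onsets, seg_len)
    for name in FEATURE_NAMES:
        table[f"pred_{name}"] = label_segments(
            starts, feature_onsets.get(name, np.empty(0)), seg_len
        )
    return table


@dataclass
class LdaModel:
    """Fisher linear discriminant over the eleven feature predictions."""

    weights: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def score_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.score(table[PRED_COLUMNS].to_numpy(dtype=float))

    def to_dict(self) -> dict:
        return {
            "weights": {n: float(w) for n, w in zip(self.feature_names, self.weights)},
            "intercept": float(self.intercept),
            "meta": self.meta,
        }


def fit_lda(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, meta: dict | None = None) -> LdaModel:
    """Closed-form Fisher discriminant with a ridge-regularized pooled covariance.

    w = (Sw + ridge * I)^-1 (mu1 - mu0); the intercept centers the score at
    the midpoint of the class means.  The ridge guards against the rank
    deficiency typical of binary inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("LDA needs exactly two classes in the labels")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = X0.shape[0], X1.shape[0]
    s0 = np.cov(X0, rowvar=False, bias=False) if n0 > 1 else np.zeros((X.shape[1],) * 2)
    s1 = np.cov(X1, rowvar=False, bias=False) if n1 > 1 else np.zeros((X.shape[1],) * 2)
    denom = max(n0 + n1 - 2, 1)
    sw = ((n0 - 1) * s0 + (n1 - 1) * s1) / denom
    sw = np.atleast_2d(sw) + ridge * np.eye(X.shape[1])
    w = np.linalg.solve(sw, mu1 - mu0)
    intercept = -float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(weights=w, intercept=intercept, meta=meta or {})


def fit_lda_table(table: pd.DataFrame, meta: dict | None = None) -> LdaModel:
    return fit_lda(
        table[PRED_COLUMNS].to_numpy(dtype=float),
        table["label"].to_numpy(),
        meta=meta,
    )


def roc_auroc(scores: np.ndarray, labels: np.ndarray, n_thresholds: int = 201) -> RocResult:
    """ROC and AUROC from a threshold sweep over the score range."""
    return core.sweep_roc(scores, labels, n_thresholds=n_thresholds)


@dataclass
class CrossvalResult:
    fold_aurocs: np.ndarray
    fold_rocs: list[RocResult]
    models: list[LdaModel]
    fold_scenes: list[list[str]]

    @property
    def mean(self) -> float:
        return float(self.fold_aurocs.mean())

    @property
    def se(self) -> float:
        return float(self.fold_aurocs.std(ddof=1) / np.sqrt(self.fold_aurocs.size))


def _scene_folds(scene_ids: list[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    scene_ids = sorted(scene_ids)
    if len(scene_ids) < k:
        raise ValueError(f"{k}-fold split needs at least {k} scenes, got {len(scene_ids)}")
    perm = [scene_ids[i] for i in rng.permutation(len(scene_ids))]
    return [list(perm[i::k]) for i in range(k)]


def crossval(
    tables: dict[str, pd.DataFrame],
    k: int = 10,
    seed: int = 0,
    n_thresholds: int = 201,
) -> CrossvalResult:
    """Scene-level k-fold cross-validated LDA with held-out ROC per fold.

    Folds partition whole scenes so overlapping segments never leak between
    train and test.
    """
    rng = np.random.default_rng(seed)
    folds = _scene_folds(list(tables), k, rng)
    aurocs, rocs, models = [], [], []
    for fold in folds:
        train = pd.concat([tables[s] for s in tables if s not in fold], ignore_index=True)
        test = pd.concat([tables[s] for s in fold], ignore_index=True)
        model = fit_lda_table(train, meta={"fold_scenes": fold, "k": k, "seed": seed})
        roc = roc_auroc(model.score_table(test), test["label"].to_numpy(), n_thresholds)
        models.append(model)
        rocs.append(roc)
        aurocs.append(roc.auroc)
    return CrossvalResult(
        fold_aurocs=np.asarray(aurocs), fold_rocs=rocs, models=models, fold_scenes=folds
    )


def _scene_minutes(table: pd.DataFrame, seg_len: float = 1.0, hop: float = 0.25) -> float:
    return (table["start"].max() + seg_len) / 60.0


def _take_minutes(
    order: list[str],
    tables: dict[str, pd.DataFrame],
    minutes: float,
) -> pd.DataFrame:
    """Whole scenes taken in order until the minute budget is met.

    The last scene is truncated (earliest segments kept) to land on the
    budget.
    """
    parts = []
    remaining = minutes * 60.0
    for sid in order:
        if remaining <= 0:
            break
        t = tables[sid]
        dur = t["start"].max() + 1.0
        if dur <= remaining:
            parts.append(t)
            remaining -= dur
        else:
            parts.append(t[t["start"] < remaining])
            remaining = 0.0
    return pd.concat(parts, ignore_index=True)


def augmentation_curve(
    tables: dict[str, pd.DataFrame],
    step_minutes: float = 10.0,
    resamples: int = 100,
    k: int = 10,
    seed: int = 0,
    sizes_minutes: list[float] | None = None,
) -> pd.DataFrame:
    """Held-out AUROC as a function of the amount of training audio.

    For each test fold, ``resamples`` random orderings of the remaining
    scenes are drawn; within one ordering the training set at each target
    size is a prefix of the next (incremental augmentation: larger budgets
    extend, never replace, the smaller ones).  A model is fitted per
    (fold, size, resample) and evaluated on the fold.  Returns a tidy frame
    (fold, size_min, resample, auroc, auroc_norm) where auroc_norm divides
    by the fold's mean AUROC at the first step, so the normalized curve
    starts at 1 by construction.
    """
    rng = np.random.default_rng(seed)
    folds = _scene_folds(list(tables), k, rng)
    pool_minutes = min(
        sum(_scene_minutes(tables[s]) for s in tables if s not in fold) for fold in folds
    )
    if sizes_minutes is None:
        n_steps = int(pool_minutes // step_minutes)
        if n_steps < 1:
            raise ValueError("step exceeds the available training audio")
        sizes_minutes = [step_minutes * (i + 1) for i in range(n_steps)]
    rows = []
    for fi, fold in enumerate(folds):
        pool = sorted(s for s in tables if s not in fold)
        test = pd.concat([tables[s] for s in fold], ignore_index=True)
        y_test = test["label"].to_numpy()
        for r in range(resamples):
            order = [pool[i] for i in rng.permutation(len(pool))]
            for size in sizes_minutes:
                train = _take_minutes(order, tables, size)
                model = fit_lda_table(train)
                auroc = roc_auroc(model.score_table(test), y_test).auroc
                rows.append(
                    {"fold": fi, "size_min": size, "resample": r, "auroc": auroc}
                )
    out = pd.DataFrame(rows)
    first = out[out["size_min"] == sizes_minutes[0]].groupby("fold")["auroc"].mean()
    out["auroc_norm"] = out["auroc"] / out["fold"].map(first)
    return out


def cross_cohort_eval(
    tables_a: dict[str, pd.DataFrame],
    tables_b: dict[str, pd.DataFrame],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """2x2 train/test AUROC grid for two cohorts' event labels on shared scenes.

    Both cohorts' segment tables must cover the same scenes (feature
    predictions are typically identical; only the behavioral labels differ).
    The same scene folds are used for all four train/test combinations and
    fold-mean AUROCs are reported.
    """
    if set(tables_a) != set(tables_b):
        raise ValueError("cohorts must cover the same scenes")
    for tag, tables in (("A", tables_a), ("B", tables_b)):
        if not any(t["label"].any() for t in tables.values()):
            raise ValueError(f"cohort {tag} has no positive segments")
    rng = np.random.default_rng(seed)
    folds = _scene_folds(list(tables_a), k, rng)
    cohorts = {"A": tables_a, "B": tables_b}
    rows = []
    for train_tag, train_tables in cohorts.items():
        for test_tag, test_tables in cohorts.items():
            aurocs = []
            for fold in folds:
                train = pd.concat(
                    [train_tables[s] for s in train_tables if s not in fold],
                    ignore_index=True,
                )
                test = pd.concat([test_tables[s] for s in fold], ignore_index=True)
                model = fit_lda_table(train)
                aurocs.append(
                    roc_auroc(model.score_table(test), test["label"].to_numpy()).auroc
                )
            rows.append(
                {
                    "train": train_tag,
                    "test": test_tag,
                    "auroc": float(np.mean(aurocs)),
                    "se": float(np.std(aurocs, ddof=1) / np.sqrt(len(aurocs)))
                    if len(aurocs) > 1
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
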