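"""Plain-text and WAV interchange for every pipeline artifact.

All tables are CSV, model weights are JSON, audio is 16-bit PCM WAV at
22 kHz.  Times are seconds from scene start, 0-based, with half-open
interval semantics everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .behavioral import SalienceCurve, SalientEvent
from .features import FEATURE_NAMES, FeatureMatrix
from .synth import (
    LABEL_CODES,
    LABEL_NAMES,
    SAMPLE_RATE,
    PlantedEvent,
    ResponseTrace,
    TrialSchedule,
)


def write_wav(path: str | Path, waveform: np.ndarray, fs: int = SAMPLE_RATE) -> None:
    peak = np.max(np.abs(waveform))
    scale = 0.9 / peak if peak > 0 else 1.0
    wavfile.write(str(path), fs, np.round(waveform * scale * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(str(path))
    raw_dtype = data.dtype
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # stereo to mono by channel average
        data = data.mean(axis=1)
    if np.issubdtype(raw_dtype, np.integer):
        data /= 32768.0
    return data, fs


def write_truth(path: str | Path, truths: dict[str, tuple[PlantedEvent, ...]]) -> None:
    rows = [
        {
            "scene_id": sid,
            "onset_s": e.onset,
            "kind": e.kind,
            "magnitude": e.magnitude,
            "duration_s": e.event_duration,
        }
        for sid, events in sorted(truths.items())
        for e in events
    ]
    pd.DataFrame(rows, columns=["scene_id", "onset_s", "kind", "magnitude", "duration_s"]).to_csv(
        path, index=False
    )


def write_schedule(path: str | Path, schedule: list[TrialSchedule]) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "trial": t.trial_index,
                "left_scene": t.left_scene_id,
                "right_scene": t.right_scene_id,
            }
            for t in schedule
        ]
    ).to_csv(path, index=False)


def write_traces(path: str | Path, traces: list[ResponseTrace]) -> None:
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "trial": tr.trial_index,
                    "t": np.round(tr.times, 6),
                    "label": [LABEL_NAMES[v] for v in tr.labels],
                    "left_scene": tr.left_scene_id,
                    "right_scene": tr.right_scene_id,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[ResponseTrace]:
    frame = pd.read_csv(path)
    traces = []
    for (sid, trial), grp in frame.groupby(["subject_id", "trial"], sort=True):
        grp = grp.sort_values("t")
        traces.append(
            ResponseTrace(
                subject_id=str(sid),
                trial_index=int(trial),
                left_scene_id=str(grp["left_scene"].iloc[0]),
                right_scene_id=str(grp["right_scene"].iloc[0]),
                times=grp["t"].to_numpy(dtype=float),
                labels=np.array([LABEL_CODES[v] for v in grp["label"]], dtype=np.int8),
            )
        )
    return traces


def write_curves(path: str | Path, curves: dict[str, SalienceCurve]) -> None:
    parts = [
        pd.DataFrame(
            {
                "scene_id": c.scene_id,
                "t": np.round(c.times, 6),
                "salience": c.salience,
                "n_subjects": c.n_subjects,
            }
        )
        for c in curves.values()
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> dict[str, SalienceCurve]:
    frame = pd.read_csv(path)
    out = {}
    for sid, grp in frame.groupby("scene_id", sort=True):
        grp = grp.sort_values("t")
        out[str(sid)] = SalienceCurve(
            scene_id=str(sid),
            times=grp["t"].to_numpy(dtype=float),
            salience=grp["salience"].to_numpy(dtype=float),
            n_subjects=grp["n_subjects"].to_numpy(dtype=int),
        )
    return out


def write_events(path: str | Path, events: dict[str, list[SalientEvent]]) -> None:
    rows = [
        {"scene_id": sid, "onset_s": e.onset, "slope_peak": e.slope_peak, "strength": e.strength}
        for sid, evs in sorted(events.items())
        for e in evs
    ]
    pd.DataFrame(rows, columns=["scene_id", "onset_s", "slope_peak", "strength"]).to_csv(
        path, index=False
    )


def read_events(path: str | Path) -> dict[str, list[SalientEvent]]:
    frame = pd.read_csv(path)
    out: dict[str, list[SalientEvent]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["scene_id"]), []).append(
            SalientEvent(
                onset=float(row["onset_s"]),
                slope_peak=float(row["slope_peak"]),
                strength=float(row["strength"]),
            )
        )
    return out


def write_features(path: str | Path, matrices: list[FeatureMatrix]) -> None:
    parts = []
    for m in matrices:
        tidy = m.data.copy()
        tidy.insert(0, "t", np.round(m.times, 6))
        tidy.insert(0, "scene_id", m.scene_id)
        parts.append(tidy.melt(id_vars=["scene_id", "t"], var_name="feature", value_name="value"))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureMatrix]:
    frame = pd.read_csv(path)
    out = []
    for sid, grp in frame.groupby("scene_id", sort=True):
        wide = grp.pivot(index="t", columns="feature", values="value").sort_index()
        hop = float(wide.index[1] - wide.index[0])
        out.append(
            FeatureMatrix(
                scene_id=str(sid),
                data=wide[list(FEATURE_NAMES)].reset_index(drop=True),
                hop=hop,
            )
        )
    return out


def write_model(path: str | Path, model) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
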