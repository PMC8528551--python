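"""Shared fixtures: simulated studies reused across test modules.

The heavier fixtures (anything that renders audio and extracts features) are
session-scoped so the suite pays for each synthetic study once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dlsalience import behavioral as B
from dlsalience import features as F
from dlsalience import prediction as P
from dlsalience import synth


def make_cohort_traces(specs, n_subjects, trials, seed, profile="normal"):
    schedule = synth.make_schedule(sorted(specs), n_subjects, trials, seed=seed)
    profiles = {
        f"S{i:04d}": synth.SubjectProfile.preset(profile) for i in range(n_subjects)
    }
    return synth.simulate_cohort(profiles, schedule, specs, seed=seed + 1)


def responses_by_scene(traces):
    out: dict[str, list] = {}
    for tr in traces:
        out.setdefault(tr.left_scene_id, []).append((tr.times, B.map_response(tr, "left")))
        out.setdefault(tr.right_scene_id, []).append((tr.times, B.map_response(tr, "right")))
    return out


@pytest.fixture(scope="session")
def recovery_study():
    """Six 2-minute scenes (one event-free), magnitude-4 events, 80 subjects."""
    rng = np.random.default_rng(1)
    specs = {
        f"sc{i}": synth.random_scene_spec(
            f"sc{i}", 120.0, 0 if i == 0 else 12,
            seed=int(rng.integers(2**31)), magnitude_range=(4.0, 4.0),
        )
        for i in range(6)
    }
    traces = make_cohort_traces(specs, 80, 3, seed=int(rng.integers(2**31)))
    qc = B.qc_filter(traces)
    curves = B.salience_by_scene(qc.kept)
    events = B.extract_events_dataset(curves)
    return {"specs": specs, "traces": traces, "qc": qc, "curves": curves, "events": events}


@pytest.fixture(scope="session")
def agreement_study():
    """A 16-scene block with 80 subjects for the interobserver analyses."""
    rng = np.random.default_rng(1)
    specs = {
        f"sc{i:02d}": synth.random_scene_spec(
            f"sc{i:02d}", 120.0, 0 if i == 0 else 12,
            seed=int(rng.integers(2**31)), magnitude_range=(3.0, 5.0),
        )
        for i in range(16)
    }
    traces = make_cohort_traces(specs, 80, 8, seed=int(rng.integers(2**31)))
    qc = B.qc_filter(traces)
    curves = B.salience_by_scene(qc.kept)
    events = B.extract_events_dataset(curves)
    return {
        "specs": specs,
        "qc": qc,
        "curves": curves,
        "events": events,
        "responses": responses_by_scene(qc.kept),
    }


@pytest.fixture(scope="session")
def harmonic_feature_study():
    """Five scenes of loud harmonic-complex events with their feature matrices."""
    rng = np.random.default_rng(8)
    out = []
    for i in range(5):
        spec = synth.random_scene_spec(
            f"h{i}", 120.0, 10, seed=int(rng.integers(2**31)),
            kinds=("harmonic_complex",), magnitude_range=(3.5, 4.5),
        )
        wav, _ = synth.generate_scene(spec)
        out.append((spec, F.assemble_features(wav, scene_id=spec.scene_id)))
    return out


@pytest.fixture(scope="session")
def prediction_study():
    """Dense, acoustically hard scene corpus with behavioral segment tables.

    32 two-minute scenes over AM-babble backgrounds, one event kind per scene
    and modest magnitudes, so acoustic predictability sits in the regime
    where the amount of training data matters.  Returns the per-scene feature
    onsets plus a factory producing segment tables for independently
    simulated cohorts.
    """
    rng = np.random.default_rng(21)
    kinds = synth.EVENT_KINDS
    specs = {}
    for i in range(32):
        sid = f"sc{i:02d}"
        specs[sid] = synth.random_scene_spec(
            sid, 120.0, 8, seed=int(rng.integers(2**31)),
            kinds=(kinds[i % 4],), magnitude_range=(0.8, 1.8),
            background="am_babble",
        )
    feat_onsets = {}
    for sid, spec in sorted(specs.items()):
        wav, _ = synth.generate_scene(spec)
        fm = F.assemble_features(wav, scene_id=sid)
        feat_onsets[sid] = (P.detect_all_feature_events(fm), fm.duration)

    def cohort_tables(seed: int, n_subjects: int = 60):
        traces = make_cohort_traces(specs, n_subjects, 16, seed=seed)
        qc = B.qc_filter(traces)
        curves = B.salience_by_scene(qc.kept)
        events = B.extract_events_dataset(curves)
        return {
            sid: P.build_segments(sid, feat_onsets[sid][1], events[sid], feat_onsets[sid][0])
            for sid in sorted(specs)
        }

    return {"specs": specs, "feat_onsets": feat_onsets, "cohort_tables": cohort_tables,
            "tables": cohort_tables(100)}
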