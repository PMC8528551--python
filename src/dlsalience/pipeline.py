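"""End-to-end runs: simulate -> qc -> salience -> events -> features -> predict -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML with unknown keys
rejected) and a master seed that deterministically spawns one substream per
stage, so any stage can be re-run in isolation with identical results.  Every
stage writes its artifacts into the run directory and appends to a plain-text
log.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavioral, io, prediction, synth
from .features import assemble_features

_STAGES = ("simulate", "qc", "salience", "events", "features", "predict", "report")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults give a small demo."""

    out_dir: str = "runs/demo"
    seed: int = 0
    cohort: str = "crowd"

    # inputs: either simulate, or point at existing artifacts
    simulate: bool = True
    scenes_dir: str | None = None
    traces_file: str | None = None

    # synthetic experiment design
    n_scenes: int = 6
    n_empty_scenes: int = 1
    scene_duration: float = 120.0
    events_per_scene: int = 8
    background: str = "pink_noise"
    n_subjects: int = 80
    trials_per_subject: int = 3
    subject_profile: str = "normal"
    write_audio: bool = True

    # analysis parameters
    trace_rate: float = 10.0
    qc_low: float = 0.025
    qc_high: float = 1.0
    qc_subject_frac: float = 0.5
    smooth_dur: float = 1.5
    rt_offset: float = 1.0
    strength_window: float = 4.0
    keep_frac: float = 0.5
    pruning: str = "global"
    prominence: float = 0.1
    folds: int = 6

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage_seed(master: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(master).spawn(len(_STAGES))[idx]
    return int(child.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _log(run_dir: Path, message: str) -> None:
    with open(run_dir / "run.log", "a") as fh:
        fh.write(message + "\n")


def run_pipeline(config: RunConfig, until: str | None = None) -> Path:
    """Execute the stages in order and return the run directory.

    ``until`` stops the run after the named stage ("simulate", "qc",
    "salience", "events", "features"); the default runs everything.
    """
    if until is not None and until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    t0 = time.time()

    # --- simulate -----------------------------------------------------------
    if config.simulate:
        seed = _stage_seed(config.seed, "simulate")
        rng = np.random.default_rng(seed)
        specs = {}
        for i in range(config.n_scenes):
            sid = f"scene{i:02d}"
            n_events = 0 if i < config.n_empty_scenes else config.events_per_scene
            specs[sid] = synth.random_scene_spec(
                sid,
                config.scene_duration,
                n_events,
                seed=int(rng.integers(2**31)),
                background=config.background,
            )
        if config.write_audio:
            scenes_dir = run_dir / "scenes"
            scenes_dir.mkdir(exist_ok=True)
            for sid, spec in specs.items():
                wav, _ = synth.generate_scene(spec)
                io.write_wav(scenes_dir / f"{sid}.wav", wav)
        io.write_truth(run_dir / "truth.csv", {s: sp.events for s, sp in specs.items()})
        schedule = synth.make_schedule(
            sorted(specs), config.n_subjects, config.trials_per_subject,
            seed=int(rng.integers(2**31)),
        )
        io.write_schedule(run_dir / "schedule.csv", schedule)
        profiles = {
            f"S{i:04d}": synth.SubjectProfile.preset(config.subject_profile)
            for i in range(config.n_subjects)
        }
        traces = synth.simulate_cohort(
            profiles, schedule, specs, seed=int(rng.integers(2**31)),
            trace_rate=config.trace_rate,
        )
        io.write_traces(run_dir / "traces.csv", traces)
        _log(run_dir, f"simulate: {len(specs)} scenes, {len(traces)} traces "
                      f"[{time.time() - t0:.1f}s]")
    else:
        if not config.traces_file or not Path(config.traces_file).exists():
            raise PipelineError("simulate", "no traces file provided and --simulate not set")
        traces = io.read_traces(config.traces_file)
        specs = None
        _log(run_dir, f"load: {len(traces)} traces from {config.traces_file}")
    if until == "simulate":
        return run_dir

    # --- qc -----------------------------------------------------------------
    qc = behavioral.qc_filter(
        traces, low=config.qc_low, high=config.qc_high, subject_frac=config.qc_subject_frac
    )
    qc.rates.to_csv(run_dir / "qc.csv", index=False)
    _log(run_dir, f"qc: kept {len(qc.kept)}/{len(traces)} trials, "
                  f"excluded subjects: {qc.excluded_subjects}")
    if until == "qc":
        return run_dir

    # --- salience -----------------------------------------------------------
    dt = 1.0 / config.trace_rate
    curves = behavioral.salience_by_scene(qc.kept, dt=dt)
    io.write_curves(run_dir / "salience.csv", curves)
    _log(run_dir, f"salience: {len(curves)} scenes")
    if until == "salience":
        return run_dir

    # --- events --------------------------------------------------------------
    events = behavioral.extract_events_dataset(
        curves,
        smooth_dur=config.smooth_dur,
        rt_offset=config.rt_offset,
        window=config.strength_window,
        keep_frac=config.keep_frac,
        pruning=config.pruning,
    )
    io.write_events(run_dir / "events.csv", events)
    n_ev = sum(len(v) for v in events.values())
    _log(run_dir, f"events: {n_ev} events [{time.time() - t0:.1f}s]")
    if until == "events":
        return run_dir

    # --- features ------------------------------------------------------------
    matrices = []
    if config.simulate and specs is not None:
        for sid, spec in sorted(specs.items()):
            wav, _ = synth.generate_scene(spec)
            matrices.append(assemble_features(wav, scene_id=sid))
    elif config.scenes_dir:
        for wav_path in sorted(Path(config.scenes_dir).glob("*.wav")):
            wav, fs = io.read_wav(wav_path)
            matrices.append(assemble_features(wav, fs=fs, scene_id=wav_path.stem))
    if matrices:
        io.write_features(run_dir / "features.csv", matrices)
    _log(run_dir, f"features: {len(matrices)} scenes [{time.time() - t0:.1f}s]")
    if until == "features":
        io.write_json(run_dir / "summary.json", {"n_events": n_ev, "n_scenes": len(curves)})
        return run_dir

    # --- predict ---------------------------------------------------------------
    summary: dict = {"n_events": n_ev, "n_scenes": len(curves)}
    if matrices:
        seed = _stage_seed(config.seed, "predict")
        tables = {}
        for m in matrices:
            onsets = prediction.detect_all_feature_events(m, prominence=config.prominence)
            tables[m.scene_id] = prediction.build_segments(
                m.scene_id, m.duration, events.get(m.scene_id, []), onsets
            )
        seg = np.concatenate([t["label"].to_numpy() for t in tables.values()])
        if seg.any() and not seg.all() and len(tables) >= config.folds:
            cv = prediction.crossval(tables, k=config.folds, seed=seed)
            io.write_model(run_dir / "model.json", cv.models[0])
            rows = []
            for fi, roc in enumerate(cv.fold_rocs):
                for th, h, f in zip(roc.thresholds, roc.hit_rate, roc.fa_rate):
                    rows.append({"fold": fi, "threshold": th, "hit_rate": h, "fa_rate": f})
            import pandas as pd

            pd.DataFrame(rows).to_csv(run_dir / "roc.csv", index=False)
            pd.DataFrame(
                {"fold": np.arange(cv.fold_aurocs.size), "auroc": cv.fold_aurocs}
            ).to_csv(run_dir / "auroc.csv", index=False)
            summary["auroc_mean"] = cv.mean
            summary["auroc_se"] = cv.se
            _log(run_dir, f"predict: AUROC {cv.mean:.3f} +/- {cv.se:.3f}")
        else:
            _log(run_dir, "predict: skipped (needs both classes and enough scenes)")

    io.write_json(run_dir / "summary.json", summary)
    _log(run_dir, f"done [{time.time() - t0:.1f}s]")
    return run_dir


def report(run_dir: str | Path) -> Path:
    """Figures plus a machine-readable summary for a completed run.

    Produces: salience curves with event markers, per-fold ROC curves, the
    distribution of event strengths, and QC switching-rate histogram.  A run
    with missing artifacts gets a report listing what is absent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    missing = [
        name
        for name in ("salience.csv", "events.csv", "qc.csv", "summary.json")
        if not (run_dir / name).exists()
    ]
    summary = io.read_json(run_dir / "summary.json") if (run_dir / "summary.json").exists() else {}
    summary["missing_artifacts"] = missing
    if "salience.csv" not in missing and "events.csv" not in missing:
        curves = io.read_curves(run_dir / "salience.csv")
        events = io.read_events(run_dir / "events.csv")
        n = len(curves)
        fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n), sharex=True, squeeze=False)
        for ax, (sid, c) in zip(axes.ravel(), sorted(curves.items())):
            ax.plot(c.times, c.salience, lw=0.8)
            for ev in events.get(sid, []):
                ax.axvline(ev.onset, color="r", lw=0.6, alpha=0.7)
            ax.set_ylabel(sid, fontsize=7)
            ax.set_ylim(0, 1)
        axes.ravel()[-1].set_xlabel("time (s)")
        fig.suptitle("average behavioral salience with extracted events")
        fig.savefig(fig_dir / "salience_events.png", dpi=110)
        plt.close(fig)
        strengths = [e.strength for evs in events.values() for e in evs]
        fig, ax = plt.subplots(figsize=(5, 3))
        if strengths:
            ax.hist(strengths, bins=20)
        else:
            ax.text(0.5, 0.5, "no events extracted", ha="center", va="center")
        ax.set_xlabel("event strength")
        fig.savefig(fig_dir / "event_strengths.png", dpi=110)
        plt.close(fig)
    if (run_dir / "qc.csv").exists():
        rates = pd.read_csv(run_dir / "qc.csv")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.hist(rates["rate"], bins=30)
        ax.axvline(0.025, color="r", ls="--", lw=0.8)
        ax.axvline(1.0, color="r", ls="--", lw=0.8)
        ax.set_xlabel("switching rate (1/s)")
        fig.savefig(fig_dir / "qc_rates.png", dpi=110)
        plt.close(fig)
    if (run_dir / "roc.csv").exists():
        roc = pd.read_csv(run_dir / "roc.csv")
        fig, ax = plt.subplots(figsize=(4, 4))
        for fi, grp in roc.groupby("fold"):
            ax.plot(grp["fa_rate"], grp["hit_rate"], lw=0.7, alpha=0.7)
        ax.plot([0, 1], [0, 1], "k--", lw=0.6)
        ax.set_xlabel("false-alarm rate")
        ax.set_ylabel("hit rate")
        fig.savefig(fig_dir / "roc.png", dpi=110)
        plt.close(fig)
    io.write_json(run_dir / "report.json", summary)
    return fig_dir
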