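"""Synthetic dichotic-listening experiments with known ground truth.

Audio scenes are stationary backgrounds (pink noise or slowly amplitude
modulated "babble" noise) with planted acoustic events of controlled kind,
magnitude and timing.  Subjects are simulated as attention state machines
whose switches toward a scene follow planted events with a ~1 s reaction
latency, plus spontaneous exploratory switches and a drift back to the
center of the screen.  Everything is a pure function of its inputs and a
seed, so every downstream analysis stage can be tested against the planted
truth without any external recordings.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

SAMPLE_RATE = 22_000
TRACE_RATE = 10.0  # Hz, cursor-position logging rate

LEFT, CENTER, RIGHT = -1, 0, 1
LABEL_NAMES = {LEFT: "L", CENTER: "C", RIGHT: "R"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

EVENT_KINDS = ("tone_pip", "harmonic_complex", "noise_burst", "am_burst")
BACKGROUNDS = ("pink_noise", "am_babble")

_BG_RMS = 0.05  # nominal background RMS in full-scale units
_RAMP_S = 0.01  # event onset/offset ramp


@dataclass(frozen=True)
class PlantedEvent:
    """One ground-truth acoustic event: onset (s), kind, SNR-like magnitude."""

    onset: float
    kind: str = "harmonic_complex"
    magnitude: float = 4.0
    event_duration: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be >= 0")
        if not 0.1 < self.event_duration <= 5.0:
            raise ValueError("event_duration must lie in (0.1, 5] s")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene."""

    scene_id: str
    duration: float
    background: str = "pink_noise"
    events: tuple[PlantedEvent, ...] = ()
    density: str = "sparse"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if self.density not in ("sparse", "dense"):
            raise ValueError("density must be 'sparse' or 'dense'")
        onsets = [e.onset for e in self.events]
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if any(o2 - o1 < 1.0 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("consecutive event onsets must be >= 1 s apart")
        for e in self.events:
            if not 2.0 <= e.onset <= self.duration - 2.0:
                raise ValueError("event onsets must lie in [2, duration - 2] s")
            if e.onset + e.event_duration > self.duration:
                raise ValueError("event must end before the scene does")


@dataclass(frozen=True)
class SubjectProfile:
    """Behavioral parameters of one simulated listener.

    ``detect_slope`` sets the detection probability p(m) = min(1, slope * m)
    for an event of magnitude m; ``spontaneous_rate`` is the Poisson rate of
    exploratory cursor moves; captures decay back to center after an
    exponential holding time (mean ``hold_mean`` seconds).
    """

    reaction_mean: float = 1.0
    reaction_sd: float = 0.25
    detect_slope: float = 0.15
    spontaneous_rate: float = 0.1
    hold_mean: float = 5.0
    profile: str = "normal"

    def __post_init__(self) -> None:
        if self.reaction_mean <= 0:
            raise ValueError("reaction_mean must be positive")
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be >= 0")

    def detect_probability(self, magnitude: float) -> float:
        return float(min(1.0, self.detect_slope * magnitude))

    @staticmethod
    def preset(name: str) -> "SubjectProfile":
        presets = {
            "normal": SubjectProfile(),
            "hyperactive": SubjectProfile(spontaneous_rate=1.5, profile="hyperactive"),
            "inactive": SubjectProfile(
                detect_slope=0.0, spontaneous_rate=0.01, profile="inactive"
            ),
        }
        if name not in presets:
            raise ValueError(f"unknown profile preset {name!r}")
        return presets[name]


@dataclass(frozen=True)
class TrialSchedule:
    """One dichotic trial: which scene goes to which ear of which subject."""

    subject_id: str
    trial_index: int
    left_scene_id: str
    right_scene_id: str

    def __post_init__(self) -> None:
        if self.left_scene_id == self.right_scene_id:
            raise ValueError("left and right scenes must differ")


@dataclass
class ResponseTrace:
    """Piecewise-constant attention labels of one subject in one trial."""

    subject_id: str
    trial_index: int
    left_scene_id: str
    right_scene_id: str
    times: np.ndarray
    labels: np.ndarray  # values in {LEFT, CENTER, RIGHT}

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)

    def n_switches(self) -> int:
        return int(np.count_nonzero(np.diff(self.labels)))

    def switching_rate(self) -> float:
        return self.n_switches() / self.duration


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    spec[1:] /= np.sqrt(freqs[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / _rms(x)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _band_noise(n: int, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    r = _rms(x)
    return x / r if r > 0 else x


def _event_envelope(n: int) -> np.ndarray:
    """Flat envelope with raised-cosine on/off ramps."""
    env = np.ones(n)
    ramp = min(int(_RAMP_S * SAMPLE_RATE), n // 2)
    if ramp > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = win
        env[-ramp:] = win[::-1]
    return env


def _event_waveform(event: PlantedEvent, rng: np.random.Generator) -> np.ndarray:
    n = int(round(event.event_duration * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE
    if event.kind == "tone_pip":
        f = float(np.exp(rng.uniform(np.log(300.0), np.log(3000.0))))
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif event.kind == "harmonic_complex":
        # Voiced/alarm-like source: 1/h harmonic rolloff, slow tremolo plus a
        # rough 40-80 Hz amplitude modulation.
        f0 = float(np.exp(rng.uniform(np.log(90.0), np.log(400.0))))
        x = np.zeros(n)
        for h in range(1, 9):
            if h * f0 < 0.45 * SAMPLE_RATE:
                x += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
        tremolo = 1 + 0.3 * np.sin(2 * np.pi * rng.uniform(4.0, 7.0) * t + rng.uniform(0, 2 * np.pi))
        rough = 1 + 0.3 * np.sin(2 * np.pi * rng.uniform(40.0, 80.0) * t + rng.uniform(0, 2 * np.pi))
        x = x * tremolo * rough
    elif event.kind == "noise_burst":
        x = rng.standard_normal(n)
    else:  # am_burst
        f_am = rng.uniform(30.0, 80.0)
        x = rng.standard_normal(n) * (1 + 0.8 * np.sin(2 * np.pi * f_am * t))
    x = x * _event_envelope(n)
    r = _rms(x)
    if r > 0:
        x /= r
    return x


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, tuple[PlantedEvent, ...]]:
    """Render a scene spec to a mono waveform at 22 kHz plus its truth list.

    Each planted event is mixed in at an RMS of ``magnitude`` times the
    background RMS, so the magnitude is directly an SNR factor.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * SAMPLE_RATE))
    x = _pink_noise(n, rng)
    if spec.background == "am_babble":
        mod = _band_noise(n, 3.0, 7.0, rng)
        x = x * np.clip(1.0 + 0.5 * mod, 0.05, None)
        x /= _rms(x)
    x = x * _BG_RMS
    for event in spec.events:
        wav = _event_waveform(event, rng) * (event.magnitude * _BG_RMS)
        start = int(round(event.onset * SAMPLE_RATE))
        stop = min(start + wav.size, n)
        x[start:stop] += wav[: stop - start]
    return x, tuple(spec.events)


def random_scene_spec(
    scene_id: str,
    duration: float,
    n_events: int,
    seed: int,
    kinds: tuple[str, ...] = EVENT_KINDS,
    magnitude_range: tuple[float, float] = (3.0, 5.0),
    background: str = "pink_noise",
    min_gap: float = 8.0,
) -> SceneSpec:
    """Scene spec with events at uniformly random, well-separated onsets.

    Onsets are uniform over the scene subject to a minimum gap (default 8 s,
    so behaviorally driven salience peaks stay distinct after smoothing),
    via the standard order-statistics construction: sorted uniforms over the
    slack plus the accumulated gaps.  The irregular placement also keeps
    event times unaligned across scenes, as in natural recordings.
    """
    rng = np.random.default_rng(seed)
    events = []
    if n_events > 0:
        max_dur = 2.5
        lo, hi = 2.0, duration - 2.0 - max_dur
        slack = (hi - lo) - (n_events - 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"{n_events} events with {min_gap} s gaps do not fit in {duration} s"
            )
        offsets = np.sort(rng.uniform(0.0, slack, size=n_events))
        onsets = lo + offsets + min_gap * np.arange(n_events)
        for onset in onsets:
            events.append(
                PlantedEvent(
                    onset=round(float(onset), 2),
                    kind=kinds[int(rng.integers(len(kinds)))],
                    magnitude=float(rng.uniform(*magnitude_range)),
                    event_duration=float(rng.uniform(1.2, max_dur)),
                )
            )
    density = "dense" if n_events >= duration / 12 else "sparse"
    return SceneSpec(
        scene_id=scene_id,
        duration=duration,
        background=background,
        events=tuple(events),
        density=density,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trial scheduling
# ---------------------------------------------------------------------------


def make_schedule(
    scene_ids: list[str],
    n_subjects: int,
    trials_per_subject: int = 10,
    seed: int = 0,
    subject_prefix: str = "S",
) -> list[TrialSchedule]:
    """Random dichotic pairings; each subject hears any scene at most once.

    Every subject receives an independent random permutation of the scene
    block, consumed two scenes per trial, so opponents per scene accumulate
    across subjects.
    """
    scene_ids = list(scene_ids)
    if 2 * trials_per_subject > len(scene_ids):
        raise ValueError(
            f"{trials_per_subject} trials need {2 * trials_per_subject} scenes, "
            f"got {len(scene_ids)}"
        )
    rng = np.random.default_rng(seed)
    schedule = []
    for s in range(n_subjects):
        sid = f"{subject_prefix}{s:04d}"
        perm = rng.permutation(scene_ids)
        for t in range(trials_per_subject):
            schedule.append(
                TrialSchedule(
                    subject_id=sid,
                    trial_index=t,
                    left_scene_id=str(perm[2 * t]),
                    right_scene_id=str(perm[2 * t + 1]),
                )
            )
    return schedule


def opponent_counts(schedule: list[TrialSchedule]) -> dict[str, int]:
    """Number of distinct opposing scenes each scene was paired with."""
    opp: dict[str, set[str]] = {}
    for tr in schedule:
        opp.setdefault(tr.left_scene_id, set()).add(tr.right_scene_id)
        opp.setdefault(tr.right_scene_id, set()).add(tr.left_scene_id)
    return {k: len(v) for k, v in opp.items()}


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def _truncated_latency(profile: SubjectProfile, rng: np.random.Generator) -> float:
    if profile.reaction_sd <= 0:
        return float(np.clip(profile.reaction_mean, 0.2, 3.0))
    for _ in range(100):
        lat = rng.normal(profile.reaction_mean, profile.reaction_sd)
        if 0.2 < lat < 3.0:
            return float(lat)
    return float(np.clip(profile.reaction_mean, 0.2 + 1e-9, 3.0 - 1e-9))


def simulate_subject(
    profile: SubjectProfile,
    schedule: list[TrialSchedule],
    truths: dict[str, SceneSpec],
    seed: int = 0,
    trace_rate: float = TRACE_RATE,
) -> list[ResponseTrace]:
    """Simulate one subject's cursor traces for their scheduled trials.

    Planted events capture attention toward their scene with probability
    p(magnitude) after a truncated-normal latency; exploratory moves occur as
    a Poisson process and pick a uniformly random different screen region;
    a captured subject drifts back to center after an exponential hold unless
    re-captured first.
    """
    rng = np.random.default_rng(seed)
    traces = []
    for trial in schedule:
        for side in (trial.left_scene_id, trial.right_scene_id):
            if side not in truths:
                raise KeyError(f"no truth available for scene {side!r}")
        left = truths[trial.left_scene_id]
        right = truths[trial.right_scene_id]
        duration = min(left.duration, right.duration)

        # (time, kind, target); kind 0 = capture, 1 = spontaneous
        actions: list[tuple[float, int, int]] = []
        for scene, target in ((left, LEFT), (right, RIGHT)):
            for event in scene.events:
                if rng.random() < profile.detect_probability(event.magnitude):
                    t = event.onset + _truncated_latency(profile, rng)
                    if t < duration:
                        actions.append((t, 0, target))
        n_spont = rng.poisson(profile.spontaneous_rate * duration)
        for t in np.sort(rng.uniform(0.0, duration, size=n_spont)):
            actions.append((float(t), 1, 0))
        heapq.heapify(actions)

        changes_t = [0.0]
        changes_v = [CENTER]
        state = CENTER
        return_time = np.inf
        while actions or return_time < duration:
            if actions and actions[0][0] <= return_time:
                t, kind, target = heapq.heappop(actions)
                if t >= duration:
                    break
                if kind == 1:  # spontaneous: move somewhere else
                    others = [lbl for lbl in (LEFT, CENTER, RIGHT) if lbl != state]
                    target = others[int(rng.integers(2))]
                if target != state:
                    state = target
                    changes_t.append(t)
                    changes_v.append(state)
                if state != CENTER:
                    return_time = t + rng.exponential(profile.hold_mean)
                else:
                    return_time = np.inf
            else:
                t = return_time
                return_time = np.inf
                if t < duration and state != CENTER:
                    state = CENTER
                    changes_t.append(t)
                    changes_v.append(state)

        dt = 1.0 / trace_rate
        times = np.arange(int(round(duration * trace_rate))) * dt
        idx = np.searchsorted(np.asarray(changes_t), times, side="right") - 1
        labels = np.asarray(changes_v, dtype=np.int8)[idx]
        traces.append(
            ResponseTrace(
                subject_id=trial.subject_id,
                trial_index=trial.trial_index,
                left_scene_id=trial.left_scene_id,
                right_scene_id=trial.right_scene_id,
                times=times,
                labels=labels,
            )
        )
    return traces


def simulate_cohort(
    profiles: dict[str, SubjectProfile],
    schedule: list[TrialSchedule],
    truths: dict[str, SceneSpec],
    seed: int = 0,
    trace_rate: float = TRACE_RATE,
) -> list[ResponseTrace]:
    """Simulate every subject in ``profiles`` over their scheduled trials."""
    seeds = np.random.SeedSequence(seed).spawn(len(profiles))
    by_subject: dict[str, list[TrialSchedule]] = {}
    for tr in schedule:
        by_subject.setdefault(tr.subject_id, []).append(tr)
    traces = []
    for (sid, profile), ss in zip(sorted(profiles.items()), seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        traces.extend(
            simulate_subject(profile, by_subject.get(sid, []), truths, seed=sub_seed,
                             trace_rate=trace_rate)
        )
    return traces
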