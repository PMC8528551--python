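import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dlsalience import behavioral as B
from dlsalience.synth import CENTER, LEFT, RIGHT, ResponseTrace
from oracles import brute_extract_events


def make_trace(labels, dt=0.1, **kw):
    labels = np.asarray(labels, dtype=np.int8)
    defaults = dict(subject_id="s", trial_index=0, left_scene_id="A", right_scene_id="B")
    defaults.update(kw)
    return ResponseTrace(times=np.arange(labels.size) * dt, labels=labels, **defaults)


def step_curve(n, step_at, dt=0.1, low=0.0, high=1.0, scene_id="x"):
    s = np.full(n, low)
    s[step_at:] = high
    return B.SalienceCurve(scene_id=scene_id, times=np.arange(n) * dt,
                           salience=s, n_subjects=np.full(n, 10))


class TestMapResponse:
    def test_side_mapping_matches_attention(self):
        tr = make_trace([RIGHT, CENTER, LEFT, RIGHT])
        assert list(B.map_response(tr, "right")) == [1, 0, 0, 1]
        assert list(B.map_response(tr, "left")) == [0, 0, 1, 0]

    def test_scene_id_accepted_in_place_of_side(self):
        tr = make_trace([RIGHT, LEFT])
        assert list(B.map_response(tr, "B")) == [1, 0]

    def test_unknown_scene_rejected(self):
        with pytest.raises(ValueError):
            B.map_response(make_trace([CENTER]), "Z")


class TestAverageSalience:
    def test_mean_across_traces(self):
        curve = B.average_salience([np.array([1.0]), np.array([0.0]), np.array([1.0])])
        assert curve.salience[0] == pytest.approx(2 / 3)

    def test_all_ones_average_to_one(self):
        curve = B.average_salience([np.ones(5)] * 4)
        assert np.all(curve.salience == 1.0)

    def test_unequal_lengths_truncate_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            curve = B.average_salience([np.ones(10), np.ones(8)])
        assert curve.salience.size == 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            B.average_salience([])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_salience_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        series = [rng.integers(0, 2, 40).astype(float) for _ in range(5)]
        curve = B.average_salience(series)
        assert curve.salience.min() >= 0 and curve.salience.max() <= 1


class TestQcFilter:
    @staticmethod
    def _trace_with_rate(n_switches, subject="s", trial=0, duration=120.0, dt=0.1):
        # piecewise-constant labels with exactly n_switches changes
        n = int(duration / dt)
        labels = np.zeros(n, dtype=np.int8)
        pos = np.linspace(1, n - 1, n_switches).astype(int)
        current = CENTER
        for k, p in enumerate(pos):
            current = LEFT if k % 2 == 0 else CENTER
            labels[p:] = current
        return make_trace(labels, dt=dt, subject_id=subject, trial_index=trial)

    def test_high_and_low_rates_flagged(self):
        high = self._trace_with_rate(130)  # 1.083/s
        low = self._trace_with_rate(2)  # 0.017/s
        ok = self._trace_with_rate(30)  # 0.25/s
        res = B.qc_filter([high, low, ok])
        assert res.rates["flagged"].tolist() == [True, True, False]

    def test_boundary_rates_kept(self):
        exactly_low = self._trace_with_rate(3)  # 0.025/s exactly
        exactly_high = self._trace_with_rate(120)  # 1.0/s exactly
        res = B.qc_filter([exactly_low, exactly_high])
        assert not res.rates["flagged"].any()

    def test_majority_flagged_subject_excluded_entirely(self):
        traces = [self._trace_with_rate(130, subject="bad", trial=t) for t in range(6)]
        traces += [self._trace_with_rate(30, subject="bad", trial=t) for t in range(6, 10)]
        traces += [self._trace_with_rate(30, subject="good", trial=t) for t in range(10)]
        res = B.qc_filter(traces)
        assert res.excluded_subjects == ["bad"]
        kept_subjects = {t.subject_id for t in res.kept}
        assert kept_subjects == {"good"}  # even the bad subject's clean trials go

    def test_half_flagged_subject_retained(self):
        traces = [self._trace_with_rate(130, subject="s", trial=t) for t in range(5)]
        traces += [self._trace_with_rate(30, subject="s", trial=t) for t in range(5, 10)]
        res = B.qc_filter(traces)
        assert res.excluded_subjects == []
        assert len(res.kept) == 5


class TestExtractEvents:
    def test_constant_curve_yields_nothing(self):
        curve = step_curve(600, 0, high=0.5, low=0.5)
        assert B.extract_events(curve) == []

    def test_clean_step_gives_one_event_at_step_minus_offset(self):
        curve = step_curve(600, 200)  # step at t = 20 s
        events = B.extract_events(curve)
        assert len(events) == 1
        assert events[0].onset == pytest.approx(19.0, abs=0.1 + 1e-9)

    def test_pruning_keeps_the_larger_of_two_steps(self):
        s = np.zeros(900)
        s[200:] = 1.0
        s[600:] = 0.3  # second (upward from 0.3? no: drop) -- build two rises
        s = np.zeros(900)
        s[200:] = 0.3
        s[600:] = 1.0
        curve = B.SalienceCurve("x", np.arange(900) * 0.1, s, np.full(900, 10))
        all_events = B.extract_events(curve, keep_frac=1.0)
        assert len(all_events) == 2
        kept = B.extract_events(curve, keep_frac=0.5)
        assert len(kept) == 1
        assert kept[0].onset == pytest.approx(59.0, abs=0.1 + 1e-9)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="smoothing support"):
            B.extract_events(step_curve(10, 5))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(12)
        base = np.clip(np.cumsum(rng.normal(0, 0.05, 400)) + 0.5, 0, 1)
        pad = np.full(100, base[0])
        tail = np.full(100, base[-1])
        a = np.concatenate([pad, base, tail, tail])
        b = np.concatenate([pad, pad, base, tail])  # shifted by 10 s
        dt = 0.1
        ca = B.SalienceCurve("a", np.arange(a.size) * dt, a, np.full(a.size, 5))
        cb = B.SalienceCurve("b", np.arange(b.size) * dt, b, np.full(b.size, 5))
        ea = B.extract_events(ca, keep_frac=1.0)
        eb = B.extract_events(cb, keep_frac=1.0)
        assert len(ea) == len(eb) > 0
        for x, y in zip(ea, eb):
            assert y.onset - x.onset == pytest.approx(10.0, abs=1e-9)
            assert y.slope_peak == pytest.approx(x.slope_peak, rel=1e-9)

    def test_matches_brute_force_oracle_on_random_curves(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(300, 800))
            s = np.clip(np.cumsum(rng.normal(0, 0.08, n)) % 1.2, 0, 1)
            curve = B.SalienceCurve("x", np.arange(n) * 0.1, s, np.full(n, 8))
            got = B.extract_events(curve)
            want = brute_extract_events(np.arange(n) * 0.1, s)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.onset == pytest.approx(w[0], abs=1e-9)
                assert g.slope_peak == pytest.approx(w[1], rel=1e-9)
                assert g.strength == pytest.approx(w[2], rel=1e-9)

    def test_dataset_pruning_modes(self):
        strong = step_curve(600, 300, scene_id="strong")
        weak = step_curve(600, 300, high=0.05, scene_id="weak")
        per_scene = B.extract_events_dataset(
            {"strong": strong, "weak": weak}, pruning="per_scene"
        )
        pooled = B.extract_events_dataset({"strong": strong, "weak": weak})
        assert len(per_scene["weak"]) == 1  # survives within its own scene
        assert len(pooled["weak"]) == 0  # pruned against the strong scene
        assert len(pooled["strong"]) == 1
        with pytest.raises(ValueError):
            B.extract_events_dataset({"strong": strong}, pruning="scene")


class TestReactionTimes:
    def _trace_switching_at(self, t_switch, duration=20.0, dt=0.1):
        n = int(duration / dt)
        labels = np.zeros(n, dtype=np.int8)
        labels[int(t_switch / dt):] = LEFT
        return make_trace(labels, dt=dt)

    def test_switch_inside_window_yields_rt(self):
        tr = self._trace_switching_at(10.8)
        assert B.reaction_times(tr, "left", [10.0]) == [pytest.approx(0.8)]

    def test_switch_before_window_ignored(self):
        tr = self._trace_switching_at(10.3)
        assert B.reaction_times(tr, "left", [10.0]) == []

    def test_switch_after_window_ignored(self):
        tr = self._trace_switching_at(12.0)
        assert B.reaction_times(tr, "left", [10.0]) == []


class TestSubjectFscore:
    def test_partial_overlap(self):
        res = B.subject_fscore(np.array([10.2, 30.5]), np.array([10.0, 50.0]))
        assert res.precision == pytest.approx(0.5)
        assert res.recall == pytest.approx(0.5)
        assert res.fscore == pytest.approx(0.5)

    def test_identical_sets_score_one(self):
        res = B.subject_fscore(np.array([1.0, 5.0]), np.array([1.0, 5.0]))
        assert res.fscore == pytest.approx(1.0)

    def test_disjoint_sets_floored_near_zero(self):
        res = B.subject_fscore(np.array([1.0]), np.array([50.0]))
        assert 0 < res.fscore < 1e-5


class TestSegments:
    def test_two_minute_scene_has_477_segments(self):
        assert B.segment_starts(120.0).size == 477

    def test_half_open_membership(self):
        starts = B.segment_starts(120.0)
        labels = B.label_segments(starts, np.array([10.0]))
        labeled = starts[labels == 1]
        assert list(labeled) == [9.25, 9.5, 9.75, 10.0]


class TestInterobserver:
    def test_perfectly_aligned_switches_give_unit_auroc(self):
        dt = 0.1
        n = 1200
        times = np.arange(n) * dt
        onsets = [20.0, 60.0, 90.0]
        mapped = np.zeros(n)
        for onset in onsets:
            i = int((onset + 1.0) / dt)  # switch one reaction time after onset
            mapped[i:i + 30] = 1
        responses = {"x": [(times, mapped)] * 10}
        res = B.interobserver_auroc(responses, {"x": np.array(onsets)})
        assert res.auroc == pytest.approx(1.0)

    def test_uniform_random_switches_sit_at_chance(self):
        rng = np.random.default_rng(7)
        dt = 0.1
        n = 1200
        times = np.arange(n) * dt
        aurocs = []
        for _ in range(50):
            responses = []
            for _ in range(20):
                mapped = np.zeros(n)
                for t in rng.uniform(2, 118, size=8):
                    i = int(t / dt)
                    mapped[i:i + 20] = 1
                responses.append((times, mapped))
            events = np.sort(rng.uniform(2, 115, size=10))
            res = B.interobserver_auroc({"x": responses}, {"x": events})
            aurocs.append(res.auroc)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.03)

    def test_eventless_scene_contributes_only_negatives(self):
        dt = 0.1
        times = np.arange(1200) * dt
        rng = np.random.default_rng(3)
        noisy = [(times, (rng.random(1200) < 0.01).astype(float)) for _ in range(5)]
        aligned = np.zeros(1200)
        aligned[110:140] = 1
        responses = {"ev": [(times, aligned)] * 5, "none": noisy}
        res = B.interobserver_auroc(responses, {"ev": np.array([10.0]), "none": []})
        assert 0 <= res.auroc <= 1


class TestCurveCorrelation:
    def test_self_correlation_is_one(self):
        c = step_curve(100, 40)
        assert B.curve_correlation(c, c) == pytest.approx(1.0)

    def test_negated_fluctuation_gives_minus_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        a = B.SalienceCurve("a", np.arange(200) * 0.1, s, np.full(200, 3))
        b = B.SalienceCurve("b", np.arange(200) * 0.1, 2 * s.mean() - s, np.full(200, 3))
        assert B.curve_correlation(a, b) == pytest.approx(-1.0)

    def test_zero_variance_flagged_as_nan(self):
        flat = step_curve(100, 0, low=0.5, high=0.5)
        wiggly = step_curve(100, 50)
        assert np.isnan(B.curve_correlation(flat, wiggly))

    def test_independent_noise_rarely_correlates(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            a = B.SalienceCurve("a", np.arange(1000) * 0.1, rng.random(1000), np.full(1000, 3))
            b = B.SalienceCurve("b", np.arange(1000) * 0.1, rng.random(1000), np.full(1000, 3))
            if abs(B.curve_correlation(a, b)) < 0.1:
                hits += 1
        assert hits >= 0.95 * 40 - 2


class TestLeaveOneOutFscores:
    def test_identical_subjects_agree_perfectly_and_noise_falls_below(self):
        dt = 0.1
        n = 1200
        times = np.arange(n) * dt
        onsets = [15.0, 45.0, 75.0, 105.0]
        aligned = np.zeros(n)
        for onset in onsets:
            i = int((onset + 1.0) / dt)
            aligned[i:i + 40] = 1
        subjects = [aligned.copy() for _ in range(12)]
        rng = np.random.default_rng(5)

        def loo_fscore(k, series):
            rest = [s for j, s in enumerate(series) if j != k]
            curve = B.average_salience(rest, dt=dt)
            # constructed curves are noise-free, so no pruning is needed
            ref = [e.onset for e in B.extract_events(curve, keep_frac=1.0)]
            own = B.toward_switch_times(times, series[k]) - 1.0
            return B.subject_fscore(own, np.array(ref)).fscore

        identical = [loo_fscore(k, subjects) for k in range(len(subjects))]
        assert min(identical) == pytest.approx(1.0)

        noise_subject = (rng.random(n) < 0.005).astype(float)
        mixed = subjects[:-1] + [noise_subject]
        noisy_score = loo_fscore(len(mixed) - 1, mixed)
        assert noisy_score < np.percentile(identical, 5)
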