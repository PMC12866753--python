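import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sleepgeom.scoring import (
    Hypnogram,
    SpindleEvents,
    _em_fit,
    _merge_short,
    awakening_stats,
    bimodal_threshold,
    detect_spindles,
    event_related_power,
    score_session,
)
from sleepgeom.synthetic import PhysioRecord


def truth_hypnogram(truth):
    return Hypnogram(intervals=[
        (row.start_s, row.end_s, row.state)
        for row in truth.block_table.itertuples()
    ])


class TestBimodalThreshold:
    def test_equal_variance_symmetric_intersection(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 3000), rng.normal(10, 1, 3000)])
        thr, ok = bimodal_threshold(x)
        assert ok
        assert thr == pytest.approx(5.0, abs=0.3)

    def test_unequal_variance_matches_grid_oracle(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 4000), rng.normal(6, 2, 4000)])
        thr, ok = bimodal_threshold(x)
        assert ok
        # oracle: brute-force root of the unit-area density equality between
        # the fitted means
        gm = _em_fit(x)
        (m1,), (m2,) = gm.means_
        s1, s2 = np.sqrt(gm.covariances_.ravel())
        if m1 > m2:
            m1, m2, s1, s2 = m2, m1, s2, s1
        grid = np.linspace(m1, m2, 200001)
        oracle = grid[np.argmin(np.abs(norm.pdf(grid, m1, s1) - norm.pdf(grid, m2, s2)))]
        assert thr == pytest.approx(oracle, abs=1e-3)

    def test_unimodal_flagged(self):
        rng = np.random.default_rng(2)
        _, ok = bimodal_threshold(rng.normal(0, 1, 2000))
        assert not ok

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bimodal_threshold(np.full(500, 3.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bimodal_threshold(np.arange(50, dtype=float))


class TestScoreSession:
    def test_agreement_with_truth(self, scoring_session):
        _, raster, _, truth, physio = scoring_session
        hyp = score_session(physio)
        times = raster.frame_times()
        hi = hyp.span[1]
        pred = np.array([hyp.state_at(min(t, hi - 1e-9)) for t in times])
        assert (pred == truth.state_sequence).mean() >= 0.95

    def test_all_wake_single_interval(self):
        from sleepgeom.config import SessionConfig
        from sleepgeom.synthetic import generate_physio, generate_session
        cfg = SessionConfig(n_neurons=5, n_sounds=2, presentations_per_sound_per_state=4,
                            states=("wake",), n_silence_blocks=1, block_duration=60.0,
                            spont_rank=0, seed=8)
        _, _, truth = generate_session(cfg)
        hyp = score_session(generate_physio(cfg, truth))
        assert len(hyp.intervals) == 1
        assert hyp.intervals[0][2] == "wake"

    def test_short_rem_islet_merged(self):
        merged = _merge_short([(0.0, 10.0, "nrem"), (10.0, 12.0, "rem"),
                               (12.0, 20.0, "nrem")])
        assert merged == [(0.0, 20.0, "nrem")]

    def test_merge_prefers_longer_neighbor(self):
        merged = _merge_short([(0.0, 4.0, "nrem"), (4.0, 6.0, "rem"),
                               (6.0, 16.0, "nrem")])
        assert merged == [(0.0, 16.0, "nrem")]

    def test_affine_rescaling_invariance(self, scoring_session):
        _, _, _, _, physio = scoring_session
        hyp1 = score_session(physio)
        scaled = PhysioRecord(
            channels={**physio.channels, "emg": 3.7 * physio.channels["emg"] + 2.0},
            rate=physio.rate)
        hyp2 = score_session(scaled)
        assert len(hyp1.intervals) == len(hyp2.intervals)
        for (s1, e1, st1), (s2, e2, st2) in zip(hyp1.intervals, hyp2.intervals):
            assert st1 == st2
            assert abs(s1 - s2) < 0.5 and abs(e1 - e2) < 0.5

    def test_missing_channel_rejected(self):
        rng = np.random.default_rng(0)
        physio = PhysioRecord(channels=dict(emg=rng.normal(size=125000)), rate=1250.0)
        with pytest.raises(ValueError, match="missing"):
            score_session(physio)

    def test_short_signal_rejected(self):
        rng = np.random.default_rng(0)
        physio = PhysioRecord(
            channels=dict(emg=rng.normal(size=1250), hpc=rng.normal(size=1250)),
            rate=1250.0)
        with pytest.raises(ValueError, match="60 s"):
            score_session(physio)


class TestHypnogram:
    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            Hypnogram(intervals=[(0.0, 10.0, "wake"), (11.0, 20.0, "nrem")])

    def test_half_open_state_lookup(self):
        hyp = Hypnogram(intervals=[(0.0, 10.0, "wake"), (10.0, 20.0, "nrem")])
        assert hyp.state_at(10.0) == "nrem"
        assert hyp.state_at(9.999) == "wake"
        with pytest.raises(ValueError):
            hyp.state_at(20.0)


class TestAwakeningStats:
    def test_no_wake_probability_zero(self):
        hyp = Hypnogram(intervals=[(0.0, 100.0, "nrem")])
        trials = pd.DataFrame(dict(trial_id=[0], onset_s=[50.0]))
        stats = awakening_stats(hyp, trials)
        assert stats["sound_evoked_awakening_prob"] == 0.0
        assert stats["awakening_rate"] == 0.0

    def test_hand_built_half(self):
        hyp = Hypnogram(intervals=[(0.0, 10.0, "nrem"), (10.0, 20.0, "wake")])
        trials = pd.DataFrame(dict(trial_id=[0, 1], onset_s=[9.5, 2.0]))
        stats = awakening_stats(hyp, trials)
        assert stats["sound_evoked_awakening_prob"] == 0.5
        assert stats["awakening_rate"] == pytest.approx(1 / 20)

    def test_no_sleep_onsets_flagged(self):
        hyp = Hypnogram(intervals=[(0.0, 20.0, "wake")])
        trials = pd.DataFrame(dict(trial_id=[0], onset_s=[5.0]))
        stats = awakening_stats(hyp, trials)
        assert not stats["defined"]
        assert np.isnan(stats["sound_evoked_awakening_prob"])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        edges = np.concatenate([[0.0], np.sort(rng.uniform(0, 1000, 40)), [1000.0]])
        states = rng.choice(["wake", "nrem", "rem"], size=len(edges) - 1)
        hyp = Hypnogram(intervals=[(edges[i], edges[i + 1], states[i])
                                   for i in range(len(states))])
        onsets = np.sort(rng.uniform(0, 999, 1000))
        trials = pd.DataFrame(dict(trial_id=np.arange(1000), onset_s=onsets))
        stats = awakening_stats(hyp, trials)

        # independent loop oracle
        transitions = []
        for i in range(len(states) - 1):
            if states[i] in ("nrem", "rem") and states[i + 1] == "wake":
                transitions.append(edges[i + 1])

        def state_of(t):
            for i in range(len(states)):
                if edges[i] <= t < edges[i + 1]:
                    return states[i]

        n_sleep, hits = 0, 0
        for t in onsets:
            if state_of(t) in ("nrem", "rem"):
                n_sleep += 1
                if any(t < tr <= t + 1.0 for tr in transitions):
                    hits += 1
        assert stats["awakening_rate"] == len(transitions) / 1000.0
        assert stats["sound_evoked_awakening_prob"] == hits / n_sleep


class TestDetectSpindles:
    rate = 1250.0

    def _background(self, seed=0, duration=60.0):
        rng = np.random.default_rng(seed)
        return rng.normal(0, 0.5, int(duration * self.rate))

    def _burst(self, x, start, duration, amp):
        i0 = int(start * self.rate)
        n = int(duration * self.rate)
        t = np.arange(n) / self.rate
        x[i0:i0 + n] += amp * np.sin(2 * np.pi * 12.0 * t)

    def _hyp(self, duration=60.0):
        return Hypnogram(intervals=[(0.0, duration, "nrem")])

    def test_injected_burst_detected(self):
        x = self._background()
        sigma_sd = 0.5 * np.sqrt(10 / (self.rate / 2))  # rough in-band SD
        self._burst(x, 5.0, 1.0, 5 * sigma_sd * 10)
        events = detect_spindles(x, self.rate, self._hyp())
        overlapping = [e for e in events.events if e[0] < 6.0 and e[1] > 5.0]
        assert len(overlapping) == 1
        assert len(events.events) == 1

    def test_short_burst_discarded(self):
        x = self._background(1)
        self._burst(x, 5.0, 0.3, 5.0)
        events = detect_spindles(x, self.rate, self._hyp())
        assert events.events == []

    def test_close_bursts_merged(self):
        x = self._background(2)
        self._burst(x, 5.0, 0.5, 5.0)
        self._burst(x, 5.65, 0.5, 5.0)  # 150 ms gap -> merged
        events = detect_spindles(x, self.rate, self._hyp())
        assert len(events.events) == 1
        s, e = events.events[0]
        assert s < 5.1 and e > 6.0

    def test_no_nrem_flagged_empty(self):
        x = self._background(3)
        hyp = Hypnogram(intervals=[(0.0, 60.0, "wake")])
        events = detect_spindles(x, self.rate, hyp)
        assert events.events == [] and events.no_nrem

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_spindles(np.zeros(100), 50.0, self._hyp())

    def test_event_invariants(self, scoring_session):
        _, _, _, truth, physio = scoring_session
        events = detect_spindles(physio["ac"], physio.rate, truth_hypnogram(truth))
        SpindleEvents(events=events.events)  # invariants re-validated


class TestEventRelatedPower:
    rate = 1250.0

    def _physio(self, trials, nr_scale, seed=0):
        rng = np.random.default_rng(seed)
        duration = trials.onset_s.max() + 5.0
        n = int(duration * self.rate)
        from sleepgeom.signal import bandpass
        sigma = bandpass(rng.normal(size=n), self.rate, (10.0, 15.0))
        scale = np.ones(n)
        for row in trials.itertuples():
            if row.label == "non-responsive":
                i0 = int((row.onset_s - 1.0) * self.rate)
                i1 = int((row.onset_s + 1.5) * self.rate)
                scale[i0:i1] = nr_scale
        ac = sigma * scale + 0.1 * rng.normal(size=n)
        return PhysioRecord(channels=dict(ac=ac), rate=self.rate)

    def _trials(self, n=40):
        onsets = 5.0 + 4.0 * np.arange(n)
        labels = np.where(np.arange(n) % 2 == 0, "responsive", "non-responsive")
        t = pd.DataFrame(dict(trial_id=np.arange(n), onset_s=onsets,
                              duration_s=0.5, label=labels))
        return t

    def test_identical_statistics_contrast_zero(self):
        trials = self._trials(120)
        physio = self._physio(trials, nr_scale=1.0)
        res = event_related_power(physio, trials.drop(columns="label"),
                                  trials[["trial_id", "label"]], band=(10.0, 15.0))
        assert abs(res["contrast"]) < 0.15

    def test_doubled_power_contrast_one(self):
        trials = self._trials(60)
        physio = self._physio(trials, nr_scale=np.sqrt(2.0))
        res = event_related_power(physio, trials.drop(columns="label"),
                                  trials[["trial_id", "label"]], band=(10.0, 15.0))
        assert res["contrast"] == pytest.approx(1.0, abs=0.2)

    def test_no_spindles_probability_zero(self):
        trials = self._trials()
        physio = self._physio(trials, nr_scale=1.0)
        res = event_related_power(physio, trials.drop(columns="label"),
                                  trials[["trial_id", "label"]], band=(10.0, 15.0),
                                  spindles=SpindleEvents(events=[]))
        assert np.all(res["spindle_prob"] == 0)

    def test_empty_class_rejected(self):
        trials = self._trials()
        trials["label"] = "responsive"
        physio = self._physio(trials, nr_scale=1.0)
        with pytest.raises(ValueError):
            event_related_power(physio, trials.drop(columns="label"),
                                trials[["trial_id", "label"]], band=(10.0, 15.0))
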