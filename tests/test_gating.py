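import numpy as np
import pandas as pd
import pytest

from sleepgeom.config import SessionConfig
from sleepgeom.gating import build_templates, gating_summary, label_trials
from sleepgeom.responses import ResponseMatrix, extract_responses
from sleepgeom.synthetic import generate_session


def manual_resp(responses, baselines=None, ids=None):
    responses = np.asarray(responses, dtype=float)
    if baselines is None:
        baselines = np.zeros_like(responses)
    if ids is None:
        ids = np.arange(len(responses))
    return ResponseMatrix(responses=responses, baselines=baselines,
                          window=(0.0, 0.75), trial_ids=np.asarray(ids))


class TestBuildTemplates:
    def test_top_30pct_of_ten_trials(self):
        rng = np.random.default_rng(0)
        responses = rng.uniform(0, 1, (10, 5)) + np.arange(10)[:, None]
        resp = manual_resp(responses)
        trials = pd.DataFrame(dict(trial_id=np.arange(10), sound_id=0, state="wake"))
        templates = build_templates(resp, trials, n_sounds=1)
        # ceil(0.3 * 10) = 3 strongest trials (largest population mean)
        expected = responses[[9, 8, 7]].mean(axis=0)
        np.testing.assert_allclose(templates[0], expected)

    def test_identical_trials_template_equals_any(self):
        responses = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        resp = manual_resp(responses)
        trials = pd.DataFrame(dict(trial_id=np.arange(6), sound_id=0, state="wake"))
        templates = build_templates(resp, trials, n_sounds=1)
        np.testing.assert_allclose(templates[0], responses[0])

    def test_noise_free_template_proportional_to_tuning(self, noisefree_session):
        raster, trials, truth = noisefree_session
        resp = extract_responses(raster, trials)
        templates = build_templates(resp, trials, n_sounds=2)
        for sound, tpl in templates.items():
            col = truth.tuning[:, sound]
            cos = tpl @ col / (np.linalg.norm(tpl) * np.linalg.norm(col))
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_keeps_strongest_sounds_only(self, wake_session):
        _, _, trials, _, resp = wake_session
        templates = build_templates(resp, trials, n_sounds=3)
        assert len(templates) == 3


class TestLabelTrials:
    def test_positive_trial_is_responsive(self):
        rng = np.random.default_rng(1)
        template_trials = rng.uniform(1.0, 2.0, (10, 200))
        resp = manual_resp(template_trials)
        trials = pd.DataFrame(dict(trial_id=np.arange(10), sound_id=0, state="wake"))
        templates = build_templates(resp, trials, n_sounds=1)
        labels = label_trials(resp, trials, templates, seed=0)
        assert (labels.label == "responsive").all()

    def test_noise_orthogonal_trials_nonresponsive(self):
        rng = np.random.default_rng(2)
        template = rng.uniform(1.0, 2.0, 200)
        noise_trials = rng.standard_normal((100, 200))
        resp = manual_resp(noise_trials)
        trials = pd.DataFrame(dict(trial_id=np.arange(100), sound_id=0, state="nrem"))
        labels = label_trials(resp, trials, {0: template}, seed=5)
        assert (labels.label == "non-responsive").mean() >= 0.85

    def test_deterministic(self, wake_session):
        _, _, trials, _, resp = wake_session
        templates = build_templates(resp, trials, n_sounds=3)
        l1 = label_trials(resp, trials, templates, seed=11)
        l2 = label_trials(resp, trials, templates, seed=11)
        pd.testing.assert_frame_equal(l1, l2)

    def test_zero_vector_nonresponsive_by_convention(self):
        responses = np.vstack([np.zeros(50), np.ones(50)])
        resp = manual_resp(responses)
        trials = pd.DataFrame(dict(trial_id=[0, 1], sound_id=0, state="wake"))
        labels = label_trials(resp, trials, {0: np.ones(50)}, seed=0)
        assert labels.loc[labels.trial_id == 0, "label"].iloc[0] == "non-responsive"

    def test_scale_invariance(self, wake_session):
        _, _, trials, _, resp = wake_session
        templates = build_templates(resp, trials, n_sounds=3)
        base = label_trials(resp, trials, templates, seed=7)
        scaled = ResponseMatrix(responses=3.0 * resp.responses,
                                baselines=3.0 * resp.baselines,
                                window=resp.window, trial_ids=resp.trial_ids)
        tpl_scaled = {s: 3.0 * t for s, t in templates.items()}
        res = label_trials(scaled, trials, tpl_scaled, seed=7)
        assert (base.label == res.label).all()

    def test_zero_template_rejected(self):
        resp = manual_resp(np.ones((4, 10)))
        trials = pd.DataFrame(dict(trial_id=np.arange(4), sound_id=0, state="wake"))
        with pytest.raises(ValueError):
            label_trials(resp, trials, {0: np.zeros(10)}, seed=0)


class TestGatingSummary:
    def _session(self, gate_nrem, gate_wake=0.0, seed=21):
        cfg = SessionConfig(n_neurons=120, n_sounds=10, presentations_per_sound_per_state=12,
                            gate_prob_nrem=gate_nrem, gate_prob_wake=gate_wake,
                            noise_sd=1.0, spont_amp=1.0, burst_amp=0.0,
                            n_silence_blocks=1, seed=seed)
        raster, trials, truth = generate_session(cfg)
        resp = extract_responses(raster, trials)
        templates = build_templates(resp, trials, n_sounds=10)
        labels = label_trials(resp, trials, templates, seed=seed)
        return resp, trials, truth, templates, labels

    def test_planted_fractions_recovered(self):
        resp, trials, truth, templates, labels = self._session(0.17, 0.078)
        summary = gating_summary(labels, resp, trials, templates, seed=0)
        for state, p in (("nrem", 0.17), ("wake", 0.078)):
            n = (labels.state == state).sum()
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(summary["fraction_nonresponsive"][state] - p) < 3 * sd

    def test_false_positive_rate_low_without_gating(self):
        resp, trials, _, templates, labels = self._session(0.0, 0.0, seed=2)
        summary = gating_summary(labels, resp, trials, templates, seed=0)
        for frac in summary["fraction_nonresponsive"].values():
            assert frac <= 0.05

    def test_fraction_monotone_in_gate_probability(self):
        fracs = []
        for p in (0.05, 0.2, 0.4):
            _, _, _, _, labels = self._session(p, 0.0, seed=33)
            fracs.append((labels[labels.state == "nrem"].label == "non-responsive").mean())
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_nonresponsive_amplitude_near_zero(self):
        resp, trials, _, templates, labels = self._session(0.25, 0.0, seed=3)
        summary = gating_summary(labels, resp, trials, templates, seed=0)
        amp = summary["amplitude"].set_index(["state", "label"]).mean_amplitude
        resp_amp = amp.loc[("nrem", "responsive")]
        nr_amp = amp.loc[("nrem", "non-responsive")]
        assert abs(nr_amp) < 0.15 * resp_amp

    def test_shuffle_control_separates_coordinated_gating(self):
        rng = np.random.default_rng(4)
        n_neurons, n_trials = 150, 120
        template = rng.uniform(0.5, 2.0, n_neurons)
        gated = rng.random(n_trials) < 0.3

        coord = np.where(gated[:, None], 0.0, template[None, :])
        coord = coord + 0.3 * rng.standard_normal(coord.shape)
        indep_mask = rng.random((n_trials, n_neurons)) < 0.3
        indep = np.where(indep_mask, 0.0, template[None, :])
        indep = indep + 0.3 * rng.standard_normal(indep.shape)

        trials = pd.DataFrame(dict(trial_id=np.arange(n_trials), sound_id=0,
                                   state="nrem"))
        out = {}
        for name, mat in (("coord", coord), ("indep", indep)):
            resp = manual_resp(mat)
            labels = label_trials(resp, trials, {0: template}, seed=1)
            summary = gating_summary(labels, resp, trials, {0: template}, seed=1)
            obs = np.asarray(summary["observed_cosine"]["nrem"])
            shuf = np.asarray(summary["shuffled_cosine"]["nrem"])
            out[name] = ((obs < 0.5).mean(), (shuf < 0.5).mean())
        obs_low, shuf_low = out["coord"]
        assert obs_low - shuf_low > 0.1          # shuffling hides coordination
        obs_low_i, shuf_low_i = out["indep"]
        assert abs(obs_low_i - shuf_low_i) < 0.05  # nothing to hide
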