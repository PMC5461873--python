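"""Cross-level scheduling: empirical priors down, probabilistic evidence
up, entropy-based termination, and full asynchronous trials."""

import numpy as np
import pytest

from actinf._math import entropy_nats, one_hot
from actinf.engine import init_beliefs
from actinf.model import InitialLink, LinkMap
from actinf.reading import ReadingConfig, build_reading_model, sample_stimuli
from actinf.experiments import reading_trial, trial_summary
from actinf.scheduler import (TerminationRule, ascend_evidence,
                              check_termination, descend_priors, run_trial)


class TestDescendPriors:
    def test_delta_beliefs_pick_the_link_column(self, rng):
        table = rng.dirichlet(np.ones(3), size=4).T      # (3 states, 4 parents)
        link = InitialLink(0, table, parent_factors=(0,))
        got = descend_priors([one_hot(2, 4)], [link])[0]
        assert np.allclose(got, table[:, 2])

    def test_uniform_sentences_support_flee_or_wait(self, reading_model):
        top = reading_model.levels[1]
        bma = [np.full(6, 1 / 6), one_hot(0, 4), one_hot(0, 3)]
        priors = descend_priors(bma, reading_model.levels[0].D)
        word_prior = priors[0]
        from actinf.reading import WORDS
        assert word_prior[WORDS.index("feed")] == 0.0
        assert word_prior[WORDS.index("flee")] > 0
        assert word_prior[WORDS.index("wait")] > 0
        assert word_prior.sum() == pytest.approx(1.0)

    def test_matches_direct_weighted_sum(self, rng):
        table = np.stack([rng.dirichlet(np.ones(2)) for _ in range(2)], axis=1)
        link = InitialLink(0, table, parent_factors=(0,))
        w = rng.dirichlet(np.ones(2))
        got = descend_priors([w], [link])[0]
        assert np.allclose(got, table @ w)


class TestAscendEvidence:
    def test_delta_and_uniform_pass_through(self, reading_model):
        level = reading_model.levels[0]
        link = LinkMap(evidence_factor=0, evidence_modality=0)
        bs = init_beliefs(level, priors=[np.full(3, 1 / 3), one_hot(0, 4),
                                         np.array([.875, .125]),
                                         np.array([.5, .5])])
        bs.n_observed = 1
        bs.s_bar[0][0] = one_hot(0, 3)
        assert np.allclose(ascend_evidence(bs, link), one_hot(0, 3))
        bs.s_bar[0][0] = np.full(3, 1 / 3)
        assert np.allclose(ascend_evidence(bs, link), np.full(3, 1 / 3))

    def test_before_any_observation_raises(self, reading_model):
        level = reading_model.levels[0]
        bs = init_beliefs(level, priors=[one_hot(0, 3), one_hot(0, 4),
                                         np.array([.875, .125]),
                                         np.array([.5, .5])])
        with pytest.raises(RuntimeError, match="not processed"):
            ascend_evidence(bs, LinkMap(0, 0))


class TestTermination:
    def _beliefs(self, posterior, reading_model):
        level = reading_model.levels[0]
        bs = init_beliefs(level, priors=[np.full(3, 1 / 3), one_hot(0, 4),
                                         np.array([.875, .125]),
                                         np.array([.5, .5])])
        bs.n_observed = 1
        bs.s_bar[0][0] = np.asarray(posterior, dtype=float)
        return bs

    def test_delta_always_terminates(self, reading_model):
        bs = self._beliefs(one_hot(1, 3), reading_model)
        assert check_termination(bs, TerminationRule(1e-9))

    def test_uniform_does_not(self, reading_model):
        bs = self._beliefs(np.full(3, 1 / 3), reading_model)
        assert not check_termination(bs, TerminationRule(1 / 512))

    def test_near_delta_entropy_threshold(self, reading_model):
        p = np.array([.999, .001, 0.0])
        assert entropy_nats(p) == pytest.approx(0.0079, abs=2e-4)
        bs = self._beliefs(p, reading_model)
        assert check_termination(bs, TerminationRule(0.01))
        assert not check_termination(bs, TerminationRule(0.001))

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            TerminationRule(0.0)


class TestExemplarTrial:
    def test_saccade_counts_decision_and_feedback(self, exemplar_summary):
        assert exemplar_summary["word_transitions"] == 4
        assert exemplar_summary["saccades_per_word"] == [1, 2, 2, 2]
        assert exemplar_summary["decision"] == "report happy"
        assert exemplar_summary["feedback"] == "right"

    def test_exactly_one_decision_action(self, exemplar_record):
        reports = [u for u in exemplar_record.top_actions if u != 0]
        assert len(reports) == 1
        assert exemplar_record.decision == 1

    def test_deterministic_rerun(self, exemplar_record, config):
        again = reading_trial(config, seed=0)
        assert again.top_actions == exemplar_record.top_actions
        assert again.saccade_log == exemplar_record.saccade_log
        for a, b in zip(again.traces, exemplar_record.traces):
            for x, y in zip(a.s0, b.s0):
                assert np.array_equal(x, y)

    def test_infinite_threshold_one_saccade_per_word(self, config):
        rec = reading_trial(config, seed=0, threshold_nats=np.inf)
        summary = trial_summary(rec, config)
        assert summary["saccades_per_word"] == [1, 1, 1, 1]

    def test_timestamps_strictly_increasing_and_asynchronous(self, exemplar_record):
        ms = np.concatenate([t.ms for t in exemplar_record.traces])
        assert np.allclose(np.diff(ms), exemplar_record.ms_per_iteration)
        spans = [(e.start_ms, e.start_ms + e.n_iter * 16.0, e.level_id)
                 for e in exemplar_record.epochs]
        for (a0, a1, la), (b0, b1, lb) in zip(spans, spans[1:]):
            assert a1 <= b0 + 1e-9       # no overlap: levels never co-iterate

    def test_probability_conserved_at_every_interface(self, exemplar_record):
        for t, res in exemplar_record.lower_runs:
            for p in res.beliefs.priors:
                assert p.min() >= 0 and p.sum() == pytest.approx(1.0)
            for sb in res.beliefs.s_bar:
                assert np.allclose(sb.sum(axis=-1), 1.0)
        for obs in exemplar_record.top_observed:
            for o in obs:
                if o is not None:
                    assert o.sum() == pytest.approx(1.0)

    def test_replay_under_unchanged_model_reproduces_trial(self, config,
                                                           exemplar_record):
        rep = reading_trial(config, seed=0, replay=exemplar_record)
        assert rep.top_actions == exemplar_record.top_actions
        assert rep.feedback == exemplar_record.feedback
        for a, b in zip(rep.traces, exemplar_record.traces):
            for x, y in zip(a.s0, b.s0):
                assert np.allclose(x, y, atol=1e-12)


class TestEpistemicSufficiency:
    def test_correct_feedback_implies_correct_sentence(self, config):
        """Whenever the agent is told it is right, its modal sentence
        belief matches the truth: it never reports while uncertain."""
        n_right = 0
        for seed in range(25):
            stimuli = sample_stimuli(config, seed=seed)
            rec = reading_trial(config, seed=seed, stimuli=stimuli)
            if rec.feedback == 1:       # "right"
                n_right += 1
                t = rec.decision_time
                posterior = rec.top_beliefs.s_bar[0][t]
                assert int(np.argmax(posterior)) == stimuli.top_states[0]
        assert n_right >= 15            # the subject mostly succeeds
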