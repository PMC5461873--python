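"""Belief updating: prediction errors, free energies, policy selection,
and equivalence with exact enumeration on small models."""

import numpy as np
import pytest

from actinf._math import one_hot
from actinf.engine import (NumericalDivergenceError, bma_states,
                           expected_free_energy, init_beliefs,
                           outcome_prediction_error, policy_free_energy,
                           policy_posterior, select_action,
                           state_prediction_error, update_epoch)
from actinf.experiments import validate_engine
from actinf.model import (InitialLink, LevelModel, LikelihoodArray, Policy,
                          PreferenceArray, TransitionArray)


def single_factor_level(A, D, C=None, horizon=1, n_policies=1):
    S = len(D)
    O = np.asarray(A).shape[0]
    return LevelModel(
        factors=[S], modalities=[O],
        A=[LikelihoodArray(0, np.asarray(A, dtype=float))],
        B=[TransitionArray(0, np.stack([np.eye(S)] * max(n_policies, 1)))],
        C=[PreferenceArray(0, np.zeros(O) if C is None else np.asarray(C, float))],
        D=[InitialLink(0, np.asarray(D, dtype=float))],
        policies=[Policy(i, [i]) for i in range(max(n_policies, 1))],
        horizon=horizon)


TWO_STATE = dict(A=[[.9, .2], [.1, .8]], D=[.5, .5])


class TestStatePredictionError:
    def test_degenerate_single_state_is_zero(self):
        level = single_factor_level(A=[[1.0]], D=[1.0])
        bs = init_beliefs(level)
        bs.n_observed = 1
        err = state_prediction_error(level, bs, 0, 0, [[one_hot(0, 1)]])
        assert np.allclose(err[0], 0.0)

    def test_uniform_model_is_zero(self):
        level = single_factor_level(A=np.full((3, 2), 1 / 3), D=[.5, .5])
        bs = init_beliefs(level)
        bs.n_observed = 1
        err = state_prediction_error(level, bs, 0, 0, [[one_hot(1, 3)]])
        assert np.allclose(err[0], 0.0, atol=1e-12)

    def test_vanishes_at_exact_posterior(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        obs = [[one_hot(0, 2)]]
        update_epoch(level, bs, obs, n_iterations=256)
        err = state_prediction_error(level, bs, 0, 0, obs)
        assert np.abs(err[0]).max() < 1e-6

    def test_tau_out_of_range(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        with pytest.raises(IndexError):
            state_prediction_error(level, bs, 0, 5, [])


class TestOracleEquivalence:
    """The converged posterior matches exact Bayes on static models."""

    def test_two_state_posterior(self):
        level = single_factor_level(**TWO_STATE)
        exact = np.array([.45, .10]) / .55
        bs = init_beliefs(level)
        update_epoch(level, bs, [[one_hot(0, 2)]], n_iterations=16)
        assert np.abs(bs.s_bar[0][0] - exact).max() < 1e-2
        bs = init_beliefs(level)
        update_epoch(level, bs, [[one_hot(0, 2)]], n_iterations=128)
        assert np.abs(bs.s_bar[0][0] - exact).max() < 1e-4

    def test_hundred_random_micro_models(self, validation_report):
        assert validation_report["max_posterior_error"] < 1e-2

    def test_excessive_step_size_breaks_descent(self):
        report = validate_engine(n_models=20, seed=3, kappa=10.0)
        assert report["descent_violations"] > 0 and not report["ok"]


class TestPolicyFreeEnergy:
    def test_degenerate_model_zero(self):
        level = single_factor_level(A=[[1.0]], D=[1.0])
        bs = init_beliefs(level)
        bs.n_observed = 1
        assert policy_free_energy(level, bs, 0, [[one_hot(0, 1)]]) == pytest.approx(
            0.0, abs=1e-6)

    def test_no_observations_prior_beliefs_zero(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        assert policy_free_energy(level, bs, 0, []) == 0.0

    def test_converged_free_energy_is_negative_log_evidence(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        obs = [[one_hot(0, 2)]]
        update_epoch(level, bs, obs, n_iterations=128)
        assert policy_free_energy(level, bs, 0, obs) == pytest.approx(
            -np.log(0.55), abs=1e-3)


class TestExpectedFreeEnergy:
    def test_flat_preferences_deterministic_world_zero(self):
        level = single_factor_level(A=np.eye(2), D=[1.0, 0.0], horizon=2)
        bs = init_beliefs(level)
        bs.n_observed = 1
        rep = expected_free_energy(level, bs, 0, [[one_hot(0, 2)]], [1])
        assert rep["G"] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_risk(self):
        # uncertain states, deterministic likelihood, aversion C=(0,-4):
        # G = sum o (ln o - C) = 2 - ln 2
        level = single_factor_level(A=np.eye(2), D=[.5, .5], C=[0.0, -4.0],
                                    horizon=2)
        bs = init_beliefs(level)
        bs.n_observed = 1
        rep = expected_free_energy(level, bs, 0, [[None]], [1])
        assert rep["G"] == pytest.approx(2 - np.log(2), abs=1e-9)
        # the outcome prediction error's inner product with o gives G
        eps = outcome_prediction_error(level, bs, 0, 1, observed=[[None]])
        o = bs.o_pred[0][0, 1]
        assert float(o @ eps[0]) == pytest.approx(rep["G"], abs=1e-5)

    def test_informative_policy_has_lower_G(self):
        # factor 1: hidden thing (2); factor 2: gaze (2); looking at
        # location 2 reveals the thing, location 1 shows nothing
        A = np.zeros((3, 2, 2))
        A[2, :, 0] = 1.0
        A[0, 0, 1] = 1.0
        A[1, 1, 1] = 1.0
        move = np.zeros((2, 2, 2))
        move[0, 0, :] = 1.0
        move[1, 1, :] = 1.0
        level = LevelModel(
            factors=[2, 2], modalities=[3],
            A=[LikelihoodArray(0, A)],
            B=[TransitionArray(0, np.stack([np.eye(2)] * 2)),
               TransitionArray(1, move)],
            C=[PreferenceArray(0, np.zeros(3))],
            D=[InitialLink(0, np.array([.5, .5])), InitialLink(1, one_hot(0, 2))],
            policies=[Policy(0, [0]), Policy(1, [1])], horizon=2)
        bs = init_beliefs(level)
        update_epoch(level, bs, [[one_hot(2, 3)]])
        G = bs.report.G
        assert G[1] < G[0]
        assert G[1] == pytest.approx(-np.log(2), abs=1e-9)
        assert np.all(bs.report.epistemic >= -1e-8)

    def test_unvisited_quadrants_beat_refixation(self, reading_model):
        # start of the second word of the exemplar: nothing seen at
        # quadrant 1; fresh quadrants must carry strictly lower G
        level = reading_model.levels[0]
        priors = [np.array([.25, 0, .75]), one_hot(0, 4),
                  np.array([7 / 8, 1 / 8]), np.array([.5, .5])]
        bs = init_beliefs(level, priors=priors)
        update_epoch(level, bs, [[one_hot(3, 4), one_hot(0, 4)]])
        G = bs.report.G
        assert all(G[q] < G[0] - 1e-6 for q in (1, 2, 3))


class TestPolicyPosterior:
    def test_equal_G_uniform(self):
        assert np.allclose(policy_posterior(np.zeros(3), np.full(3, 1.7)),
                           np.full(3, 1 / 3))

    def test_closed_form_softmax(self):
        pi = policy_posterior(np.zeros(2), np.array([0.0, np.log(2)]))
        assert np.allclose(pi, [2 / 3, 1 / 3])

    def test_single_policy(self):
        assert np.allclose(policy_posterior(np.zeros(1), np.zeros(1)), [1.0])

    def test_use_F_combines_both(self):
        pi = policy_posterior(np.array([np.log(2), 0.0]), np.zeros(2), use_F=True)
        assert np.allclose(pi, [1 / 3, 2 / 3])

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([np.nan]), np.zeros(1))


class TestUpdateEpoch:
    def test_fixed_point_beliefs_unchanged(self):
        level = single_factor_level(A=np.full((2, 2), .5), D=[.5, .5])
        bs = init_beliefs(level)
        before = bs.s[0].copy()
        update_epoch(level, bs, [[one_hot(0, 2)]])
        assert np.allclose(bs.s[0], before, atol=1e-12)

    def test_free_energy_descent_within_epoch(self, rng):
        for _ in range(25):
            S, O = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            A = rng.random((O, S)) + .05
            level = single_factor_level(A / A.sum(0), rng.dirichlet(np.ones(S)))
            bs = init_beliefs(level)
            tr = update_epoch(level, bs, [[one_hot(int(rng.integers(O)), O)]])
            assert np.all(np.diff(tr.f_avg) <= 1e-6)

    def test_trace_has_one_snapshot_per_iteration(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        tr = update_epoch(level, bs, [[one_hot(0, 2)]], n_iterations=16,
                          ms_offset=512.0)
        assert len(tr) == 16
        assert np.allclose(np.diff(tr.ms), level.ms_per_iteration)
        assert tr.ms[0] == 512.0

    def test_divergence_raises_with_iteration_index(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        bs.v[0][:] = np.nan
        with pytest.raises(NumericalDivergenceError) as exc:
            update_epoch(level, bs, [[one_hot(0, 2)]], reset=False)
        assert exc.value.iteration == 0


class TestBayesianModelAverage:
    def test_single_policy_average_is_itself(self):
        level = single_factor_level(**TWO_STATE)
        bs = init_beliefs(level)
        assert np.allclose(bma_states(bs)[0], bs.s[0][0])

    def test_two_delta_policies_mix(self):
        level = single_factor_level(**TWO_STATE, n_policies=2)
        bs = init_beliefs(level)
        bs.s[0][0, 0] = one_hot(0, 2)
        bs.s[0][1, 0] = one_hot(1, 2)
        bs.pi = np.array([.5, .5])
        assert np.allclose(bma_states(bs)[0][0], [.5, .5])

    def test_matches_direct_weighted_sum(self, rng):
        level = single_factor_level(A=np.eye(3), D=[1 / 3] * 3, n_policies=3)
        bs = init_beliefs(level)
        bs.s[0] = rng.dirichlet(np.ones(3), size=(3, 1))
        bs.pi = rng.dirichlet(np.ones(3))
        want = np.einsum("p,pts->ts", bs.pi, bs.s[0])
        assert np.allclose(bma_states(bs)[0], want)


class TestSelectAction:
    def test_most_probable_policy_wins(self):
        level = single_factor_level(**TWO_STATE, n_policies=2)
        bs = init_beliefs(level)
        bs.pi = np.array([.1, .9])
        assert select_action(bs, level, 0) == 1

    def test_exact_tie_breaks_to_lowest_index(self):
        level = single_factor_level(**TWO_STATE, n_policies=2)
        bs = init_beliefs(level)
        bs.pi = np.array([.5, .5])
        assert select_action(bs, level, 0) == 0


class TestDecompositions:
    def test_risk_ambiguity_matches_epistemic_pragmatic(self, rng):
        for _ in range(20):
            S, O = int(rng.integers(2, 4)), int(rng.integers(2, 4))
            A = rng.random((O, S)) + .05
            level = single_factor_level(A / A.sum(0), rng.dirichlet(np.ones(S)),
                                        C=rng.normal(size=O), horizon=2)
            bs = init_beliefs(level)
            obs = [[one_hot(int(rng.integers(O)), O)]]
            update_epoch(level, bs, obs)
            rep = bs.report
            gap = np.abs((rep.risk + rep.ambiguity)
                         + (rep.epistemic + rep.pragmatic)).max()
            assert gap < 1e-6
            assert np.all(rep.epistemic >= -1e-8)
            # dual route: inner product of outcome prediction error
            eps = outcome_prediction_error(level, bs, 0, 1, observed=obs)
            o = bs.o_pred[0][0, 1]
            assert float(o @ eps[0]) == pytest.approx(rep.G[0], abs=1e-5)
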