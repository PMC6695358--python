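"""Tests for task-model construction, the generative process and trials."""

import numpy as np
import pytest

from oculopharm.engine import Precisions
from oculopharm.task import (FB_CORRECT, FB_INCORRECT, FB_NULL, TaskConfig,
                             TrialProcess, build_model, run_trial)


class TestBuildModel:
    def test_cardinalities(self, task_model):
        assert task_model.state_sizes == (5, 4, 4)
        assert [a.shape[0] for a in task_model.A] == [5, 2, 3, 5]
        assert task_model.T == 4
        assert task_model.policies.shape == (125, 3)

    def test_target_transitions_near_identity(self, task_model):
        B = task_model.B[1][:, :, 0]
        assert (np.diag(B) == 0.9).all()
        np.testing.assert_allclose(B.sum(axis=0), 1.0, atol=1e-12)

    def test_stage_advances_deterministically(self, task_model):
        B = task_model.B[2][:, :, 0]
        for s in range(3):
            assert B[s + 1, s] == 1.0
        assert B[3, 3] == 1.0  # absorbing final stage

    def test_proprioception_diagonal(self, task_model):
        A = task_model.A[3]
        for fx in range(5):
            assert (A[fx, fx] == 0.95).all()

    def test_cue_visible_only_at_cue_stage(self, task_model):
        A = task_model.A[0]
        assert (A[4, :, :, 1:] == 1.0).all()      # 'none' after the cue stage
        for tg in range(4):
            assert (A[tg, :, tg, 0] == 0.99).all()

    def test_feedback_structure(self, task_model):
        A = task_model.A[2]
        # delay: incorrect iff fixation left the cross
        assert (np.argmax(A[:, 0, :, 1], axis=0) == FB_NULL).all()
        assert (np.argmax(A[:, 1:, :, 1], axis=0) == FB_INCORRECT).all()
        # go/feedback: correct iff fixating the target
        for tg in range(4):
            assert np.argmax(A[:, tg + 1, tg, 2]) == FB_CORRECT
            assert np.argmax(A[:, 0, tg, 2]) == FB_INCORRECT

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TaskConfig(eccentricity_deg=-3.0)
        with pytest.raises(ValueError):
            TaskConfig(n_delay_steps=0)
        with pytest.raises(ValueError):
            TaskConfig(p_cue=0.3)

    def test_extended_delay(self):
        cfg = TaskConfig(n_delay_steps=3)
        model = build_model(cfg)
        assert model.T == 6
        assert model.state_sizes == (5, 4, 6)
        assert model.policies.shape == (5 ** 5, 5)


class TestTrialProcess:
    def test_premature_latch(self):
        cfg = TaskConfig()
        proc = TrialProcess(cfg, true_target=1)
        assert proc.outcomes(0, 0) == (1, 0, FB_NULL, 0)
        # saccade during the delay: incorrect immediately and latched
        assert proc.outcomes(1, 2)[2] == FB_INCORRECT
        # returning to the target location does not rescue the trial
        assert proc.outcomes(2, 2)[2] == FB_INCORRECT
        assert proc.outcomes(3, 2)[2] == FB_INCORRECT

    def test_clean_trial_is_correct(self):
        cfg = TaskConfig()
        proc = TrialProcess(cfg, true_target=1)
        proc.outcomes(0, 0)
        assert proc.outcomes(1, 0) == (4, 1, FB_NULL, 0)
        assert proc.outcomes(2, 2)[2] == FB_CORRECT
        assert proc.outcomes(3, 2)[2] == FB_CORRECT

    def test_wrong_location_incorrect(self):
        proc = TrialProcess(TaskConfig(), true_target=1)
        proc.outcomes(0, 0)
        proc.outcomes(1, 0)
        assert proc.outcomes(2, 3)[2] == FB_INCORRECT

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            TrialProcess(TaskConfig(), true_target=5)


class TestRunTrial:
    def test_default_trial_correct_and_timed(self, task_model, task_config):
        r = run_trial(task_model, Precisions(), true_target=0, seed=3,
                      config=task_config)
        assert r.correct and not r.premature
        assert r.saccade_steps == [task_config.go_step]
        assert r.metrics.endpoint_error < 1.0
        assert len(r.fix_states) == 4
        assert r.trajectory.times[-1] == pytest.approx(1.0)
        assert r.segment_metrics[r.go_segment].n_saccades == 1
        assert r.n_inappropriate == 0

    def test_beliefs_are_bma_of_policy_beliefs(self, task_model):
        r = run_trial(task_model, Precisions(), true_target=2, seed=0,
                      keep_final_beliefs=True)
        pi = r.policy_posteriors[-1]
        for f in range(3):
            bma = np.einsum("p,ptn->tn", pi, r.final_beliefs[f])
            np.testing.assert_allclose(bma, r.bma_beliefs[-1][f], atol=1e-9)
            np.testing.assert_allclose(r.bma_beliefs[-1][f].sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_zero_likelihood_precision_no_movement(self, task_model):
        r = run_trial(task_model, Precisions(zeta=0.0), true_target=0, seed=1)
        assert r.metrics.amplitude < 0.5
        for eta in r.eta_history:
            np.testing.assert_allclose(eta, [0.0, 0.0], atol=1e-6)

    def test_seed_reproducibility(self, task_model):
        a = run_trial(task_model, Precisions(beta=4.0), true_target=1, seed=11)
        b = run_trial(task_model, Precisions(beta=4.0), true_target=1, seed=11)
        assert a.actions == b.actions
        np.testing.assert_array_equal(a.gamma_trace, b.gamma_trace)
        np.testing.assert_array_equal(a.trajectory.positions,
                                      b.trajectory.positions)

    def test_uniform_policy_mode_randomises(self, task_model):
        hits = [run_trial(task_model, Precisions(), true_target=i % 4, seed=i,
                          policy_mode="uniform").correct for i in range(40)]
        assert np.mean(hits) < 0.5

    def test_raster_shape_and_normalisation(self, task_model):
        r = run_trial(task_model, Precisions(), true_target=3, seed=2,
                      policy_mode="greedy")
        raster = r.target_raster()
        assert raster.shape == (16, 4)
        for tau in range(4):
            np.testing.assert_allclose(raster[tau * 4:(tau + 1) * 4].sum(axis=0),
                                       1.0, atol=1e-9)
        assert 0.0 <= r.persistence_index <= 1.0

    def test_trial_serialisation(self, task_model):
        import json

        r = run_trial(task_model, Precisions(), true_target=0, seed=0)
        payload = json.loads(json.dumps(r.to_dict()))
        assert payload["correct"] is True
        assert len(payload["gamma_trace"]) == 4 * 16
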