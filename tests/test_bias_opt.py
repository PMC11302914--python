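"""Bias initialization, the Adam recurrence, and the optimization loop."""

import numpy as np
import pytest

from afprofile import (
    AdamState,
    BackendError,
    OptConfig,
    Prediction,
    ProfileBias,
    SurrogateBackend,
    adam_update,
    apply_bias,
    compute_profile,
    confidence_loss,
    init_bias,
    make_problem,
    optimize,
    select_best,
)
from afprofile.bias_opt import Trajectory, TrajectoryRecord

from conftest import deterministic_config


def adam_reference(grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    """Independent scalar Adam recurrence, written out step by step."""
    x, m, v = 0.0, 0.0, 0.0
    for t, g in enumerate(grads, start=1):
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        m_hat = m / (1 - beta1**t)
        v_hat = v / (1 - beta2**t)
        x = x - lr * m_hat / (v_hat**0.5 + eps)
    return x


class TestInitAndApply:
    def test_zero_init_shape(self):
        b = init_bias(4)
        assert b.matrix.shape == (4, 22) and not b.matrix.any()

    def test_zero_bias_is_additive_identity(self, small_problem):
        prof = small_problem.blurred_profile
        out = apply_bias(prof, init_bias(prof.L))
        np.testing.assert_array_equal(out, prof.matrix)

    def test_negated_profile_zeroes_features(self, small_problem):
        prof = small_problem.blurred_profile
        bias = ProfileBias(-prof.matrix)
        assert not apply_bias(prof, bias).any()

    def test_bad_dims(self):
        with pytest.raises(ValueError):
            init_bias(0)

    def test_shape_mismatch(self, small_problem):
        with pytest.raises(ValueError):
            apply_bias(small_problem.blurred_profile, init_bias(3))


class TestConfidenceLoss:
    @pytest.mark.parametrize("c,expected", [(1.0, 1.0), (0.5, 2.0), (0.25, 4.0)])
    def test_reciprocal(self, c, expected):
        assert confidence_loss(c) == expected

    @pytest.mark.parametrize("c", [0.0, -0.1])
    def test_degenerate_confidence_rejected(self, c):
        with pytest.raises(ValueError):
            confidence_loss(c)


class TestAdamUpdate:
    def test_zero_gradient_leaves_bias_unchanged(self):
        bias = ProfileBias(np.full((2, 22), 0.3))
        out, state = adam_update(
            bias, np.zeros((2, 22)), AdamState.zeros((2, 22)), OptConfig()
        )
        np.testing.assert_array_equal(out.matrix, bias.matrix)
        assert state.t == 1

    def test_first_step_matches_hand_formula(self):
        g = 0.5
        lr = 1e-4
        out, _ = adam_update(
            ProfileBias(np.zeros((1, 1))),
            np.array([[g]]),
            AdamState.zeros((1, 1)),
            OptConfig(learning_rate=lr),
        )
        expected = -lr * g / (abs(g) + 1e-8)  # bias-corrected moments cancel at t=1
        assert out.matrix[0, 0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("grads", [[0.5, 0.5], [0.3, -0.2], [1.0, 0.1, -0.4]])
    def test_matches_scalar_reference_recurrence(self, grads):
        bias = ProfileBias(np.zeros((1, 1)))
        state = AdamState.zeros((1, 1))
        cfg = OptConfig(learning_rate=1e-3)
        for g in grads:
            bias, state = adam_update(bias, np.array([[g]]), state, cfg)
        assert bias.matrix[0, 0] == pytest.approx(
            adam_reference(grads, lr=1e-3), abs=1e-15
        )

    def test_moment_state_nonnegative_v(self, rng):
        bias = ProfileBias(np.zeros((3, 22)))
        state = AdamState.zeros((3, 22))
        for _ in range(5):
            bias, state = adam_update(
                bias, rng.normal(size=(3, 22)), state, OptConfig()
            )
        assert (state.v >= 0).all() and state.t == 5


class TestOptimize:
    def test_single_step_moves_bias(self, small_problem, small_backend):
        cfg = deterministic_config(max_iters=1)
        traj, bias = optimize(small_backend, small_problem.observed_msa, cfg)
        assert len(traj.records) == 1
        assert traj.records[0].bias_l2 == 0.0  # recorded pre-update
        assert np.linalg.norm(bias.matrix) > 0

    def test_confidence_improves_on_planted_problem(self, small_problem, small_backend):
        cfg = deterministic_config()
        traj, _ = optimize(small_backend, small_problem.observed_msa, cfg)
        assert select_best(traj).confidence > traj.records[0].confidence

    def test_deterministic_runs_bit_identical(self):
        problem = make_problem(L=20, n_rows=50, noise_sigma=0.05, seed=3)
        backend = SurrogateBackend(problem)
        cfg = OptConfig(max_iters=10, master_seed=42, stochastic=True)
        t1, b1 = optimize(backend, problem.observed_msa, cfg)
        t2, b2 = optimize(backend, problem.observed_msa, cfg)
        np.testing.assert_array_equal(b1.matrix, b2.matrix)
        assert [r.confidence for r in t1.records] == [r.confidence for r in t2.records]

    def test_loss_nonincreasing_without_noise(self, small_problem, small_backend):
        cfg = deterministic_config(learning_rate=1e-3, max_iters=50)
        traj, _ = optimize(small_backend, small_problem.observed_msa, cfg)
        losses = [r.loss for r in traj.records]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_record_identities_hold(self, small_problem, small_backend):
        cfg = deterministic_config(max_iters=20, stochastic=True)
        traj, _ = optimize(small_backend, small_problem.observed_msa, cfg)
        assert len(traj.records) == 20
        for r in traj.records:
            assert r.confidence == pytest.approx(0.8 * r.iptm + 0.2 * r.ptm, abs=1e-12)
            assert r.loss == pytest.approx(1.0 / r.confidence, abs=1e-9)

    def test_chain_rule_against_finite_differences(self, small_problem, small_backend):
        """d(loss)/d(features) = -c^-2 dc/df, vs central differences of 1/c."""
        rng = np.random.default_rng(0)
        features = small_problem.blurred_profile.matrix.copy()
        grad_c = small_backend.gradient(features, 0, np.random.default_rng(0), False)
        pred = small_backend.forward(features, 0, np.random.default_rng(0), False)
        grad_loss = -(pred.confidence**-2) * grad_c
        h = 1e-6
        for _ in range(20):
            i = rng.integers(features.shape[0])
            j = rng.integers(features.shape[1])
            fp = features.copy(); fp[i, j] += h
            fm = features.copy(); fm[i, j] -= h
            lp = 1.0 / small_backend.forward(fp, 0, np.random.default_rng(0), False).confidence
            lm = 1.0 / small_backend.forward(fm, 0, np.random.default_rng(0), False).confidence
            fd = (lp - lm) / (2 * h)
            assert grad_loss[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_backend_failure_carries_partial_trajectory(self, small_problem):
        class FlakyBackend(SurrogateBackend):
            def __init__(self, problem):
                super().__init__(problem)
                self.calls = 0

            def forward(self, *args, **kwargs):
                self.calls += 1
                if self.calls > 3:
                    raise RuntimeError("synthetic backend crash")
                return super().forward(*args, **kwargs)

        cfg = deterministic_config(max_iters=10)
        with pytest.raises(BackendError) as err:
            optimize(FlakyBackend(small_problem), small_problem.observed_msa, cfg)
        assert len(err.value.trajectory.records) == 3


class TestSelectBest:
    def _traj(self, confidences):
        records = [
            TrajectoryRecord(
                iteration=i, iptm=c, ptm=c, confidence=c, loss=1 / c, bias_l2=0.0
            )
            for i, c in enumerate(confidences)
        ]
        return Trajectory(records=records, config=OptConfig(), best_index=0)

    def test_maximum_selected(self):
        assert select_best(self._traj([0.3, 0.9, 0.5])).iteration == 1

    def test_tie_broken_by_earliest(self):
        assert select_best(self._traj([0.7, 0.7])).iteration == 0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            select_best(Trajectory(records=[], config=OptConfig(), best_index=0))

    def test_best_at_least_initial(self, small_problem, small_backend):
        cfg = deterministic_config(max_iters=30, stochastic=True)
        traj, _ = optimize(small_backend, small_problem.observed_msa, cfg)
        assert select_best(traj).confidence >= traj.records[0].confidence


def test_opt_config_validation():
    with pytest.raises(ValueError):
        OptConfig(learning_rate=0)
    with pytest.raises(ValueError):
        OptConfig(max_iters=0)
    with pytest.raises(ValueError):
        OptConfig(beta1=1.0)
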