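"""Reward rule, action selection, TD arithmetic, episode mechanics."""

import numpy as np
import pytest

from bias3d import (
    BIAS3D,
    BIAS3DConfig,
    TrainerConfig,
    compute_reward,
    select_action,
    sync_target,
    td_error,
    total_loss,
    train_episode,
)
from bias3d.optim import Adam
from bias3d.rl import GlimpseCache, cross_entropy, epsilon_at, softmax_probs


class TestComputeReward:
    @pytest.mark.parametrize(
        "p, d, expected",
        [
            ((0.96, 0.02, 0.02), (1, 0, 0), 1),
            ((0.70, 0.20, 0.10), (1, 0, 0), 0),  # confident enough? no
            ((0.10, 0.90, 0.00), (1, 0, 0), 0),  # wrong argmax
            ((0.85, 0.10, 0.05), (1, 0, 0), 1),  # threshold is inclusive
        ],
    )
    def test_cases(self, p, d, expected):
        assert compute_reward(p, d, 0.85) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_reward([0.5, 0.5], [1, 0, 0], 0.85)


class TestSelectAction:
    def test_greedy_picks_argmax(self, rng):
        assert select_action(np.array([5.0, 1.0, 1.0]), 0.0, rng) == 0
        assert select_action(np.array([0.0, 2.0, 1.0]), 0.0, rng) == 1

    def test_greedy_tie_breaks_lowest_index(self, rng):
        assert select_action(np.array([1.0, 1.0, 1.0]), 0.0, rng) == 0

    def test_full_exploration_is_uniform(self):
        rng = np.random.default_rng(0)
        q = np.array([9.0, 0.0, 0.0])
        counts = np.bincount(
            [select_action(q, 1.0, rng) for _ in range(10_000)], minlength=3
        )
        # binomial(10000, 1/3): 4 sigma band around 3333
        assert np.all(np.abs(counts - 10_000 / 3) < 4 * np.sqrt(10_000 * 2 / 9))

    def test_softmax_readout_normalized(self):
        assert softmax_probs(np.array([3.0, -1.0, 0.5])).sum() == pytest.approx(1.0)


class TestTDError:
    def test_worked_example(self):
        # r=1, gamma=0.43, max q'=2, q=1 -> 1 + 0.86 - 1 = 0.86
        assert td_error(1.0, [2.0, 0.0, -1.0], 1.0, 0.43) == pytest.approx(0.86)

    def test_gamma_zero_is_reward_minus_q(self):
        assert td_error(1.0, [5.0, 5.0, 5.0], 0.3, 0.0) == pytest.approx(0.7)

    def test_all_zero(self):
        assert td_error(0.0, [0.0, 0.0, 0.0], 0.0, 0.43) == 0.0


class TestTotalLoss:
    def test_perfect_onehot_zero_ce(self):
        d = np.array([0.0, 1.0, 0.0])
        assert total_loss(d, d, [0.0]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_tds_zero_mse(self, rng):
        p = rng.dirichlet(np.ones(4))
        d = np.eye(4)[1]
        assert total_loss(p, d, [0.0, 0.0]) == pytest.approx(cross_entropy(p, d))

    def test_sum_decomposition(self, rng):
        p = rng.dirichlet(np.ones(4))
        d = np.eye(4)[2]
        tds = rng.normal(size=5)
        assert total_loss(p, d, tds) == pytest.approx(
            cross_entropy(p, d) + np.mean(tds**2)
        )


class TestEpsilonSchedule:
    def test_decay_formula(self):
        cfg = TrainerConfig()
        for k in (0, 1, 10, 500):
            assert epsilon_at(cfg, k) == pytest.approx(max(0.99 * 0.999**k, 0.1))

    def test_floor(self):
        cfg = TrainerConfig()
        assert epsilon_at(cfg, 10_000) == 0.1


@pytest.fixture(scope="module")
def episode_setup(scene):
    model = BIAS3D(BIAS3DConfig.small(n_classes=3), seed=1)
    cfg = TrainerConfig(timesteps_per_cube=10, jump_length=12.0, seed=0)
    cache = GlimpseCache(scene)
    return model, cfg, cache


class TestTrainEpisode:
    def test_fixed_length_and_reward_range(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        target = model.copy()
        opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.l2_factor)
        m = train_episode(scene, model, target, opt, cfg, np.random.default_rng(0),
                          0.5, cache=cache)
        assert len(m["trajectory"]) == cfg.timesteps_per_cube
        assert 0 <= m["total_reward"] <= cfg.timesteps_per_cube
        assert isinstance(m["total_reward"], int)

    def test_frozen_weights_reproducible_trajectory(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        target = model.copy()
        runs = []
        for _ in range(2):
            frozen = Adam(model.params, lr=0.0, weight_decay=0.0)
            m = train_episode(scene, model, target, frozen, cfg,
                              np.random.default_rng(7), 0.3, cache=cache)
            runs.append(m["trajectory"])
        assert runs[0] == runs[1]

    def test_zero_lr_zero_decay_leaves_weights_identical(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        target = model.copy()
        before = model.get_weights()
        frozen = Adam(model.params, lr=0.0, weight_decay=0.0)
        train_episode(scene, model, target, frozen, cfg, np.random.default_rng(1),
                      0.5, cache=cache)
        after = model.get_weights()
        for name in before:
            assert np.array_equal(before[name], after[name]), name

    def test_learning_changes_weights(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        model = BIAS3D(model.config, seed=2)
        target = model.copy()
        before = model.get_weights()
        opt = Adam(model.params, lr=1e-3, weight_decay=0.0)
        train_episode(scene, model, target, opt, cfg, np.random.default_rng(1),
                      0.5, cache=cache)
        changed = sum(
            not np.array_equal(before[k], model.params[k].data) for k in before
        )
        assert changed == len(before)

    def test_missing_target_model_rejected(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        opt = Adam(model.params, lr=0.0)
        with pytest.raises(ValueError):
            train_episode(scene, model, None, opt, cfg, np.random.default_rng(0),
                          0.5, cache=cache)


class TestSyncTarget:
    def test_hard_copy_and_staleness(self, scene, episode_setup):
        model, cfg, cache = episode_setup
        model = BIAS3D(model.config, seed=4)
        target = BIAS3D(model.config, seed=5)
        sync_target(model, target)
        for name in model.params:
            assert np.array_equal(
                model.params[name].data, target.params[name].data
            )
        # an online update leaves the target stale until the next sync
        opt = Adam(model.params, lr=1e-3)
        train_episode(scene, model, target, opt, cfg, np.random.default_rng(2),
                      0.5, cache=cache)
        assert not np.array_equal(
            model.params["q_W"].data, target.params["q_W"].data
        )


def test_gamma_zero_optimal_q_equals_immediate_reward():
    """Value-iteration oracle on a toy 4-state orbit: with gamma = 0 the
    optimal Q-value of every state-action pair is its immediate reward."""
    n_states, jump = 4, 1
    reward = {s: float(s == 0) for s in range(n_states)}  # target at state 0

    def step(s, a):  # actions: right, left, stay
        return {0: (s + jump) % n_states, 1: (s - jump) % n_states, 2: s}[a]

    for gamma in (0.0, 0.43):
        Q = np.zeros((n_states, 3))
        for _ in range(200):
            Qn = np.empty_like(Q)
            for s in range(n_states):
                for a in range(3):
                    s2 = step(s, a)
                    Qn[s, a] = reward[s2] + gamma * Q[s2].max()
            if np.allclose(Qn, Q, atol=1e-12):
                break
            Q = Qn
        if gamma == 0.0:
            for s in range(n_states):
                for a in range(3):
                    assert Q[s, a] == pytest.approx(reward[step(s, a)])
        else:
            assert np.all(Q >= 0) and np.isfinite(Q).all()


def test_trainer_config_validation():
    with pytest.raises(ValueError):
        TrainerConfig(gamma=1.0)
    with pytest.raises(ValueError):
        TrainerConfig(epsilon_min=0.5, epsilon_start=0.2)


def test_trainer_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("gamma: 0.5\nepochs: 2\njump_length: 20.0\n")
    cfg = TrainerConfig.from_yaml(path)
    assert cfg.gamma == 0.5 and cfg.epochs == 2 and cfg.jump_length == 20.0
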