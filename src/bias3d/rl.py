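"""End-to-end Q-learning of the search policy.

Each training episode orbits the camera around one cube for a fixed number
of timesteps.  The reward is 1 exactly when the classifier assigns its
maximum probability to the cube's target class *and* that probability
crosses the confidence threshold lambda -- i.e. the agent is paid for
looking at the target and recognising it confidently.  Bootstrapped Q
targets come from a periodically hard-synced copy of the model (the target
network); the temporal-difference error is

    TD = (r + gamma * max_a' Q_target(S_{t+1}, a')) - Q(S_t, a_t).

The episode loss is the mean cross-entropy of the classifier head against
the view labels plus the mean squared TD, backpropagated once per episode
through the unrolled recurrences; parameters update with Adam and an L2
penalty through the optimizer's weight decay.  Exploration is
epsilon-greedy over a softmax readout of the Q-values, with epsilon decayed
per episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import no_grad
from .env3d import ACTIONS, ViewCache, step_camera, relative_offset
from .glimpse import GlimpseConfig, extract_glimpse
from .model import BIAS3D, BIAS3DConfig
from .optim import Adam, clip_global_norm
from .pretraining import TARGET_HALF_RANGE, PretrainClassifier


@dataclass
class TrainerConfig:
    lr: float = 1e-4
    gamma: float = 0.43
    lambda_threshold: float = 0.85
    l2_factor: float = 0.1
    epsilon_start: float = 0.99
    epsilon_decay: float = 0.999
    epsilon_min: float = 0.1
    timesteps_per_cube: int = 50
    epochs: int = 25
    jump_length: float = 12.0
    target_sync_every: int = 10
    grad_clip: float = 5.0
    td_all_actions: bool = False  # mean squared TD over all 3 actions vs taken one
    test_threshold: float = 0.95
    max_search_steps: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if not 0.0 <= self.epsilon_min <= self.epsilon_start <= 1.0:
            raise ValueError("need 0 <= epsilon_min <= epsilon_start <= 1")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def epsilon_at(cfg, episode):
    """Exploration rate after `episode` completed episodes."""
    return max(cfg.epsilon_start * cfg.epsilon_decay**episode, cfg.epsilon_min)


def compute_reward(p, d, lambda_threshold=0.85):
    """1 iff argmax p == argmax d and max(p) >= lambda, else 0."""
    p = np.asarray(p, float)
    d = np.asarray(d, float)
    if p.shape != d.shape:
        raise ValueError("probability and desired vectors must match in length")
    return int(np.argmax(p) == np.argmax(d) and p.max() >= lambda_threshold)


def softmax_probs(q):
    z = np.asarray(q, float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def select_action(q, epsilon, rng):
    """Epsilon-greedy over the softmax action readout.

    With probability epsilon a uniform random action; otherwise the
    highest-softmax-probability action (equivalently argmax q), ties broken
    by lowest index.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if rng.random() < epsilon:
        return int(rng.integers(len(np.asarray(q))))
    return int(np.argmax(softmax_probs(q)))


def td_error(r, q_next_target, q_taken, gamma):
    """TD = (r + gamma * max q_target(next)) - q_taken."""
    return r + gamma * float(np.max(np.asarray(q_next_target, float))) - q_taken


def cross_entropy(p, d):
    """- sum d * log(p + 1e-12); mean over the batch axis if 2-D."""
    p = np.asarray(p, float)
    d = np.asarray(d, float)
    ce = -(d * np.log(p + 1e-12)).sum(axis=-1)
    return float(np.mean(ce))


def total_loss(class_probs, target_onehot, td_errors):
    """Combined loss: cross-entropy plus mean squared TD error."""
    tds = np.asarray(td_errors, float)
    return cross_entropy(class_probs, target_onehot) + float(np.mean(tds * tds))


def sync_target(model, target_model):
    """Hard copy of the online parameters into the target network."""
    target_model.load_weights(model.get_weights())


class GlimpseCache:
    """Glimpses by azimuth for one scene (rendering + cropping are pure)."""

    def __init__(self, scene, render_cfg=None, glimpse_cfg=None):
        self.views = ViewCache(scene, render_cfg)
        self.glimpse_cfg = glimpse_cfg or GlimpseConfig()
        self._cache = {}

    def get(self, theta):
        key = round(theta % 360.0, 6)
        if key not in self._cache:
            self._cache[key] = extract_glimpse(
                self.views.get(key), self.glimpse_cfg
            ).astype(np.float32)
        return self._cache[key]


def _start_theta(cfg, rng):
    # on the jump lattice when it divides the circle, so views repeat and cache
    if cfg.jump_length > 0 and 360.0 % cfg.jump_length == 0:
        return cfg.jump_length * int(rng.integers(int(360.0 // cfg.jump_length)))
    return float(rng.uniform(0.0, 360.0))


def train_episode(scene, model, target_model, optimizer, cfg, rng, epsilon,
                  cache=None):
    """Run one fixed-length episode on `scene` and apply one Adam update.

    Returns metrics including the integer total reward, the episode loss and
    the visited (theta, action, reward) trajectory.
    """
    if target_model is None:
        raise ValueError("a target network is required for bootstrapped TD")
    cache = cache or GlimpseCache(scene)
    n_bg = model.config.n_classes
    d_target = np.zeros(model.config.n_outputs)
    d_target[scene.target_class] = 1.0

    def view_label(theta):
        off = relative_offset(theta, scene)
        return scene.target_class if abs(off) <= TARGET_HALF_RANGE else n_bg

    theta = _start_theta(cfg, rng)
    state = model.reset_state()
    t_state = target_model.reset_state()
    out, state = model.forward(cache.get(theta), theta, state)
    with no_grad():
        _, t_state = target_model.forward(cache.get(theta), theta, t_state)

    ce_terms, td_terms, rewards, trajectory = [], [], [], []
    T = cfg.timesteps_per_cube
    for t in range(T):
        label = view_label(theta)
        ce_terms.append(-ad.pick(ad.log(out.class_probs + 1e-12), label))
        action = select_action(out.q_values.data, epsilon, rng)
        if cfg.td_all_actions:
            q_taken = out.q_values
        else:
            q_taken = ad.pick(out.q_values, action)
        next_theta = step_camera(theta, ACTIONS[action], cfg.jump_length)

        if t < T - 1:
            out_next, state = model.forward(cache.get(next_theta), next_theta, state)
        else:
            with no_grad():
                out_next, state = model.forward(
                    cache.get(next_theta), next_theta, state
                )
        with no_grad():
            t_out, t_state = target_model.forward(
                cache.get(next_theta), next_theta, t_state
            )

        r = compute_reward(out_next.class_probs.data, d_target, cfg.lambda_threshold)
        boot = r + cfg.gamma * float(t_out.q_values.data.max())
        td = boot - q_taken  # scalar (or 3-vector) tensor in the episode graph
        td_terms.append((td * td).mean() if cfg.td_all_actions else td * td)
        rewards.append(r)
        trajectory.append((theta, ACTIONS[action], r))
        theta, out = next_theta, out_next

    loss = sum(ce_terms[1:], ce_terms[0]) / T
    loss = loss + sum(td_terms[1:], td_terms[0]) / T
    model.zero_grad()
    loss.backward()
    clip_global_norm(model.params, cfg.grad_clip)
    optimizer.step()
    return {
        "total_reward": int(sum(rewards)),
        "loss": loss.item(),
        "trajectory": trajectory,
        "epsilon": epsilon,
    }


def fit(train_cubes, val_cubes, cfg, model=None, pretrained=None,
        render_cfg=None, glimpse_cfg=None, caches=None, progress=False):
    """Full training loop: epochs x cubes episodes with per-epoch validation.

    `pretrained` may be a PretrainClassifier or a weight dict for the
    classifier pipeline.  Returns (model, curves); the model carries the
    best-validation weights and `curves` has one entry per epoch.
    """
    if not train_cubes:
        raise ValueError("no training cubes")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        n_classes = max(c.target_class for c in train_cubes) + 1
        channels = 3 * train_cubes[0].channels
        model = BIAS3D(
            BIAS3DConfig.small(n_classes=n_classes, channels=channels),
            seed=int(rng.integers(2**31)),
        )
    if pretrained is not None:
        weights = (
            pretrained.model_weights()
            if isinstance(pretrained, PretrainClassifier)
            else pretrained
        )
        model.load_weights(weights)
    target = model.copy()
    optimizer = Adam(model.params, lr=cfg.lr, weight_decay=cfg.l2_factor)
    if caches is None:
        caches = [GlimpseCache(sc, render_cfg, glimpse_cfg) for sc in train_cubes]
    curves = {"mean_reward": [], "val_accuracy": [], "epsilon": []}
    best_acc, best_weights = -1.0, None
    episode = 0
    from .evaluation import EvalConfig, evaluate  # local import avoids a cycle

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_cubes))
        rewards = []
        for idx in order:
            eps = epsilon_at(cfg, episode)
            metrics = train_episode(
                train_cubes[idx], model, target, optimizer, cfg, rng, eps,
                cache=caches[idx],
            )
            rewards.append(metrics["total_reward"])
            episode += 1
            if episode % cfg.target_sync_every == 0:
                sync_target(model, target)
        ecfg = EvalConfig(
            threshold=cfg.test_threshold, max_steps=cfg.max_search_steps,
            jump_length=cfg.jump_length, seed=int(rng.integers(2**31)),
        )
        val_metrics, _ = evaluate(val_cubes, model, ecfg,
                                  render_cfg=render_cfg, glimpse_cfg=glimpse_cfg)
        curves["mean_reward"].append(float(np.mean(rewards)))
        curves["val_accuracy"].append(val_metrics["accuracy"])
        curves["epsilon"].append(epsilon_at(cfg, episode))
        if val_metrics["accuracy"] >= best_acc:
            best_acc, best_weights = val_metrics["accuracy"], model.get_weights()
        if progress:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}: mean reward "
                f"{curves['mean_reward'][-1]:.2f}, val accuracy {best_acc:.2f}"
            )
    if best_weights is not None:
        model.load_weights(best_weights)
    return model, curves
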