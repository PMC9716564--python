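"""Desk-scale reproducible study on synthetic-glyph cubes.

Runs the full pipeline at CPU scale: generate a 3-class cluttered-cube
dataset from procedural glyphs, pretrain the classifier on orbital views,
train the search policy with Q-learning for a few epochs, and score the
trained agent against the uniform-random-action baseline (same pretrained
classifier, same stopping rule) on a held-out test set.

Problem sizes default to 300 training / 20 validation / 50 test cubes,
5 pretraining epochs and 5 Q-learning epochs with the reduced-width model
preset; the hyperparameters of the learning rules themselves (learning
rate, discount, thresholds, exploration schedule, episode length) keep
their full-scale defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetSpec, generate_split, synth_glyphs
from .evaluation import EvalConfig, evaluate
from .model import BIAS3D, BIAS3DConfig
from .pretraining import (
    collect_glimpse_dataset,
    pretrain_classifier,
    views_to_glimpse_arrays,
)
from .rl import GlimpseCache, TrainerConfig, fit


@dataclass
class BenchmarkConfig:
    n_classes: int = 3
    split_sizes: tuple = (300, 20, 50)
    pretrain_epochs: int = 40
    pretrain_lr: float = 1e-3
    pretrain_batch: int = 32
    pretrain_decay_after: int = 25  # step the pretraining lr down once here
    rl_epochs: int = 5
    # ~1500 episodic updates instead of ~10^6 at full scale: the step size is
    # scaled up and the L2 penalty scaled down accordingly (TrainerConfig
    # keeps the full-scale defaults)
    rl_lr: float = 2e-3
    rl_l2_factor: float = 1e-3
    # hard-sync the bootstrap (target) network every 5 episodes: with only
    # ~1.5k episodes, value information must propagate quickly
    rl_target_sync: int = 5
    jump_length: float = 12.0
    test_threshold: float = 0.85
    max_steps: int = 50
    # mild cross-channel inhibition; the aggressive (0,1,1,C) normalization
    # is available through LRNParams() but learns worse at this scale
    lrn: object = None

    def model_config(self, channels=3):
        from .nn_layers import LRNParams

        lrn = self.lrn if self.lrn is not None else LRNParams(2.0, 1e-4, 0.75, 5)
        return BIAS3DConfig(
            n_classes=self.n_classes, channels=channels,
            cls_conv=(8, 16, 32), cls_fc=128,
            mot_conv=(6, 12), mot_fc=96, mot_ff=96,
            pos_fc=32, pos_ff=16, fusion=96, lrn=lrn,
        )


class PretrainedSearcher:
    """The pretrained feed-forward classifier wrapped in the search-model
    protocol: uniform Q-values (the policy is supplied externally, e.g.
    random actions), class probabilities straight from the pretraining head.
    This is the classifier-only baseline agent."""

    def __init__(self, net):
        self.net = net
        self.config = net.config

    def reset_state(self):
        return None

    def forward(self, glimpse, theta, state):
        from .autodiff import Tensor
        from .model import ModelOutput

        probs = self.net.forward(np.asarray(glimpse)[None]).data[0]
        return ModelOutput(Tensor(np.zeros(3)), Tensor(probs)), None


@dataclass
class BenchmarkData:
    """Dataset plus shared render/glimpse caches (reusable across seeds)."""

    train: list
    val: list
    test: list
    pretrain_data: tuple  # (X, y) balanced training glimpses
    test_views: tuple  # (X, y) balanced held-out view glimpses
    caches: list = field(default=None)


def prepare_data(data_seed, cfg=None):
    """Generate the cube splits and precompute the view glimpses once."""
    cfg = cfg or BenchmarkConfig()
    total = sum(cfg.split_sizes)
    per_class = -(-total // cfg.n_classes) + 1
    images = synth_glyphs(cfg.n_classes, per_class, seed=data_seed)
    spec = DatasetSpec(
        n_classes=cfg.n_classes, split_sizes=cfg.split_sizes, seed=data_seed
    )
    train, val, test = generate_split(images, spec)
    rng = np.random.default_rng(data_seed + 1)
    pretrain_data = collect_glimpse_dataset(train, cfg.n_classes)
    test_views = views_to_glimpse_arrays(test, cfg.n_classes, rng)
    caches = [GlimpseCache(sc) for sc in train]
    return BenchmarkData(train, val, test, pretrain_data, test_views, caches)


def run_study(data, seed, cfg=None, progress=False):
    """One seeded pretrain -> Q-learning -> evaluation pass.

    Returns a dict with the pretraining view accuracy, the trained agent's
    search success on the test cubes, the random-action baseline's success
    with the same classifier, step counts, and the training curves.
    """
    cfg = cfg or BenchmarkConfig()
    model_cfg = cfg.model_config(channels=3 * data.train[0].channels)
    net, pre_hist = pretrain_classifier(
        data.train, epochs=cfg.pretrain_epochs, lr=cfg.pretrain_lr, seed=seed,
        config=model_cfg, data=data.pretrain_data,
        batch_size=cfg.pretrain_batch, lr_decay_after=cfg.pretrain_decay_after,
    )
    view_acc = net.accuracy(*data.test_views)

    tc = TrainerConfig(
        lr=cfg.rl_lr, l2_factor=cfg.rl_l2_factor, epochs=cfg.rl_epochs,
        jump_length=cfg.jump_length, test_threshold=cfg.test_threshold,
        max_search_steps=cfg.max_steps, target_sync_every=cfg.rl_target_sync,
        seed=seed,
    )
    model = BIAS3D(model_cfg, seed=seed)
    model, curves = fit(
        data.train, data.val, tc, model=model, pretrained=net,
        caches=data.caches, progress=progress,
    )

    ecfg = EvalConfig(
        threshold=cfg.test_threshold, max_steps=cfg.max_steps,
        jump_length=cfg.jump_length, seed=seed,
    )
    trained_metrics, _ = evaluate(data.test, model, ecfg)
    baseline_metrics, _ = evaluate(
        data.test, PretrainedSearcher(net),
        EvalConfig(threshold=cfg.test_threshold, max_steps=cfg.max_steps,
                   jump_length=cfg.jump_length, policy="random", seed=seed),
    )
    return {
        "pretrain_view_accuracy": view_acc,
        "pretrain_loss": pre_hist["loss"],
        "search_success": trained_metrics["accuracy"],
        "baseline_success": baseline_metrics["accuracy"],
        "mean_steps": trained_metrics["mean_steps"],
        "baseline_mean_steps": baseline_metrics["mean_steps"],
        "curves": curves,
        "model": model,
        "n_test": trained_metrics["n"],
    }
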