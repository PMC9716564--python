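"""The dual-pathway attentional search model.

Three parallel pipelines process each timestep of the orbit:

* **classifier** ("what"): Conv16-LRN-ReLU-pool, Conv32-LRN-ReLU-pool,
  Conv64-ReLU, flatten, FC Elman-Jordan (512).  Its Jordan context is the
  previous step's class-probability head output.
* **camera motion** ("where"): ConvJKFF16-LRN-ReLU-pool,
  ConvJKFF32-LRN-ReLU-pool, flatten, FC Elman-Jordan (512), FC flip-flop
  (512).  Its Jordan context is the previous step's Q-value head output.
* **camera position**: (sin theta, cos theta) -> FC Elman (128) -> FC
  flip-flop (64).  Elman-only; no Jordan feedback.

The three pipeline outputs are concatenated (512+512+64 = 1088), passed
through a fusion FC layer, and split into two heads: a linear head with the
three action Q-values (right, left, stay) and a softmax head with the n+1
class probabilities (n targets plus background/clutter).

Flip-flop hidden states initialize to ones at t = 0; Elman and Jordan
contexts initialize to zeros.  All weights are Xavier-initialized from a
single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn_layers import (
    LRNParams,
    conv2d,
    conv_block,
    conv_jkff_step,
    fcej_forward,
    jkff_step,
    lrn_relu_pool,
    xavier_init,
)


def encode_theta(theta):
    """Sinusoidal encoding of the azimuth: (sin theta, cos theta)."""
    t = np.deg2rad(theta)
    return np.array([np.sin(t), np.cos(t)])


@dataclass
class BIAS3DConfig:
    n_classes: int  # target classes; the softmax head has n_classes + 1 outputs
    channels: int = 3  # glimpse depth = n_windows * view channels
    glimpse_size: int = 16
    cls_conv: tuple = (16, 32, 64)
    cls_fc: int = 512
    mot_conv: tuple = (16, 32)
    mot_fc: int = 512
    mot_ff: int = 512
    pos_fc: int = 128
    pos_ff: int = 64
    fusion: int = 512
    lrn: LRNParams = field(default_factory=LRNParams)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 target classes")
        widths = (*self.cls_conv, self.cls_fc, *self.mot_conv, self.mot_ff,
                  self.mot_fc, self.pos_fc, self.pos_ff, self.fusion)
        if any(w <= 0 for w in widths):
            raise ValueError("all layer widths must be positive")
        if self.glimpse_size % 4:
            raise ValueError("glimpse size must be divisible by 4 (two poolings)")

    @classmethod
    def paper(cls, n_classes, channels=3):
        """Full-width preset matching the published architecture."""
        return cls(n_classes=n_classes, channels=channels)

    @classmethod
    def small(cls, n_classes, channels=3):
        """Reduced-width preset for CPU-scale experiments."""
        return cls(
            n_classes=n_classes,
            channels=channels,
            cls_conv=(6, 12, 24),
            cls_fc=96,
            mot_conv=(6, 12),
            mot_fc=96,
            mot_ff=96,
            pos_fc=32,
            pos_ff=16,
            fusion=96,
        )

    @property
    def n_outputs(self):
        return self.n_classes + 1

    @property
    def cls_flat(self):
        return (self.glimpse_size // 4) ** 2 * self.cls_conv[2]

    @property
    def mot_flat(self):
        return (self.glimpse_size // 4) ** 2 * self.mot_conv[1]


@dataclass
class RecurrentState:
    """Per-layer recurrent stores carried between timesteps."""

    cff1_H: Tensor
    cff2_H: Tensor
    mot_ff_H: Tensor
    pos_ff_H: Tensor
    cls_elman: Tensor
    mot_elman: Tensor
    pos_elman: Tensor
    cls_jordan: Tensor
    mot_jordan: Tensor


@dataclass
class ModelOutput:
    q_values: Tensor  # (3,) unbounded action values
    class_probs: Tensor  # (n+1,) on the simplex


def _param_specs(cfg):
    """(name, fan_in, fan_out, shape) for every trainable tensor."""
    g = cfg.glimpse_size
    C = cfg.channels
    k1, k2, k3 = cfg.cls_conv
    m1, m2 = cfg.mot_conv
    n_out = cfg.n_outputs
    specs = [
        ("cls_conv1_W", 9 * C, 9 * k1, (3, 3, C, k1)),
        ("cls_conv1_b", None, None, (k1,)),
        ("cls_conv2_W", 9 * k1, 9 * k2, (3, 3, k1, k2)),
        ("cls_conv2_b", None, None, (k2,)),
        ("cls_conv3_W", 9 * k2, 9 * k3, (3, 3, k2, k3)),
        ("cls_conv3_b", None, None, (k3,)),
        ("cls_fcej_Win", cfg.cls_flat, cfg.cls_fc, (cfg.cls_flat, cfg.cls_fc)),
        ("cls_fcej_Wrec", cfg.cls_fc, cfg.cls_fc, (cfg.cls_fc, cfg.cls_fc)),
        ("cls_fcej_Wjord", n_out, cfg.cls_fc, (n_out, cfg.cls_fc)),
        ("cls_fcej_b", None, None, (cfg.cls_fc,)),
        ("mot_cff1_Wj", 9 * (C + m1), 9 * m1, (3, 3, C + m1, m1)),
        ("mot_cff1_Wk", 9 * (C + m1), 9 * m1, (3, 3, C + m1, m1)),
        ("mot_cff1_Wout", m1, m1, (1, 1, m1, m1)),
        ("mot_cff2_Wj", 9 * (m1 + m2), 9 * m2, (3, 3, m1 + m2, m2)),
        ("mot_cff2_Wk", 9 * (m1 + m2), 9 * m2, (3, 3, m1 + m2, m2)),
        ("mot_cff2_Wout", m2, m2, (1, 1, m2, m2)),
        ("mot_fcej_Win", cfg.mot_flat, cfg.mot_fc, (cfg.mot_flat, cfg.mot_fc)),
        ("mot_fcej_Wrec", cfg.mot_fc, cfg.mot_fc, (cfg.mot_fc, cfg.mot_fc)),
        ("mot_fcej_Wjord", 3, cfg.mot_fc, (3, cfg.mot_fc)),
        ("mot_fcej_b", None, None, (cfg.mot_fc,)),
        ("mot_fcff_Wj", cfg.mot_fc + cfg.mot_ff, cfg.mot_ff,
         (cfg.mot_fc + cfg.mot_ff, cfg.mot_ff)),
        ("mot_fcff_Wk", cfg.mot_fc + cfg.mot_ff, cfg.mot_ff,
         (cfg.mot_fc + cfg.mot_ff, cfg.mot_ff)),
        ("mot_fcff_Wout", cfg.mot_ff, cfg.mot_ff, (cfg.mot_ff, cfg.mot_ff)),
        ("pos_fce_Win", 2, cfg.pos_fc, (2, cfg.pos_fc)),
        ("pos_fce_Wrec", cfg.pos_fc, cfg.pos_fc, (cfg.pos_fc, cfg.pos_fc)),
        ("pos_fce_b", None, None, (cfg.pos_fc,)),
        ("pos_fcff_Wj", cfg.pos_fc + cfg.pos_ff, cfg.pos_ff,
         (cfg.pos_fc + cfg.pos_ff, cfg.pos_ff)),
        ("pos_fcff_Wk", cfg.pos_fc + cfg.pos_ff, cfg.pos_ff,
         (cfg.pos_fc + cfg.pos_ff, cfg.pos_ff)),
        ("pos_fcff_Wout", cfg.pos_ff, cfg.pos_ff, (cfg.pos_ff, cfg.pos_ff)),
        ("fus_W", cfg.cls_fc + cfg.mot_ff + cfg.pos_ff, cfg.fusion,
         (cfg.cls_fc + cfg.mot_ff + cfg.pos_ff, cfg.fusion)),
        ("fus_b", None, None, (cfg.fusion,)),
        ("q_W", cfg.fusion, 3, (cfg.fusion, 3)),
        ("q_b", None, None, (3,)),
        ("cls_head_W", cfg.fusion, n_out, (cfg.fusion, n_out)),
        ("cls_head_b", None, None, (n_out,)),
    ]
    return specs


class BIAS3D:
    """Recurrent what/where search model over glimpse + azimuth inputs."""

    #: classifier-pipeline parameter names shared with the pretraining net
    CLASSIFIER_PARAMS = (
        "cls_conv1_W", "cls_conv1_b", "cls_conv2_W", "cls_conv2_b",
        "cls_conv3_W", "cls_conv3_b", "cls_fcej_Win", "cls_fcej_b",
    )

    #: parameter and activation dtype; single precision is ample here
    dtype = np.float32

    def __init__(self, config, seed=0):
        self.config = config
        self.params = {}
        seed_rng = np.random.default_rng(seed)
        for name, fin, fout, shape in _param_specs(config):
            if fin is None:  # bias: zero-initialized
                arr = np.zeros(shape)
            else:
                arr = xavier_init(fin, fout, int(seed_rng.integers(2**31)), shape=shape)
            self.params[name] = Tensor(arr.astype(self.dtype), requires_grad=True)

    # -- state -------------------------------------------------------------
    def reset_state(self):
        """Fresh episode state: flip-flop H maps at one, contexts at zero."""
        cfg = self.config
        g = cfg.glimpse_size
        dt = self.dtype
        return RecurrentState(
            cff1_H=Tensor(np.ones((1, g, g, cfg.mot_conv[0]), dtype=dt)),
            cff2_H=Tensor(np.ones((1, g // 2, g // 2, cfg.mot_conv[1]), dtype=dt)),
            mot_ff_H=Tensor(np.ones((1, cfg.mot_ff), dtype=dt)),
            pos_ff_H=Tensor(np.ones((1, cfg.pos_ff), dtype=dt)),
            cls_elman=Tensor(np.zeros((1, cfg.cls_fc), dtype=dt)),
            mot_elman=Tensor(np.zeros((1, cfg.mot_fc), dtype=dt)),
            pos_elman=Tensor(np.zeros((1, cfg.pos_fc), dtype=dt)),
            cls_jordan=Tensor(np.zeros((1, cfg.n_outputs), dtype=dt)),
            mot_jordan=Tensor(np.zeros((1, 3), dtype=dt)),
        )

    # -- forward ------------------------------------------------------------
    def forward(self, glimpse, theta, state):
        """One synchronous step of all three pipelines.

        Returns (ModelOutput, next RecurrentState); the caller owns the state.
        """
        cfg = self.config
        p = self.params
        g = np.asarray(glimpse, dtype=self.dtype)
        expected = (cfg.glimpse_size, cfg.glimpse_size, cfg.channels)
        if g.shape != expected:
            raise ValueError(f"glimpse shape {g.shape} != expected {expected}")
        x = Tensor(g[None])
        lp = cfg.lrn

        # classifier ("what") pipeline
        h = conv_block(x, p["cls_conv1_W"], p["cls_conv1_b"], lp)
        h = conv_block(h, p["cls_conv2_W"], p["cls_conv2_b"], lp)
        h = conv2d(h, p["cls_conv3_W"], p["cls_conv3_b"], act="relu")
        cls_feat = fcej_forward(
            ad.reshape(h, (1, -1)), state.cls_elman, state.cls_jordan,
            (p["cls_fcej_Win"], p["cls_fcej_Wrec"], p["cls_fcej_Wjord"]),
            p["cls_fcej_b"],
        )

        # camera-motion ("where") pipeline
        o1, H1 = conv_jkff_step(
            x, state.cff1_H,
            {"w_j": p["mot_cff1_Wj"], "w_k": p["mot_cff1_Wk"], "w_out": p["mot_cff1_Wout"]},
        )
        m = lrn_relu_pool(o1, lp)
        o2, H2 = conv_jkff_step(
            m, state.cff2_H,
            {"w_j": p["mot_cff2_Wj"], "w_k": p["mot_cff2_Wk"], "w_out": p["mot_cff2_Wout"]},
        )
        m = lrn_relu_pool(o2, lp)  # LRN/ReLU/pool after each flip-flop conv
        mot_fc = fcej_forward(
            ad.reshape(m, (1, -1)), state.mot_elman, state.mot_jordan,
            (p["mot_fcej_Win"], p["mot_fcej_Wrec"], p["mot_fcej_Wjord"]),
            p["mot_fcej_b"],
        )
        mot_feat, H3 = jkff_step(
            mot_fc, state.mot_ff_H,
            p["mot_fcff_Wj"], p["mot_fcff_Wk"], p["mot_fcff_Wout"],
        )

        # camera-position pipeline (Elman only)
        enc = Tensor(encode_theta(theta).astype(self.dtype)[None])
        pos_fc = fcej_forward(
            enc, state.pos_elman, None,
            (p["pos_fce_Win"], p["pos_fce_Wrec"], None), p["pos_fce_b"],
        )
        pos_feat, H4 = jkff_step(
            pos_fc, state.pos_ff_H,
            p["pos_fcff_Wj"], p["pos_fcff_Wk"], p["pos_fcff_Wout"],
        )

        fused = ad.linear(
            ad.concat([cls_feat, mot_feat, pos_feat], axis=-1),
            p["fus_W"], p["fus_b"], act="relu",
        )
        q = ad.linear(fused, p["q_W"], p["q_b"])
        probs = ad.softmax(ad.linear(fused, p["cls_head_W"], p["cls_head_b"]))

        new_state = RecurrentState(
            cff1_H=H1, cff2_H=H2, mot_ff_H=H3, pos_ff_H=H4,
            cls_elman=cls_feat, mot_elman=mot_fc, pos_elman=pos_fc,
            cls_jordan=probs, mot_jordan=q,
        )
        out = ModelOutput(
            q_values=ad.reshape(q, (3,)),
            class_probs=ad.reshape(probs, (cfg.n_outputs,)),
        )
        return out, new_state

    # -- bookkeeping ---------------------------------------------------------
    def param_breakdown(self):
        return {name: int(t.size) for name, t in self.params.items()}

    def count_params(self):
        return sum(self.param_breakdown().values())

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def load_weights(self, weights, strict=True):
        for name, arr in weights.items():
            if name not in self.params:
                if strict:
                    raise KeyError(f"unknown parameter {name!r}")
                continue
            tgt = self.params[name]
            arr = np.asarray(arr, dtype=tgt.data.dtype)
            if arr.shape != tgt.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {arr.shape} != {tgt.data.shape}"
                )
            tgt.data = arr.copy()

    def get_weights(self):
        return {name: t.data.copy() for name, t in self.params.items()}

    def copy(self):
        """Independent clone (e.g. the target network)."""
        clone = BIAS3D(self.config, seed=0)
        clone.load_weights(self.get_weights())
        return clone

    def save(self, path):
        np.savez_compressed(path, **self.get_weights())
        manifest = {
            "config": _config_dict(self.config),
            "layers": {k: list(v.data.shape) for k, v in self.params.items()},
            "n_params": self.count_params(),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path):
        with open(str(path) + ".json") as fh:
            manifest = json.load(fh)
        c = manifest["config"]
        cfg = BIAS3DConfig(**{**c, "lrn": LRNParams(**c["lrn"])})
        model = cls(cfg, seed=0)
        data = np.load(path)
        model.load_weights({k: data[k] for k in data.files})
        return model


def _config_dict(cfg):
    d = asdict(cfg)
    for key in ("cls_conv", "mot_conv"):
        d[key] = list(d[key])
    return d
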