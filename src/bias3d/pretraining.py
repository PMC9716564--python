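"""Classifier pretraining on labeled orbital views.

Before end-to-end training, views are collected on a 9-degree grid around
each cube (40 views), labeled by the +-45-degree rule -- views within
[-45, +45] of the target face's frontal azimuth carry the cube's target
class, all others the background class -- balanced so target and background
counts match, and used to train the feed-forward classifier pipeline (the
convolutional stack plus first FC layer, without any recurrence) with
cross-entropy.  The trained weights transplant directly into the full
recurrent model's classifier pipeline; the pretraining softmax head is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .env3d import RenderConfig, camera_pose, relative_offset, render
from .glimpse import GlimpseConfig, extract_glimpse
from .model import BIAS3D, _param_specs
from .nn_layers import conv2d, conv_block, xavier_init
from .optim import Adam

TARGET_HALF_RANGE = 45.0  # degrees; inclusive on both sides


@dataclass
class LabeledView:
    view: np.ndarray  # (H, W, C)
    label: int  # class id; n_classes means background
    theta_offset: float  # signed degrees from the target face's front


def collect_views(scene, n_classes, step=9.0, render_cfg=None):
    """Render one view per theta on a `step`-degree grid over [0, 360).

    `step` must divide 360.  Labels follow the +-45 rule applied to the
    signed offset from the target face.
    """
    if step <= 0 or 360.0 % step != 0:
        raise ValueError("step must be positive and divide 360")
    render_cfg = render_cfg or RenderConfig()
    views = []
    for k in range(int(round(360.0 / step))):
        theta = k * step
        off = relative_offset(theta, scene)
        label = scene.target_class if abs(off) <= TARGET_HALF_RANGE else n_classes
        views.append(
            LabeledView(render(scene, camera_pose(theta), render_cfg), label, off)
        )
    return views


def balance(views, rng):
    """Keep all target-labeled views and subsample background views (without
    replacement) to the same count.  Returns (views, info); info flags the
    degenerate case where backgrounds were already the minority."""
    targets = [v for v in views if abs(v.theta_offset) <= TARGET_HALF_RANGE]
    background = [v for v in views if abs(v.theta_offset) > TARGET_HALF_RANGE]
    if not targets:
        raise ValueError("no target-labeled views to balance against")
    if len(background) >= len(targets):
        keep = rng.choice(len(background), size=len(targets), replace=False)
        background = [background[i] for i in sorted(keep)]
        info = {"balanced": True}
    else:
        info = {"balanced": False, "n_target": len(targets),
                "n_background": len(background)}
    return targets + background, info


def views_to_glimpse_arrays(cubes, n_classes, rng, step=9.0, render_cfg=None,
                            glimpse_cfg=None, balanced=True):
    """Stacked (X, y) training arrays of balanced glimpses over many cubes."""
    glimpse_cfg = glimpse_cfg or GlimpseConfig()
    X, y = [], []
    for scene in cubes:
        views = collect_views(scene, n_classes, step=step, render_cfg=render_cfg)
        if balanced:
            views, _ = balance(views, rng)
        for v in views:
            X.append(extract_glimpse(v.view, glimpse_cfg))
            y.append(v.label)
    return np.stack(X), np.array(y, dtype=int)


def collect_glimpse_dataset(cubes, n_classes, step=9.0, render_cfg=None,
                            glimpse_cfg=None):
    """All views of all cubes as (X, y, cube_id) glimpse arrays (unbalanced).

    Keeping every view lets the trainer redraw the balanced background
    subsample each epoch instead of committing to one draw.
    """
    glimpse_cfg = glimpse_cfg or GlimpseConfig()
    X, y, cube_id = [], [], []
    for i, scene in enumerate(cubes):
        for v in collect_views(scene, n_classes, step=step, render_cfg=render_cfg):
            X.append(extract_glimpse(v.view, glimpse_cfg))
            y.append(v.label)
            cube_id.append(i)
    return np.stack(X), np.array(y, dtype=int), np.array(cube_id, dtype=int)


def _balanced_indices(y, cube_id, background, rng):
    """Per-cube balanced index set: all target views plus an equally sized
    random background subsample (a fresh draw per call)."""
    idx = []
    for c in np.unique(cube_id):
        mask = cube_id == c
        tgt = np.flatnonzero(mask & (y != background))
        bg = np.flatnonzero(mask & (y == background))
        take = min(len(tgt), len(bg))
        idx.append(tgt)
        idx.append(rng.choice(bg, size=take, replace=False))
    return np.concatenate(idx)


class PretrainClassifier:
    """The classifier pipeline as a standalone feed-forward network.

    Same conv/LRN/pool stack and first FC layer as the full model (with the
    Elman/Jordan contexts absent, i.e. held at zero), topped with its own
    softmax head.  After training, :meth:`model_weights` yields the tensors
    that load into :class:`~bias3d.model.BIAS3D`.
    """

    dtype = BIAS3D.dtype

    def __init__(self, config, seed=0):
        self.config = config
        shapes = {n: (fi, fo, sh) for n, fi, fo, sh in _param_specs(config)}
        seed_rng = np.random.default_rng(seed)
        self.params = {}
        for name in BIAS3D.CLASSIFIER_PARAMS:
            fin, fout, shape = shapes[name]
            arr = (
                np.zeros(shape)
                if fin is None
                else xavier_init(fin, fout, int(seed_rng.integers(2**31)), shape=shape)
            )
            self.params[name] = Tensor(arr.astype(self.dtype), requires_grad=True)
        n_out = config.n_outputs
        self.params["pre_head_W"] = Tensor(
            xavier_init(config.cls_fc, n_out, int(seed_rng.integers(2**31))).astype(
                self.dtype
            ),
            requires_grad=True,
        )
        self.params["pre_head_b"] = Tensor(
            np.zeros(n_out, dtype=self.dtype), requires_grad=True
        )

    def forward(self, X):
        """Class probabilities for a glimpse batch (N, 16, 16, C)."""
        p = self.params
        lp = self.config.lrn
        X = np.asarray(X, dtype=self.dtype)
        h = conv_block(Tensor(X), p["cls_conv1_W"], p["cls_conv1_b"], lp)
        h = conv_block(h, p["cls_conv2_W"], p["cls_conv2_b"], lp)
        h = conv2d(h, p["cls_conv3_W"], p["cls_conv3_b"], act="relu")
        feat = ad.linear(
            ad.reshape(h, (X.shape[0], -1)), p["cls_fcej_Win"], p["cls_fcej_b"],
            act="relu",
        )
        return ad.softmax(ad.linear(feat, p["pre_head_W"], p["pre_head_b"]))

    def predict(self, X, batch_size=256):
        out = []
        with no_grad():
            for i in range(0, len(X), batch_size):
                out.append(self.forward(X[i:i + batch_size]).data)
        return np.concatenate(out).argmax(axis=1)

    def accuracy(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())

    def model_weights(self):
        """Weights for the full model's classifier pipeline (head dropped)."""
        return {
            name: self.params[name].data.copy()
            for name in BIAS3D.CLASSIFIER_PARAMS
        }

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


def pretrain_classifier(cubes, epochs=5, lr=1e-3, seed=0, config=None,
                        batch_size=64, step=9.0, render_cfg=None,
                        glimpse_cfg=None, data=None, net=None,
                        lr_decay_after=None, lr_decay=0.3):
    """Pretrain the classifier pipeline with cross-entropy on balanced views.

    Returns (classifier, history); `history["loss"]` holds per-epoch mean
    training loss.  `config` must be the BIAS3DConfig the weights will be
    loaded into (widths must match).  `data` supplies precomputed glimpse
    arrays and skips view collection: either `(X, y)` already balanced, or
    `(X, y, cube_id)` unbalanced, in which case the balanced background
    subsample is redrawn per cube each epoch.
    """
    if not cubes and data is None:
        raise ValueError("no cubes to pretrain on")
    if config is None:
        raise ValueError("a BIAS3DConfig is required to size the classifier")
    rng = np.random.default_rng(seed)
    cube_id = None
    if data is None:
        X, y, cube_id = collect_glimpse_dataset(
            cubes, config.n_classes, step=step,
            render_cfg=render_cfg, glimpse_cfg=glimpse_cfg,
        )
    elif len(data) == 3:
        X, y, cube_id = data
    else:
        X, y = data
    if len(np.unique(y)) < 2:
        raise ValueError("pretraining data must contain at least two classes")
    if net is None:
        net = PretrainClassifier(config, seed=int(rng.integers(2**31)))
    opt = Adam(net.params, lr=lr)
    onehot = np.eye(config.n_outputs, dtype=PretrainClassifier.dtype)[y]
    history = {"loss": []}
    for epoch in range(epochs):
        if lr_decay_after is not None and epoch == lr_decay_after:
            opt.lr = lr * lr_decay
        if cube_id is not None:
            epoch_idx = _balanced_indices(y, cube_id, config.n_classes, rng)
        else:
            epoch_idx = np.arange(len(X))
        order = rng.permutation(epoch_idx)
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            probs = net.forward(X[idx])
            ce = -(ad.log(probs + 1e-12) * Tensor(onehot[idx])).sum() / len(idx)
            net.zero_grad()
            ce.backward()
            opt.step()
            losses.append(ce.item())
        history["loss"].append(float(np.mean(losses)))
    return net, history
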