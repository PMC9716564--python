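"""Inference-time search and scoring.

At test time the agent exploits greedily (epsilon = 0): starting from a
random azimuth it renders, glimpses, and steps the camera until the maximum
class probability crosses the testing threshold with a non-background
argmax, or a step budget runs out.  A run succeeds when the confident
prediction equals the cube's target class.  Background confidence never
stops the search -- only a (possibly wrong) target-class prediction does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import no_grad
from .env3d import ACTIONS, RenderConfig, ViewCache, step_camera
from .glimpse import GlimpseConfig, crop_bounds, extract_glimpse
from .rl import softmax_probs


@dataclass
class SearchResult:
    trajectory: list  # (theta, action or None, max_prob, argmax_class) per visit
    steps_taken: int
    predicted_class: int
    success: bool
    terminated_by: str  # "threshold" or "max_steps"


@dataclass
class EvalConfig:
    threshold: float = 0.95
    max_steps: int = 50
    jump_length: float = 12.0
    policy: str = "greedy"  # or "random": the random-action baseline
    seed: int = 0


def run_search(scene, model, test_threshold=0.95, max_steps=50, rng=None,
               jump_length=12.0, policy="greedy", start_theta=None,
               render_cfg=None, glimpse_cfg=None):
    """Search one cube; returns a :class:`SearchResult`.

    ``policy="random"`` replaces the greedy action choice with uniform
    random actions (the search-free baseline) while keeping the same
    classifier stopping rule.
    """
    if not 0.0 < test_threshold < 1.0:
        raise ValueError("test threshold must lie in (0, 1)")
    rng = rng or np.random.default_rng(0)
    views = ViewCache(scene, render_cfg)
    glimpse_cfg = glimpse_cfg or GlimpseConfig()
    background = model.config.n_classes
    theta = float(rng.uniform(0.0, 360.0)) if start_theta is None else float(start_theta)
    state = model.reset_state()
    trajectory = []
    with no_grad():
        for move in range(max_steps + 1):
            out, state = model.forward(
                extract_glimpse(views.get(theta), glimpse_cfg), theta, state
            )
            p = out.class_probs.data
            pred = int(np.argmax(p))
            pmax = float(p.max())
            if pmax >= test_threshold and pred != background:
                trajectory.append((theta, None, pmax, pred))
                return SearchResult(
                    trajectory, move, pred, pred == scene.target_class, "threshold"
                )
            if move == max_steps:
                trajectory.append((theta, None, pmax, pred))
                return SearchResult(trajectory, move, pred, False, "max_steps")
            if policy == "random":
                action = int(rng.integers(3))
            else:
                action = int(np.argmax(softmax_probs(out.q_values.data)))
            trajectory.append((theta, ACTIONS[action], pmax, pred))
            theta = step_camera(theta, ACTIONS[action], jump_length)


def evaluate(cubes, model, cfg=None, render_cfg=None, glimpse_cfg=None):
    """Score a cube set; returns (metrics dict, list of SearchResults)."""
    if not cubes:
        raise ValueError("no cubes to evaluate")
    cfg = cfg or EvalConfig()
    rng = np.random.default_rng(cfg.seed)
    results = []
    for scene in cubes:
        results.append(
            run_search(
                scene, model, test_threshold=cfg.threshold,
                max_steps=cfg.max_steps, rng=rng, jump_length=cfg.jump_length,
                policy=cfg.policy, render_cfg=render_cfg,
                glimpse_cfg=glimpse_cfg,
            )
        )
    succ = np.array([r.success for r in results])
    steps = np.array([r.steps_taken for r in results])
    classified = np.array(
        [r.predicted_class == c.target_class for r, c in zip(results, cubes)]
    )
    per_class = {}
    for scene, res in zip(cubes, results):
        per_class.setdefault(scene.target_class, []).append(res.success)
    metrics = {
        "accuracy": float(succ.mean()),
        "classification_accuracy": float(classified.mean()),
        "mean_steps": float(steps.mean()),
        "median_steps": float(np.median(steps)),
        "per_class_accuracy": {
            k: float(np.mean(v)) for k, v in sorted(per_class.items())
        },
        "n": len(cubes),
    }
    return metrics, results


def trace_plot(result, scene, out_path, render_cfg=None, glimpse_cfg=None):
    """Write one PNG per visited step: the camera view with the three red
    concentric glimpse boxes, above the predicted class-probability bars and
    the ground-truth probabilities.  Returns the list of written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    from .env3d import camera_pose, relative_offset, render

    render_cfg = render_cfg or RenderConfig()
    glimpse_cfg = glimpse_cfg or GlimpseConfig()
    cy, cx = render_cfg.view_height // 2, render_cfg.view_width // 2
    n_out = None
    paths = []
    stem = str(out_path)
    if stem.endswith(".png"):
        stem = stem[:-4]
    for t, (theta, action, pmax, pred) in enumerate(result.trajectory):
        view = render(scene, camera_pose(theta), render_cfg)
        off = relative_offset(theta, scene)
        fig, (ax_v, ax_p) = plt.subplots(2, 1, figsize=(3.2, 4.6))
        ax_v.imshow(view.squeeze(), cmap="gray", vmin=0, vmax=1)
        for size in glimpse_cfg.window_sizes:
            r0, r1 = crop_bounds(cy, size)
            c0, c1 = crop_bounds(cx, size)
            ax_v.add_patch(
                Rectangle((c0 - 0.5, r0 - 0.5), r1 - r0, r1 - r0,
                          edgecolor="red", facecolor="none", linewidth=1.0)
            )
        ax_v.set_title(f"t={t}  theta={theta:.0f}  a={action}")
        ax_v.axis("off")
        if n_out is None:
            n_out = max(pred + 1, scene.target_class + 2)
        truth = np.zeros(n_out)
        truth[scene.target_class if abs(off) <= 45 else n_out - 1] = 1.0
        ax_p.bar(np.arange(n_out), truth, color="green", alpha=0.4, label="truth")
        ax_p.axhline(pmax, color="blue", linestyle="-.", label=f"max p (cls {pred})")
        ax_p.set_ylim(0, 1.05)
        ax_p.legend(fontsize=6)
        path = f"{stem}_step{t}.png"
        fig.savefig(path, dpi=80)
        plt.close(fig)
        paths.append(path)
    return paths
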