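"""Cluttered-cube dataset construction.

Builds the search benchmark: each cube carries one 28x28 target image on a
vertical face and composited clutter on the other three vertical faces.
Target images can come from external MNIST/QuickDraw-style collections
(IDX/NPY loaders) or from the built-in procedural glyph generator, which
draws n distinct stroke-pattern classes (circle, bars, crosses, ...) with
per-sample affine jitter so the whole pipeline is testable without any
download.

Clutter is composited from 2-4 randomly cropped fragments (8-16 px square)
of images belonging to *other* classes, giving the classifier hard negatives
that share local stroke statistics with real targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .env3d import CubeScene

CANVAS = 28

#: fixed colour palette for RGB colorization (fg/bg drawn with fg != bg)
PALETTE = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.2, 1.0),
    (1.0, 1.0, 0.0),
    (1.0, 0.0, 1.0),
    (0.0, 1.0, 1.0),
    (1.0, 1.0, 1.0),
    (1.0, 0.5, 0.0),
)


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (28, 28) grayscale or (28, 28, 3) RGB, values in [0, 1]
    label: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class DatasetSpec:
    n_classes: int = 10
    split_sizes: tuple = (48000, 12000, 10000)
    seed: int = 0
    mode: str = "grayscale"

    def __post_init__(self):
        if any(s <= 0 for s in self.split_sizes):
            raise ValueError("split sizes must be positive")
        if self.mode not in ("grayscale", "rgb"):
            raise ValueError("mode must be 'grayscale' or 'rgb'")


# -- procedural glyphs -----------------------------------------------------

# Stroke templates in unit coordinates [-1, 1]^2 (x right, y up).
_T = {
    "seg": lambda a, b: ("seg", np.array(a, float), np.array(b, float)),
    "circle": lambda c, r: ("circle", np.array(c, float), float(r)),
}
GLYPH_TEMPLATES = (
    (_T["circle"]((0, 0), 0.6),),
    (_T["seg"]((0, -0.7), (0, 0.7)),),
    (_T["seg"]((-0.6, -0.6), (0.6, 0.6)), _T["seg"]((-0.6, 0.6), (0.6, -0.6))),
    (
        _T["seg"]((-0.6, -0.5), (0.6, -0.5)),
        _T["seg"]((-0.6, 0.0), (0.6, 0.0)),
        _T["seg"]((-0.6, 0.5), (0.6, 0.5)),
    ),
    (
        _T["seg"]((-0.65, -0.55), (0.65, -0.55)),
        _T["seg"]((0.65, -0.55), (0.0, 0.6)),
        _T["seg"]((0.0, 0.6), (-0.65, -0.55)),
    ),
    (_T["seg"]((-0.6, 0), (0.6, 0)), _T["seg"]((0, -0.6), (0, 0.6))),
    (_T["seg"]((-0.45, 0.65), (-0.45, -0.55)), _T["seg"]((-0.45, -0.55), (0.55, -0.55))),
    (_T["seg"]((-0.6, 0.6), (0.6, 0.6)), _T["seg"]((0, 0.6), (0, -0.65))),
    (_T["seg"]((-0.6, -0.6), (0.6, 0.6)),),
    (
        _T["seg"]((-0.55, -0.55), (0.55, -0.55)),
        _T["seg"]((0.55, -0.55), (0.55, 0.55)),
        _T["seg"]((0.55, 0.55), (-0.55, 0.55)),
        _T["seg"]((-0.55, 0.55), (-0.55, -0.55)),
    ),
)
MAX_GLYPH_CLASSES = len(GLYPH_TEMPLATES)


def _pixel_grid(size=CANVAS):
    idx = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    x = idx[None, :].repeat(size, axis=0)
    y = (-idx)[:, None].repeat(size, axis=1)
    return x, y


def _rasterize(primitives, rotation_deg=0.0, shift=(0.0, 0.0), stroke_px=2.2,
               size=CANVAS, smooth=0.5):
    x, y = _pixel_grid(size)
    half_w = stroke_px / size  # stroke half-width in unit coords
    aa = 2.0 / size  # one-pixel antialiasing band
    rot = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    canvas = np.zeros((size, size))
    for prim in primitives:
        if prim[0] == "seg":
            a = R @ prim[1] + shift
            b = R @ prim[2] + shift
            ab = b - a
            denom = float(ab @ ab)
            px, py = x - a[0], y - a[1]
            t = np.clip((px * ab[0] + py * ab[1]) / max(denom, 1e-12), 0.0, 1.0)
            d = np.hypot(px - t * ab[0], py - t * ab[1])
        else:
            c = R @ prim[1] + shift
            d = np.abs(np.hypot(x - c[0], y - c[1]) - prim[2])
        canvas = np.maximum(canvas, np.clip((half_w + aa - d) / aa, 0.0, 1.0))
    if smooth:
        canvas = gaussian_filter(canvas, smooth)
    return np.clip(canvas, 0.0, 1.0)


def glyph_template(class_id, size=CANVAS):
    """Clean, jitter-free rendering of a glyph class (the oracle template)."""
    return _rasterize(GLYPH_TEMPLATES[class_id], size=size)


def synth_glyphs(n_classes, n_per_class, seed):
    """Procedural labeled 28x28 glyphs: n_classes distinct stroke patterns
    with per-sample rotation (+-15 deg), translation (+-2 px) and
    stroke-width jitter.  Deterministic under `seed`."""
    if not 2 <= n_classes <= MAX_GLYPH_CLASSES:
        raise ValueError(f"n_classes must be in [2, {MAX_GLYPH_CLASSES}]")
    rng = np.random.default_rng(seed)
    out = []
    for cls in range(n_classes):
        for _ in range(n_per_class):
            img = _rasterize(
                GLYPH_TEMPLATES[cls],
                rotation_deg=rng.uniform(-15, 15),
                shift=rng.uniform(-2.0, 2.0, size=2) * (2.0 / CANVAS),
                stroke_px=2.2 + rng.uniform(-0.4, 0.4),
            )
            out.append(LabeledImage(img, cls))
    return out


def nearest_template_label(img, n_classes):
    """Normalized-correlation nearest-template classification (test oracle)."""
    img = np.asarray(img, float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    v = img.ravel()
    v = v / max(np.linalg.norm(v), 1e-12)
    scores = []
    for cls in range(n_classes):
        t = glyph_template(cls).ravel()
        scores.append(float(v @ (t / np.linalg.norm(t))))
    return int(np.argmax(scores))


# -- composition -----------------------------------------------------------

def make_clutter(source_pool, rng, n_fragments=(2, 4), frag_sizes=(8, 16)):
    """Composite clutter texture: 2-4 randomly cropped fragments of pool
    images pasted at random positions, summed and clipped to [0, 1]."""
    if len(source_pool) == 0:
        raise ValueError("source pool must be non-empty")
    proto = np.asarray(source_pool[0], float)
    canvas = np.zeros_like(proto)
    H, W = proto.shape[:2]
    k = int(rng.integers(n_fragments[0], n_fragments[1] + 1))
    for _ in range(k):
        src = np.asarray(source_pool[rng.integers(len(source_pool))], float)
        s = int(rng.integers(frag_sizes[0], min(frag_sizes[1], H, W) + 1))
        sr = int(rng.integers(0, H - s + 1))
        sc = int(rng.integers(0, W - s + 1))
        dr = int(rng.integers(0, H - s + 1))
        dc = int(rng.integers(0, W - s + 1))
        canvas[dr:dr + s, dc:dc + s] += src[sr:sr + s, sc:sc + s]
    return np.clip(canvas, 0.0, 1.0)


def colorize(gray, fg_color, bg_color, threshold=0.2):
    """Map a grayscale image to RGB: pixels at or above `threshold` blend
    toward `fg_color` proportionally to intensity, the rest become
    `bg_color`."""
    fg = np.asarray(fg_color, float)
    bg = np.asarray(bg_color, float)
    if np.allclose(fg, bg):
        raise ValueError("foreground and background colours must differ")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    gray = np.asarray(gray, float)
    out = np.broadcast_to(bg, gray.shape + (3,)).copy()
    mask = gray >= threshold
    inten = gray[mask][:, None]
    out[mask] = (1.0 - inten) * bg + inten * fg
    return np.clip(out, 0.0, 1.0)


def random_colorize(gray, rng, threshold=0.2):
    fg_i = int(rng.integers(len(PALETTE)))
    bg_i = int(rng.integers(len(PALETTE) - 1))
    if bg_i >= fg_i:
        bg_i += 1
    return colorize(gray, PALETTE[fg_i], PALETTE[bg_i], threshold)


def build_cube(target, clutter, rng):
    """Assemble a CubeScene: target texture on the azimuth-0 face, the three
    clutter textures on the remaining vertical faces in shuffled order."""
    textures = [np.atleast_3d(np.asarray(c, float)) for c in clutter]
    tgt = np.atleast_3d(np.asarray(target.pixels, float))
    if len(textures) != 3:
        raise ValueError("exactly three clutter textures required")
    if any(t.shape != tgt.shape for t in textures):
        raise ValueError("all textures must share shape and channel count")
    order = rng.permutation(3)
    faces = {0.0: tgt}
    for az, idx in zip((90.0, 180.0, 270.0), order):
        faces[az] = textures[idx]
    return CubeScene(face_textures=faces, target_class=int(target.label))


def generate_split(images, spec):
    """Build disjoint train/val/test lists of cubes from labeled images.

    Source images are partitioned across the splits (no image leaks between
    them); within a split, each cube takes a random image as target and
    clutter composited from that split's other-class images.
    """
    total = sum(spec.split_sizes)
    if len(images) < total:
        raise ValueError(
            f"need at least {total} source images for splits {spec.split_sizes}, "
            f"got {len(images)}"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(images))
    splits = []
    start = 0
    for n_cubes in spec.split_sizes:
        pool = [images[i] for i in order[start:start + n_cubes]]
        start += n_cubes
        if spec.mode == "rgb":
            pool = [
                LabeledImage(random_colorize(im.pixels, rng), im.label) for im in pool
            ]
        cubes = []
        for _ in range(n_cubes):
            target = pool[rng.integers(len(pool))]
            others = [im.pixels for im in pool if im.label != target.label]
            if not others:
                raise ValueError("pool must contain images of more than one class")
            clutter = [make_clutter(others, rng) for _ in range(3)]
            cubes.append(build_cube(target, clutter, rng))
        splits.append(cubes)
    return tuple(splits)


# -- loaders and persistence ----------------------------------------------

def load_idx_images(images_path, labels_path, limit=None):
    """Read IDX-format (MNIST-style) images and labels into LabeledImages."""
    with open(images_path, "rb") as fh:
        magic = int.from_bytes(fh.read(4), "big")
        if magic != 2051:
            raise ValueError("not an IDX image file")
        n, h, w = (int.from_bytes(fh.read(4), "big") for _ in range(3))
        data = np.frombuffer(fh.read(n * h * w), dtype=np.uint8).reshape(n, h, w)
    with open(labels_path, "rb") as fh:
        magic = int.from_bytes(fh.read(4), "big")
        if magic != 2049:
            raise ValueError("not an IDX label file")
        n_l = int.from_bytes(fh.read(4), "big")
        labels = np.frombuffer(fh.read(n_l), dtype=np.uint8)
    if limit:
        data, labels = data[:limit], labels[:limit]
    return [LabeledImage(img / 255.0, int(lab)) for img, lab in zip(data, labels)]


def load_npy_images(images_path, labels_path, limit=None):
    """Read NPY arrays (N,28,28[,3]) in [0,1] or [0,255] plus integer labels."""
    data = np.load(images_path)
    labels = np.load(labels_path)
    if data.max() > 1.0:
        data = data / 255.0
    if limit:
        data, labels = data[:limit], labels[:limit]
    return [LabeledImage(img, int(lab)) for img, lab in zip(data, labels)]


def save_cubes(path, cubes):
    """Write a cube list as an NPZ bundle plus a JSON manifest."""
    faces = np.stack(
        [
            np.stack([c.face_textures[az] for az in (0.0, 90.0, 180.0, 270.0)])
            for c in cubes
        ]
    )
    labels = np.array([c.target_class for c in cubes])
    azimuths = np.array([c.target_face_azimuth for c in cubes])
    np.savez_compressed(path, faces=faces, labels=labels, azimuths=azimuths)
    manifest = {
        "n_cubes": len(cubes),
        "texture_shape": list(faces.shape[2:]),
        "face_order_azimuths": [0, 90, 180, 270],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_cubes(path):
    data = np.load(path)
    cubes = []
    for i in range(data["faces"].shape[0]):
        faces = {
            az: data["faces"][i, j]
            for j, az in enumerate((0.0, 90.0, 180.0, 270.0))
        }
        cubes.append(
            CubeScene(
                face_textures=faces,
                target_class=int(data["labels"][i]),
                target_face_azimuth=float(data["azimuths"][i]),
            )
        )
    return cubes
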