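"""Foveated attentional glimpse extraction.

Three concentric windows (16, 32 and 50 px by default) are cropped at the
view centre; every window except the smallest is resized down to the
smallest with bilinear interpolation, and the results are stacked along
depth, smallest first.  The small window plays the role of the
high-resolution fovea, the large ones of the low-resolution periphery.

Crop intervals are half-open: a window of size s centred at c covers
[c - s//2, c - s//2 + s), which reproduces the standard worked example for a
75x100 view -- windows 16/32/50 centred at (y, x) = (35, 50) cover rows/cols
[27,43)/[42,58), [19,51)/[34,66) and [10,60)/[25,75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GlimpseConfig:
    window_sizes: tuple = (16, 32, 50)
    out_size: int = 16

    def __post_init__(self):
        sizes = tuple(self.window_sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("window sizes must be strictly increasing")
        if self.out_size != sizes[0]:
            raise ValueError("out_size must equal the smallest window")
        self.window_sizes = sizes

    @property
    def n_windows(self):
        return len(self.window_sizes)


def crop_bounds(center, size):
    """Half-open pixel interval [lo, hi) of a window of `size` at `center`."""
    lo = int(center) - size // 2
    return lo, lo + size


def bilinear_resize(img, out_h, out_w):
    """Centre-aligned bilinear resize of an (H, W, C) array."""
    H, W, _ = img.shape
    rows = (np.arange(out_h) + 0.5) * (H / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (W / out_w) - 0.5
    rows = np.clip(rows, 0, H - 1)
    cols = np.clip(cols, 0, W - 1)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (rows - r0)[:, None, None]
    fc = (cols - c0)[None, :, None]
    top = img[np.ix_(r0, c0)] * (1 - fc) + img[np.ix_(r0, c1)] * fc
    bot = img[np.ix_(r1, c0)] * (1 - fc) + img[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def extract_glimpse(view, cfg=None):
    """Extract the stacked multi-resolution glimpse from the view centre.

    Returns an (out, out, a*C) array where a = number of windows and C = view
    channels; channel order within each window is preserved and windows are
    stacked smallest-first.
    """
    if cfg is None:
        cfg = GlimpseConfig()
    view = np.asarray(view, dtype=float)
    if view.ndim == 2:
        view = view[:, :, None]
    H, W, _ = view.shape
    cy, cx = H // 2, W // 2
    largest = cfg.window_sizes[-1]
    for c, dim in ((cy, H), (cx, W)):
        lo, hi = crop_bounds(c, largest)
        if lo < 0 or hi > dim:
            raise ValueError(
                f"view of size {H}x{W} too small for a {largest}px centre window"
            )
    slices = []
    for size in cfg.window_sizes:
        r0, r1 = crop_bounds(cy, size)
        c0, c1 = crop_bounds(cx, size)
        crop = view[r0:r1, c0:c1]
        if size != cfg.out_size:
            crop = bilinear_resize(crop, cfg.out_size, cfg.out_size)
        slices.append(crop)
    return np.concatenate(slices, axis=2)
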