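import numpy as np
import pytest

from bias3d import build_cube, make_clutter, synth_glyphs


@pytest.fixture(scope="session")
def glyphs():
    return synth_glyphs(3, 10, seed=7)


@pytest.fixture(scope="session")
def scene(glyphs):
    """One grayscale cluttered cube with a class-0 glyph target."""
    rng = np.random.default_rng(11)
    target = next(im for im in glyphs if im.label == 0)
    pool = [im.pixels for im in glyphs if im.label != 0]
    return build_cube(target, [make_clutter(pool, rng) for _ in range(3)], rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
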