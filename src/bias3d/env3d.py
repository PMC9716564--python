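"""Cube world: a textured cube at the origin and a camera orbiting it.

The camera sits on a horizontal circle of radius ``r`` (default 2.5 world
units), always looking at the origin; its single degree of freedom is the
azimuth theta.  Views are rendered with a software pinhole-projection
ray caster: for each front-facing vertical face the pixel rays are
intersected with the face plane and the texture is sampled bilinearly.
Rendering is fully deterministic.

Conventions: camera position = (r sin(theta), 0, r cos(theta)); the face at
azimuth 0 has outward normal +z, so theta = 0 places the camera directly in
front of it.  Views are stored height-first (row 0 at the top).  The cube
edge is 2 world units (faces span [-1, 1]); vertical FOV defaults to 45 deg
so that the facing texture fills most of the view height at r = 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FACE_AZIMUTHS = (0.0, 90.0, 180.0, 270.0)
ACTIONS = ("right", "left", "stay")


@dataclass
class CubeScene:
    """Four vertical face textures, exactly one of which carries the target.

    ``face_textures`` maps azimuth in {0, 90, 180, 270} to an (H, W, C) array
    in [0, 1].  The two horizontal faces are a constant fill (they are edge-on
    for the equatorial camera and never rendered).
    """

    face_textures: dict
    target_class: int
    target_face_azimuth: float = 0.0
    top_bottom_fill: float = 0.0

    def __post_init__(self):
        if set(self.face_textures) != set(FACE_AZIMUTHS):
            raise ValueError("face_textures must cover azimuths 0, 90, 180, 270")
        textures = {}
        shapes = set()
        for az, tex in self.face_textures.items():
            arr = np.asarray(tex, dtype=float)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            textures[az] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError("all four face textures must share shape and channels")
        if self.target_face_azimuth not in FACE_AZIMUTHS:
            raise ValueError("target_face_azimuth must be one of 0, 90, 180, 270")
        self.face_textures = textures

    @property
    def channels(self):
        return next(iter(self.face_textures.values())).shape[2]


@dataclass
class CameraPose:
    r: float
    theta: float
    phi: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("orbit radius must be positive")
        if self.phi != 0.0:
            raise ValueError("polar angle is fixed at 0 in this environment")
        self.theta = self.theta % 360.0

    @property
    def position(self):
        t = np.deg2rad(self.theta)
        return np.array([self.r * np.sin(t), 0.0, self.r * np.cos(t)])


@dataclass
class RenderConfig:
    view_height: int = 75
    view_width: int = 100
    cube_edge: float = 2.0
    vertical_fov: float = 45.0
    background: float = 0.0

    def __post_init__(self):
        if self.view_height <= 0 or self.view_width <= 0:
            raise ValueError("view dimensions must be positive")
        if not 0.0 < self.vertical_fov < 180.0:
            raise ValueError("vertical FOV must lie in (0, 180)")
        if self.cube_edge <= 0:
            raise ValueError("cube edge must be positive")


def camera_pose(theta, r=2.5):
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return CameraPose(r=r, theta=float(theta))


def step_camera(theta, action, jump):
    """Move the camera on its orbit: right -> theta+jump, left -> theta-jump."""
    if jump < 0:
        raise ValueError("jump length must be >= 0")
    if action == "right":
        return (theta + jump) % 360.0
    if action == "left":
        return (theta - jump) % 360.0
    if action == "stay":
        return theta % 360.0
    raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")


def relative_offset(theta, scene):
    """Signed angular distance from the target face's frontal azimuth,
    wrapped to (-180, 180]."""
    off = (theta - scene.target_face_azimuth) % 360.0
    if off > 180.0:
        off -= 360.0
    return off


def _bilinear_sample(tex, rows, cols):
    """Sample (H,W,C) texture at fractional pixel coords with edge clamping."""
    H, W, _ = tex.shape
    r = np.clip(rows, 0.0, H - 1.0)
    c = np.clip(cols, 0.0, W - 1.0)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (r - r0)[..., None]
    fc = (c - c0)[..., None]
    top = tex[r0, c0] * (1 - fc) + tex[r0, c1] * fc
    bot = tex[r1, c0] * (1 - fc) + tex[r1, c1] * fc
    return top * (1 - fr) + bot * fr


def _camera_basis(pose):
    cam = pose.position
    fwd = -cam / np.linalg.norm(cam)
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, up)
    right /= np.linalg.norm(right)
    true_up = np.cross(right, fwd)
    return cam, fwd, right, true_up


def face_frame(azimuth, half_edge):
    """(centre point, tangent axis, up axis, outward normal) of a vertical face."""
    a = np.deg2rad(azimuth)
    normal = np.array([np.sin(a), 0.0, np.cos(a)])
    tangent = np.array([np.cos(a), 0.0, -np.sin(a)])
    up = np.array([0.0, 1.0, 0.0])
    return normal * half_edge, tangent, up, normal


def project_point(point, pose, cfg):
    """Project a world point to (row, col) pixel coordinates (pixel centres).

    Returns (row, col, depth); depth <= 0 means the point is behind the camera.
    """
    cam, fwd, right, true_up = _camera_basis(pose)
    v = np.asarray(point, float) - cam
    depth = v @ fwd
    fpix = (cfg.view_height / 2.0) / np.tan(np.deg2rad(cfg.vertical_fov) / 2.0)
    x = (v @ right) / depth * fpix if depth != 0 else np.inf
    y = (v @ true_up) / depth * fpix if depth != 0 else np.inf
    col = x + cfg.view_width / 2.0 - 0.5
    row = cfg.view_height / 2.0 - 0.5 - y
    return row, col, depth


def visible_faces(pose, cfg):
    """Azimuths of vertical faces passing the front-face test n . cam > e/2."""
    half = cfg.cube_edge / 2.0
    cam = pose.position
    out = []
    for az in FACE_AZIMUTHS:
        _, _, _, n = face_frame(az, half)
        if n @ cam > half:
            out.append(az)
    return out


def render(scene, pose, cfg=None):
    """Render the scene to an (H, W, C) float view in [0, 1]."""
    if cfg is None:
        cfg = RenderConfig()
    C = scene.channels
    H, W = cfg.view_height, cfg.view_width
    half = cfg.cube_edge / 2.0
    cam, fwd, right, true_up = _camera_basis(pose)
    fpix = (H / 2.0) / np.tan(np.deg2rad(cfg.vertical_fov) / 2.0)

    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    xs = (jj + 0.5 - W / 2.0) / fpix
    ys = (H / 2.0 - (ii + 0.5)) / fpix
    dirs = fwd[None, None, :] + xs[..., None] * right + ys[..., None] * true_up

    view = np.full((H, W, C), float(cfg.background))
    depth = np.full((H, W), np.inf)
    for az in visible_faces(pose, cfg):
        centre, tangent, up, normal = face_frame(az, half)
        dn = dirs @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((centre - cam) @ normal) / dn
        valid = (dn < 0) & (t > 0)
        if not valid.any():
            continue
        pts = cam + t[..., None] * dirs
        rel = pts - centre
        u = rel @ tangent
        v = rel @ up
        inside = valid & (np.abs(u) <= half) & (np.abs(v) <= half)
        nearer = inside & (t < depth)
        if not nearer.any():
            continue
        tex = scene.face_textures[az]
        th, tw, _ = tex.shape
        cols = (u[nearer] / half + 1.0) / 2.0 * tw - 0.5
        rows = (1.0 - v[nearer] / half) / 2.0 * th - 0.5
        view[nearer] = _bilinear_sample(tex, rows, cols)
        depth[nearer] = t[nearer]
    return view


class ViewCache:
    """Memoizes rendered views of one scene by azimuth (rendering is pure)."""

    def __init__(self, scene, cfg=None):
        self.scene = scene
        self.cfg = cfg or RenderConfig()
        self._cache = {}

    def get(self, theta):
        key = round(theta % 360.0, 6)
        if key not in self._cache:
            self._cache[key] = render(self.scene, camera_pose(key), self.cfg)
        return self._cache[key]
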