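"""Seeded generator of synthetic fundus-like scenes with vessel ground truth.

Real fundus photographs show dark, branching, curvilinear vessels of
decreasing calibre on a bright circular disc with uneven illumination and
sensor noise.  The generator emulates exactly those statistics — and no
more (no optic disc, fovea or lesions) — so that training, evaluation and
every test can run without downloaded data:

1. **Vessel trees**: random walks started on the rim of the field of view
   heading inward.  Each walker steps a fixed length with its heading
   perturbed by Gaussian noise (``curl``), stamps an anti-aliased disc of
   its current width at every step, spawns a child walker with probability
   ``branch_prob`` per step (widths decay by ``width_decay`` at a branch),
   and dies when its width falls below one pixel or it leaves the disc.
   The accumulated soft stamp is thresholded at 0.5, keeping the ground
   truth strictly binary without stair-stepped single-pixel vessels.
2. **Rendering**: bright base intensity with radial illumination falloff,
   vessels darkened by ``vessel_contrast``, Gaussian blur (sigma 1), additive
   Gaussian noise, circular FOV mask (zero outside), clipped to [0,1].

Everything is deterministic given the seed, at every granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .data import FundusRecord


@dataclass
class SceneParams:
    """Knobs of the synthetic scene; defaults give DRIVE-like statistics
    at desk scale (dark vessels covering a few percent of a bright disc)."""

    size: tuple[int, int] = (128, 128)
    n_trees: int = 3
    branch_prob: float = 0.03
    initial_width: float = 3.0
    width_decay: float = 0.8
    step_length: float = 2.0
    curl: float = 0.15
    vessel_contrast: float = 0.35
    noise_sigma: float = 0.02
    illumination_strength: float = 0.3
    fov_radius_frac: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 64 or w < 64:
            raise ValueError(f"scene must be at least 64x64, got {self.size}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError(f"branch_prob must lie in [0,1], got {self.branch_prob}")
        if not 0.0 < self.width_decay <= 1.0:
            raise ValueError(f"width_decay must lie in (0,1], got {self.width_decay}")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError(f"fov_radius_frac must lie in (0,1], got {self.fov_radius_frac}")


def _fov_mask(params: SceneParams) -> np.ndarray:
    h, w = params.size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = params.fov_radius_frac * min(h, w) / 2
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.int64)


def _stamp_disc(canvas: np.ndarray, y: float, x: float, radius: float) -> None:
    """Accumulate an anti-aliased disc of given radius onto the canvas."""
    h, w = canvas.shape
    r_out = radius + 1.0
    y0, y1 = max(0, int(y - r_out)), min(h, int(y + r_out) + 2)
    x0, x1 = max(0, int(x - r_out)), min(w, int(x + r_out) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    soft = np.clip(radius + 0.5 - dist, 0.0, 1.0)  # 1 inside, ramp at the rim
    np.maximum(canvas[y0:y1, x0:x1], soft, out=canvas[y0:y1, x0:x1])


def generate_vessel_tree(params: SceneParams) -> np.ndarray:
    """Binary vessel mask from branching random walks inside the FOV disc."""
    h, w = params.size
    rng = np.random.default_rng(params.seed)
    fov = _fov_mask(params).astype(bool)
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r_disc = params.fov_radius_frac * min(h, w) / 2
    canvas = np.zeros((h, w), dtype=np.float64)
    max_steps = 4 * (h + w)

    # walkers: (y, x, heading, width)
    walkers: list[tuple[float, float, float, float]] = []
    for _ in range(params.n_trees):
        phi = rng.uniform(0, 2 * math.pi)
        y = cy + 0.95 * r_disc * math.sin(phi)
        x = cx + 0.95 * r_disc * math.cos(phi)
        heading = phi + math.pi + rng.normal(0, 0.3)  # point roughly inward
        walkers.append((y, x, heading, params.initial_width))

    while walkers:
        y, x, heading, width = walkers.pop()
        for _ in range(max_steps):
            if width < 1.0:
                break
            if (y - cy) ** 2 + (x - cx) ** 2 > r_disc * r_disc:
                break
            _stamp_disc(canvas, y, x, width / 2)
            heading += rng.normal(0.0, params.curl)
            y += params.step_length * math.sin(heading)
            x += params.step_length * math.cos(heading)
            if rng.random() < params.branch_prob:
                child_heading = heading + rng.choice((-1, 1)) * rng.uniform(0.4, 1.0)
                child_width = width * params.width_decay
                walkers.append((y, x, child_heading, child_width))
                width *= params.width_decay
    gt = (canvas >= 0.5).astype(np.int64)
    gt[~fov] = 0
    return gt


def render_fundus(gt: np.ndarray, params: SceneParams) -> FundusRecord:
    """Render one scene around a vessel mask; returns image + gt + fov."""
    gt = np.asarray(gt)
    if gt.shape != tuple(params.size):
        raise ValueError(f"gt shape {gt.shape} != params.size {params.size}")
    h, w = params.size
    rng = np.random.default_rng(params.seed + 1)
    fov = _fov_mask(params)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = params.fov_radius_frac * min(h, w) / 2
    radial = np.hypot(yy - cy, xx - cx) / max(r, 1.0)
    image = 0.75 * (1.0 - params.illumination_strength * radial**2)
    image = image - params.vessel_contrast * gt
    image = ndimage.gaussian_filter(image, sigma=1.0)
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    image[fov == 0] = 0.0
    return FundusRecord(id=f"synth{params.seed:05d}", image=image,
                        label=gt.astype(np.int64), fov=fov)


def generate_scene(params: SceneParams) -> FundusRecord:
    return render_fundus(generate_vessel_tree(params), params)


def generate_dataset(n: int, params: SceneParams | None = None, seed: int = 0
                     ) -> list[FundusRecord]:
    """Generate ``n`` scenes with per-record seeds ``seed + index``."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    params = params if params is not None else SceneParams()
    return [generate_scene(replace(params, seed=seed + i)) for i in range(n)]
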