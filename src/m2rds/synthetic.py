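"""Seeded synthetic fixtures and evaluation metrics.

Generators render anti-aliased line-like structures (crossing lines,
Archimedean spirals, circles of known curvature) on the 0-255 display scale,
degrade them with additive correlated Gaussian noise K_rho * n_sigma (white
noise of standard deviation sigma convolved with a unit-mass Gaussian of
standard deviation rho), and provide the ground truth needed by the
evaluation metrics (centrelines for the crossing score, analytic
curvature for the gauge-frame check).  All generators are pure functions of
their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GAUSS_TRUNCATE

__all__ = [
    "NoiseSpec",
    "make_crossing_lines",
    "make_spirals",
    "make_circle",
    "add_correlated_noise",
    "make_square_mask",
    "psnr",
    "crossing_score",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive correlated noise: white noise of intensity ``sigma`` (0-255
    scale) convolved with a Gaussian of standard deviation ``rho`` pixels."""

    sigma: float = 255.0
    rho: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.rho < 0:
            raise ValueError("sigma and rho must be non-negative")


def _soft_band(dist: np.ndarray, width: float, contrast: float) -> np.ndarray:
    """Anti-aliased band profile: full intensity inside |dist| < width/2,
    linear one-pixel falloff outside (area-sampling approximation)."""
    return contrast * np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)


def make_crossing_lines(
    H: int,
    W: int,
    angles=(0.0, 90.0),
    width: float = 3.0,
    contrast: float = 255.0,
):
    """Bright anti-aliased lines through the image centre at the given angles
    (degrees, measured from the x/row axis).

    Returns ``(image, centrelines)`` where ``centrelines[i]`` is an (M, 2)
    integer array of pixel coordinates on the i-th line's centreline.
    """
    angles = [float(a) for a in angles]
    if len(angles) < 2:
        raise ValueError("need at least two angles")
    for i, a in enumerate(angles):
        for b in angles[i + 1 :]:
            if abs((a - b + 90.0) % 180.0 - 90.0) < 5.0:
                raise ValueError(f"angles {a} and {b} are closer than 5 degrees")
    cx, cy = (H - 1) / 2.0, (W - 1) / 2.0
    x = np.arange(H)[:, None] - cx
    y = np.arange(W)[None, :] - cy
    img = np.zeros((H, W))
    centrelines = []
    for a in angles:
        t = np.radians(a)
        # distance to the line through the centre with direction (cos t, sin t)
        dist = np.abs(-np.sin(t) * x + np.cos(t) * y)
        img = np.maximum(img, _soft_band(dist, width, contrast))
        # centreline pixels: march along the direction, round to grid
        span = int(np.hypot(H, W))
        s = np.arange(-span, span + 1)
        px = np.round(cx + s * np.cos(t)).astype(int)
        py = np.round(cy + s * np.sin(t)).astype(int)
        keep = (px >= 0) & (px < H) & (py >= 0) & (py < W)
        pts = np.unique(np.stack([px[keep], py[keep]], axis=1), axis=0)
        centrelines.append(pts)
    return img, centrelines


def _render_curve(H: int, W: int, pts: np.ndarray, width: float, contrast: float) -> np.ndarray:
    """Anti-aliased rendering of a densely sampled polyline via the distance
    to its nearest sample point."""
    tree = cKDTree(pts)
    xx, yy = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    q = np.stack([xx.ravel(), yy.ravel()], axis=1)
    dist, _ = tree.query(q, k=1)
    return _soft_band(dist.reshape(H, W), width, contrast)


def make_spirals(
    H: int = 128,
    W: int = 128,
    n_arms: int = 2,
    pitch: float = 9.0,
    width: float = 5.0,
    contrast: float = 255.0,
    turns: float = 3.5,
) -> np.ndarray:
    """Cartoon image of overlapping Archimedean spiral arms.

    Arms are r = pitch/(2*pi) * phi; arms alternate winding direction, so the
    curves genuinely overlap and cross each other several times per turn —
    the structure whose restoration distinguishes orientation-aware from
    planar filtering.
    """
    cx, cy = (H - 1) / 2.0, (W - 1) / 2.0
    img = np.zeros((H, W))
    b = pitch / (2 * np.pi)
    phi = np.linspace(0.0, 2 * np.pi * turns, max(int(400 * turns), 400))
    rmax = min(H, W) / 2.0 - 2.0
    for arm in range(n_arms):
        off = 2 * np.pi * arm / n_arms
        sign = 1.0 if arm % 2 == 0 else -1.0  # alternate chirality: crossings
        r = b * phi
        keep = r <= rmax
        px = cx + r[keep] * np.cos(sign * phi[keep] + off)
        py = cy + r[keep] * np.sin(sign * phi[keep] + off)
        img = np.maximum(img, _render_curve(H, W, np.stack([px, py], axis=1), width, contrast))
    return np.clip(img, 0.0, 255.0)


def make_circle(H: int, W: int, r: float, width: float = 3.0, contrast: float = 255.0):
    """Anti-aliased ring of radius r; returns ``(image, curvature)`` with the
    analytic curvature label 1/r."""
    if r >= min(H, W) / 2.0:
        raise ValueError(f"radius {r} does not fit in a {H}x{W} image")
    if r <= 0:
        raise ValueError("radius must be positive")
    cx, cy = (H - 1) / 2.0, (W - 1) / 2.0
    x = np.arange(H)[:, None] - cx
    y = np.arange(W)[None, :] - cy
    dist = np.abs(np.hypot(x, y) - r)
    return _soft_band(dist, width, contrast), 1.0 / r


def add_correlated_noise(f: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """f + K_rho * n_sigma, kept in float (no clipping) so the PSNR of the
    degraded input is well defined."""
    f = np.asarray(f, dtype=float)
    if spec.sigma == 0:
        return f.copy()
    rng = np.random.default_rng(spec.seed)
    n = rng.normal(0.0, spec.sigma, size=f.shape)
    if spec.rho > 0:
        n = ndimage.gaussian_filter(n, spec.rho, mode="reflect", truncate=GAUSS_TRUNCATE)
    return f + n


def make_square_mask(H: int, W: int, side: int, centre=None) -> np.ndarray:
    """Boolean known-pixel mask with a hidden ``side x side`` square.

    True marks known pixels; the square (the inpainting region) is False and
    must lie fully inside the image.
    """
    if centre is None:
        centre = ((H - 1) / 2.0, (W - 1) / 2.0)
    cx, cy = centre
    x0 = int(round(cx - side / 2.0 + 0.5))
    y0 = int(round(cy - side / 2.0 + 0.5))
    if x0 < 0 or y0 < 0 or x0 + side > H or y0 + side > W:
        raise ValueError("square must lie fully inside the image")
    mask = np.ones((H, W), dtype=bool)
    mask[x0 : x0 + side, y0 : y0 + side] = False
    return mask


def psnr(f: np.ndarray, g: np.ndarray) -> float:
    """Peak signal-to-noise ratio 10 log10(255^2 / MSE) in dB (inf if equal)."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    mse = float(np.mean((f - g) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def crossing_score(image: np.ndarray, centrelines, hole_mask: np.ndarray) -> list[float]:
    """Per-line ratio of mean centreline intensity inside the hidden region to
    that outside.  A ratio >= 0.5 on every line means the crossing has been
    restored through the hole."""
    image = np.asarray(image, dtype=float)
    hole = ~np.asarray(hole_mask, dtype=bool)  # True inside the hidden square
    ratios = []
    for pts in centrelines:
        inside = hole[pts[:, 0], pts[:, 1]]
        vals = image[pts[:, 0], pts[:, 1]]
        if not inside.any() or inside.all():
            raise ValueError("centreline must cross the hidden region boundary")
        mean_in = float(vals[inside].mean())
        mean_out = float(vals[~inside].mean())
        ratios.append(mean_in / max(mean_out, 1e-12))
    return ratios
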