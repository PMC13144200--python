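"""Discrete geometry and calculus on the position-orientation grid M2 = R2 x S1.

The grid carries an image-like spatial part (rows = x, columns = y, reflective
extension) and a periodic orientation axis with N equally spaced angles
theta_k = 2*pi*k/N.  The roto-translation invariant frame is

    A1 = cos(theta) d/dx + sin(theta) d/dy      (along the orientation)
    A2 = -sin(theta) d/dx + cos(theta) d/dy     (lateral)
    A3 = d/dtheta                               (angular)

All finite differences sample off-grid points with (bi/tri)linear interpolation,
using reflective spatial extension and periodic orientational extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "M2Grid",
    "OrientationScore",
    "invariant_frame_directions",
    "invariant_samples",
    "directional_derivative",
    "spatial_laplacian",
    "upwind_gradient_norm",
    "se2_gaussian_smooth",
    "commutator_table",
]

#: truncation radius (in standard deviations) for all Gaussian convolutions;
#: large enough that the discrete kernel matches the sampled Gaussian to ~1e-9
GAUSS_TRUNCATE = 6.0


@dataclass(frozen=True)
class M2Grid:
    """Regular H x W x N grid on M2.

    Parameters
    ----------
    H, W : int
        Spatial row/column counts.
    N : int
        Number of orientations; the angular step is exactly ``2*pi/N``.
    dxy : float
        Spatial step in pixels (default 1).
    """

    H: int
    W: int
    N: int
    dxy: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"need at least 4 orientations, got N={self.N}")
        if self.H < 3 or self.W < 3:
            raise ValueError("spatial grid must be at least 3x3")
        if self.dxy <= 0:
            raise ValueError("spatial step must be positive")

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.N

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.N) * self.dtheta

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.H, self.W, self.N)


@dataclass
class OrientationScore:
    """Real-valued field on an M2 grid; the state evolved by the PDE."""

    values: np.ndarray
    grid: M2Grid = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("orientation score contains non-finite entries")

    def copy(self) -> "OrientationScore":
        return OrientationScore(self.values.copy(), self.grid)


def invariant_frame_directions(theta_index: int, grid: M2Grid):
    """Coefficients (c_x, c_y, c_theta) of A1, A2, A3 at orientation theta_k."""
    if not 0 <= theta_index < grid.N:
        raise IndexError(f"orientation index {theta_index} out of range [0, {grid.N})")
    th = theta_index * grid.dtheta
    a1 = np.array([np.cos(th), np.sin(th), 0.0])
    a2 = np.array([-np.sin(th), np.cos(th), 0.0])
    a3 = np.array([0.0, 0.0, 1.0])
    return a1, a2, a3


def _shift_slice(a: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Sample ``a[x + dx, y + dy]`` (bilinear, reflective extension).

    The offset is constant over the slice, so the interpolation reduces to a
    convex combination of four integer-shifted copies, which is much faster
    than generic interpolation and keeps the stencil weights explicit (they
    must be non-negative for the max-min principle).
    """
    ix, iy = int(np.floor(dx)), int(np.floor(dy))
    fx, fy = dx - ix, dy - iy
    pad = 2 + max(abs(ix), abs(iy))
    ap = np.pad(a, pad, mode="symmetric")
    H, W = a.shape

    def block(sx: int, sy: int) -> np.ndarray:
        return ap[pad + sx : pad + sx + H, pad + sy : pad + sy + W]

    w00 = (1 - fx) * (1 - fy)
    w01 = (1 - fx) * fy
    w10 = fx * (1 - fy)
    w11 = fx * fy
    out = w00 * block(ix, iy)
    if w10 != 0.0:
        out += w10 * block(ix + 1, iy)
    if w01 != 0.0:
        out += w01 * block(ix, iy + 1)
    if w11 != 0.0:
        out += w11 * block(ix + 1, iy + 1)
    return out


def invariant_samples(values: np.ndarray, grid: M2Grid, i: int):
    """Neighbour samples ``U(p + e_i)``, ``U(p - e_i)`` and the step size.

    One step along A1/A2 displaces by ``dxy`` spatially (never in theta), one
    step along A3 by ``dtheta`` (never spatially), so the stencils decouple per
    axis and the per-axis stability constants of the explicit scheme apply.
    """
    if i == 3:
        return np.roll(values, -1, axis=2), np.roll(values, 1, axis=2), grid.dtheta
    if i not in (1, 2):
        raise ValueError(f"frame index must be 1, 2 or 3, got {i}")
    up = np.empty_like(values)
    um = np.empty_like(values)
    for k in range(grid.N):
        th = k * grid.dtheta
        if i == 1:
            dx, dy = np.cos(th), np.sin(th)
        else:
            dx, dy = -np.sin(th), np.cos(th)
        up[:, :, k] = _shift_slice(values[:, :, k], dx, dy)
        um[:, :, k] = _shift_slice(values[:, :, k], -dx, -dy)
    return up, um, grid.dxy


def spatial_laplacian(values: np.ndarray, grid: M2Grid) -> np.ndarray:
    """Axis-aligned 5-point spatial Laplacian per orientation slice."""
    pad = np.pad(values, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
    H, W = grid.H, grid.W
    return (
        pad[2:, 1 : W + 1] + pad[: H, 1 : W + 1] + pad[1 : H + 1, 2:] + pad[1 : H + 1, : W]
        - 4.0 * values
    ) / grid.dxy**2


def _axis_second(values: np.ndarray, grid: M2Grid, axis: int) -> np.ndarray:
    pad_width = [(0, 0), (0, 0), (0, 0)]
    pad_width[axis] = (1, 1)
    pad = np.pad(values, pad_width, mode="symmetric")
    n = values.shape[axis]
    sl_p = [slice(None)] * 3
    sl_m = [slice(None)] * 3
    sl_p[axis] = slice(2, n + 2)
    sl_m[axis] = slice(0, n)
    return (pad[tuple(sl_p)] - 2.0 * values + pad[tuple(sl_m)]) / grid.dxy**2


def directional_derivative(
    U: OrientationScore, i: int, order: int, corrected: bool = True
) -> np.ndarray:
    """First or second central difference along invariant frame direction i.

    Off-grid samples use bilinear interpolation.  For ``order=2`` the
    interpolation itself contributes an O(1) excess of axis-aligned diffusion,
    |c_x|(1-|c_x|) d_xx + |c_y|(1-|c_y|) d_yy, at orientations not aligned
    with the grid; with ``corrected=True`` (default) this known bias is
    subtracted, restoring O(h^2) consistency.  The uncorrected stencil is a
    convex combination of neighbours (needed by the max-min principle) and is
    what the monotone diffusion scheme uses for its anisotropic part.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not np.all(np.isfinite(U.values)):
        raise ValueError("non-finite orientation score")
    up, um, h = invariant_samples(U.values, U.grid, i)
    if order == 1:
        return (up - um) / (2.0 * h)
    out = (up - 2.0 * U.values + um) / (h * h)
    if corrected and i in (1, 2):
        out = out - _interp_bias(U.values, U.grid, i)
    return out


def _interp_bias(values: np.ndarray, grid: M2Grid, i: int) -> np.ndarray:
    """Bilinear-interpolation bias of the directional second difference."""
    thetas = grid.thetas
    if i == 1:
        dxs, dys = np.abs(np.cos(thetas)), np.abs(np.sin(thetas))
    else:
        dxs, dys = np.abs(np.sin(thetas)), np.abs(np.cos(thetas))
    a = dxs * (1.0 - dxs)
    b = dys * (1.0 - dys)
    out = np.zeros_like(values)
    if np.any(a > 1e-15):
        out += a[None, None, :] * _axis_second(values, grid, 0)
    if np.any(b > 1e-15):
        out += b[None, None, :] * _axis_second(values, grid, 1)
    return out


def upwind_gradient_norm(
    U: OrientationScore,
    dual_metric,
    mode: str,
) -> np.ndarray:
    """Rouy-Tourin upwind approximation of the metric gradient norm.

    ``dual_metric`` holds the dual coefficients (g^11, g^22, g^33) >= 0. For
    dilation the larger ascending neighbour difference is selected per axis,
    |A_i U| ~ max(D_i^+ U, -D_i^- U, 0); erosion mirrors the selection.
    """
    g = tuple(float(c) for c in dual_metric)
    if any(c < 0 for c in g):
        raise ValueError("dual metric coefficients must be non-negative")
    if all(c == 0 for c in g):
        raise ValueError("dual metric must have a positive coefficient")
    if mode not in ("dilation", "erosion"):
        raise ValueError(f"mode must be 'dilation' or 'erosion', got {mode!r}")
    acc = np.zeros_like(U.values)
    for i, gi in zip((1, 2, 3), g):
        if gi == 0.0:
            continue
        up, um, h = invariant_samples(U.values, U.grid, i)
        dplus = (up - U.values) / h
        dminus = (U.values - um) / h
        if mode == "dilation":
            d = np.maximum(np.maximum(dplus, -dminus), 0.0)
        else:
            d = np.maximum(np.maximum(-dplus, dminus), 0.0)
        acc += gi * d * d
    return np.sqrt(acc)


def se2_gaussian_smooth(
    U: OrientationScore, spatial_scale: float, orientation_scale: float = 0.0
) -> OrientationScore:
    """Spatially isotropic Gaussian smoothing per orientation slice, optionally
    composed with a periodic Gaussian along theta.

    Scale 0 on an axis is the identity on that axis.  The kernel is separable
    and isotropic in the plane, so the operation commutes with grid
    roto-translations.
    """
    if spatial_scale < 0 or orientation_scale < 0:
        raise ValueError("smoothing scales must be non-negative")
    v = U.values
    if spatial_scale > 0:
        v = ndimage.gaussian_filter(
            v,
            sigma=(spatial_scale / U.grid.dxy, spatial_scale / U.grid.dxy, 0),
            mode="reflect",
            truncate=GAUSS_TRUNCATE,
        )
    if orientation_scale > 0:
        v = ndimage.gaussian_filter1d(
            v,
            sigma=orientation_scale / U.grid.dtheta,
            axis=2,
            mode="wrap",
            truncate=GAUSS_TRUNCATE,
        )
    return OrientationScore(v, U.grid)


def _trig_test_fields(grid: M2Grid, n_fields: int, seed: int, max_freq: int = 2):
    """Smooth pseudo-random trigonometric polynomials on the grid, with their
    analytic coordinate derivatives (for internal validation)."""
    rng = np.random.default_rng(seed)
    x = np.arange(grid.H)[:, None, None] * grid.dxy
    y = np.arange(grid.W)[None, :, None] * grid.dxy
    th = grid.thetas[None, None, :]
    fields = []
    for _ in range(n_fields):
        kx = 2 * np.pi * rng.integers(1, max_freq + 1) / (grid.H * grid.dxy)
        ky = 2 * np.pi * rng.integers(1, max_freq + 1) / (grid.W * grid.dxy)
        m = int(rng.integers(1, max_freq + 1))
        px, py, pt = rng.uniform(0, 2 * np.pi, 3)
        amp = rng.uniform(0.5, 2.0)
        fields.append(amp * np.cos(kx * x + px) * np.cos(ky * y + py) * np.cos(m * th + pt))
    return fields


def commutator_table(
    grid: M2Grid,
    n_fields: int = 8,
    seed: int = 17,
    residual_tol: float = 0.05,
    max_freq: int = 2,
) -> np.ndarray:
    """Numerically estimate the structure constants c^k_ij of the frame.

    Applies the discrete commutator [A_i, A_j] = A_i A_j - A_j A_i to smooth
    trigonometric test fields and regresses the result onto the first-order
    frame derivatives (A_1 f, A_2 f, A_3 f) over interior voxels.  For the
    invariant frame on M2 the exact table is [A3, A1] = A2, [A3, A2] = -A1,
    [A1, A2] = 0; its trace c^k_ki vanishes (the group is unimodular), which
    is what makes the second-order generator the Laplace-Beltrami operator.

    Raises ``RuntimeError`` if the relative regression residual exceeds
    ``residual_tol`` — a signal that the derivative implementation is broken.
    """
    fields = _trig_test_fields(grid, n_fields, seed, max_freq)
    m = 4  # interior margin, in voxels
    sl = (slice(m, grid.H - m), slice(m, grid.W - m), slice(None))

    design_cols = []
    targets = {pair: [] for pair in ((1, 2), (3, 1), (3, 2))}
    for f in fields:
        U = OrientationScore(f, grid)
        first = {i: directional_derivative(U, i, 1) for i in (1, 2, 3)}
        design_cols.append(np.stack([first[i][sl].ravel() for i in (1, 2, 3)], axis=1))
        for (i, j) in targets:
            AiAj = directional_derivative(OrientationScore(first[j], grid), i, 1)
            AjAi = directional_derivative(OrientationScore(first[i], grid), j, 1)
            targets[(i, j)].append((AiAj - AjAi)[sl].ravel())

    A = np.concatenate(design_cols, axis=0)
    table = np.zeros((3, 3, 3))
    for (i, j), rows in targets.items():
        b = np.concatenate(rows)
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = np.linalg.norm(A @ coef - b) / max(np.linalg.norm(b), np.linalg.norm(A) * 1e-12, 1e-30)
        if resid > residual_tol and np.linalg.norm(b) > 1e-8 * np.linalg.norm(A):
            raise RuntimeError(
                f"commutator regression residual {resid:.3g} exceeds {residual_tol} "
                f"for [A{i}, A{j}] — directional derivatives look inconsistent"
            )
        table[i - 1, j - 1, :] = coef
        table[j - 1, i - 1, :] = -coef
    return table
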