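"""Data-adapted (gauge) frames fitted from an orientation score.

The first gauge vector at a voxel is the unit-norm direction (w.r.t. the
weighted metric G_xi, with G_xi(A1,A1)=G_xi(A2,A2)=xi^2 and G_xi(A3,A3)=1)
along which the component-wise derivative of the score gradient is smallest:
it aligns with the lifted structure, correcting the deviation from
horizontality caused by orientation discretisation, and its angular component
encodes the curvature of the underlying planar curve.  The remaining two
vectors complete a right-handed G_xi-orthonormal frame with a purely spatial
second vector.

Minimising the objective reduces, per voxel, to a 3x3 generalized eigenvalue
problem S X = mu G_xi X, where S is the Gram matrix of the frame derivatives
of the gradient components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import M2Grid, OrientationScore, directional_derivative, se2_gaussian_smooth

__all__ = [
    "GaugeFrameField",
    "hessian_quadratic_form",
    "fit_first_gauge_vector",
    "complete_gauge_frame",
    "fit_gauge_frame",
    "gauge_derivative",
    "gauge_samples",
    "pde_frame_coefficients",
    "curvature_from_gauge",
]


@dataclass
class GaugeFrameField:
    """Per-voxel coefficients of the gauge frame w.r.t. the invariant frame.

    ``coeffs[..., i, j]`` holds c_i^j with A_i^U = sum_j c_i^j A_j; each row
    has unit G_xi-norm, row 2 is purely spatial, rows are mutually
    G_xi-orthogonal and right-handed.  ``degenerate`` flags voxels where the
    fit was ambiguous and the invariant frame was substituted.
    """

    coeffs: np.ndarray  # (H, W, N, 3, 3)
    xi: float
    grid: M2Grid = field(repr=False)
    degenerate: np.ndarray | None = None  # (H, W, N) bool

    def __post_init__(self) -> None:
        expected = self.grid.shape + (3, 3)
        if self.coeffs.shape != expected:
            raise ValueError(f"coefficient shape {self.coeffs.shape} != {expected}")


def _gxi_diag(xi: float) -> np.ndarray:
    return np.array([xi * xi, xi * xi, 1.0])


def hessian_quadratic_form(
    U: OrientationScore,
    xi: float = 0.1,
    spatial_smoothing: float = 1.0,
    orientation_smoothing: float | None = None,
) -> np.ndarray:
    """Per-voxel symmetric 3x3 matrix S of the gauge-fitting objective.

    Computes the G_xi-gradient components W^j = (1/g_jj) A_j U of the smoothed
    score and assembles S_im = sum_j g_jj (A_i W^j)(A_m W^j), so that the
    fitting objective for a candidate direction with frame coefficients X is
    exactly X^T S X (component-wise differentiation; no connection terms).

    The score is smoothed before differentiating (default: 1 px spatially and
    one angular step along theta) so the Gram matrix is not noise-dominated.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    if orientation_smoothing is None:
        orientation_smoothing = U.grid.dtheta
    Us = se2_gaussian_smooth(U, spatial_smoothing, orientation_smoothing)
    g = _gxi_diag(xi)
    W = [directional_derivative(Us, j, 1) / g[j - 1] for j in (1, 2, 3)]
    S = np.zeros(U.grid.shape + (3, 3))
    for j in range(3):
        Wj = OrientationScore(W[j], U.grid)
        dWj = [directional_derivative(Wj, i, 1) for i in (1, 2, 3)]
        for i in range(3):
            for m in range(i, 3):
                S[..., i, m] += g[j] * dWj[i] * dWj[m]
    for i in range(3):
        for m in range(i + 1, 3):
            S[..., m, i] = S[..., i, m]
    return S


def fit_first_gauge_vector(S: np.ndarray, xi: float = 0.1, tie_tol: float = 1e-12):
    """Smallest-eigenvalue direction of S X = mu G_xi X, per voxel.

    Returns ``(coeffs, degenerate)`` where ``coeffs[..., :]`` is the
    G_xi-normalised eigenvector with non-negative A1-component (ties broken
    towards non-negative A3), and ``degenerate`` flags voxels whose two
    smallest eigenvalues are indistinguishable (flat regions); there the
    invariant A1 is returned.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    g = _gxi_diag(xi)
    sq = np.sqrt(g)
    # symmetrise the generalized problem: B = G^-1/2 S G^-1/2
    B = S / sq[None, :] / sq[:, None]
    w, V = np.linalg.eigh(B)
    y = V[..., :, 0]  # eigenvector of the smallest eigenvalue, |y| = 1
    x = y / sq
    # scale spread between the two smallest eigenvalues relative to the matrix
    scale = np.maximum(np.abs(w).max(axis=-1), tie_tol)
    degenerate = (w[..., 1] - w[..., 0]) <= tie_tol * scale

    # sign convention: A1-component >= 0; ties towards A3-component >= 0
    s = np.sign(x[..., 0])
    tie = s == 0
    s = np.where(tie, np.sign(x[..., 2]), s)
    s = np.where(s == 0, 1.0, s)
    x = x * s[..., None]

    x = np.where(degenerate[..., None], np.array([1.0 / np.sqrt(g[0]), 0.0, 0.0]), x)
    # exact G_xi-normalisation (guard against accumulated rounding)
    norm = np.sqrt(np.einsum("...i,i,...i->...", x, g, x))
    return x / norm[..., None], degenerate


def complete_gauge_frame(a1: np.ndarray, xi: float, grid: M2Grid) -> GaugeFrameField:
    """Complete a unit first gauge vector field to a G_xi-orthonormal frame.

    The second vector is the purely spatial 90-degree rotation of the spatial
    part of the first; the third is the unique unit vector G_xi-orthogonal to
    both with right-handed orientation.  Voxels whose first vector has no
    spatial part fall back to the invariant frame and are flagged.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    g = _gxi_diag(xi)
    sq = np.sqrt(g)
    spatial_norm = np.hypot(a1[..., 0], a1[..., 1])
    bad = spatial_norm < 1e-12

    a2 = np.zeros_like(a1)
    safe = np.where(bad, 1.0, spatial_norm)
    a2[..., 0] = -a1[..., 1] / (xi * safe)
    a2[..., 1] = a1[..., 0] / (xi * safe)

    # right-handed completion via the cross product in G_xi-orthonormal coords
    y1 = a1 * sq
    y2 = a2 * sq
    y3 = np.cross(y1, y2)
    a3 = y3 / sq

    coeffs = np.stack([a1, a2, a3], axis=-2)
    ident = np.diag(1.0 / sq)  # invariant frame directions, G_xi-normalised
    coeffs = np.where(bad[..., None, None], ident, coeffs)
    return GaugeFrameField(coeffs=coeffs, xi=xi, grid=grid, degenerate=bad)


def fit_gauge_frame(
    U: OrientationScore,
    xi: float = 0.1,
    spatial_smoothing: float = 1.0,
    orientation_smoothing: float | None = None,
) -> GaugeFrameField:
    """Fit the full gauge frame on an orientation score (held fixed during
    any subsequent PDE evolution)."""
    S = hessian_quadratic_form(U, xi, spatial_smoothing, orientation_smoothing)
    a1, degen_fit = fit_first_gauge_vector(S, xi)
    frame = complete_gauge_frame(a1, xi, U.grid)
    frame.degenerate = frame.degenerate | degen_fit
    return frame


def pde_frame_coefficients(frame: GaugeFrameField) -> np.ndarray:
    """Gauge frame rescaled for use inside the PDE.

    The stored rows are G_xi-unit, so the spatial vectors have Euclidean
    length ~1/xi.  Rescaling rows 1 and 2 by xi (row 3 is already unit in the
    flat limit) makes the frame reduce exactly to {A1, A2, A3} on flat data,
    so the invariant-frame metric weights and the timestep bound carry over.
    """
    scale = np.array([frame.xi, frame.xi, 1.0])
    return frame.coeffs * scale[:, None]


def gauge_samples(values: np.ndarray, grid: M2Grid, directions: np.ndarray, pad_theta: int = 2):
    """Neighbour samples along per-voxel frame directions.

    ``directions[..., :]`` holds coefficients (c1, c2, c3) w.r.t. the
    invariant frame.  The parameter step is h = min(dxy/|c_sp|, dtheta/|c3|),
    which keeps the trilinear stencil within one grid cell and reduces to the
    invariant-frame convention for the unit coordinate directions.  Returns
    (U_plus, U_minus, h) with h a per-voxel array.
    """
    H, W, N = grid.shape
    th = grid.thetas[None, None, :]
    c1, c2, c3 = directions[..., 0], directions[..., 1], directions[..., 2]
    vx = c1 * np.cos(th) - c2 * np.sin(th)
    vy = c1 * np.sin(th) + c2 * np.cos(th)
    csp = np.hypot(vx, vy)

    with np.errstate(divide="ignore"):
        h_sp = np.where(csp > 0, grid.dxy / np.where(csp > 0, csp, 1.0), np.inf)
        h_th = np.where(np.abs(c3) > 0, grid.dtheta / np.where(np.abs(c3) > 0, np.abs(c3), 1.0), np.inf)
    h = np.minimum(h_sp, h_th)
    h = np.where(np.isinf(h), 1.0, h)  # zero direction: samples collapse onto p

    vol = np.concatenate(
        [values[:, :, -pad_theta:], values, values[:, :, :pad_theta]], axis=2
    )
    ii, jj, kk = np.meshgrid(
        np.arange(H, dtype=float), np.arange(W, dtype=float), np.arange(N, dtype=float),
        indexing="ij",
    )
    kk = kk + pad_theta
    out = []
    for sign in (1.0, -1.0):
        ci = ii + sign * h * vx / grid.dxy
        cj = jj + sign * h * vy / grid.dxy
        ck = kk + sign * h * c3 / grid.dtheta
        out.append(
            ndimage.map_coordinates(
                vol, [ci, cj, ck], order=1, mode="reflect", prefilter=False
            )
        )
    return out[0], out[1], h


def gauge_derivative(
    U: OrientationScore, frame: GaugeFrameField, i: int, order: int
) -> np.ndarray:
    """First/second central difference along gauge direction i (1..3)."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if i not in (1, 2, 3):
        raise ValueError("frame index must be 1, 2 or 3")
    if frame.grid.shape != U.grid.shape:
        raise ValueError("frame and score grids do not match")
    up, um, h = gauge_samples(U.values, U.grid, frame.coeffs[..., i - 1, :])
    if order == 1:
        return (up - um) / (2.0 * h)
    return (up - 2.0 * U.values + um) / (h * h)


def curvature_from_gauge(frame: GaugeFrameField) -> np.ndarray:
    """Signed curvature estimate kappa = c3 / |c_spatial| of the first gauge
    vector: its tangent direction advances theta at rate kappa per unit
    spatial arclength, exactly matching a lifted circle of radius 1/|kappa|."""
    a1 = frame.coeffs[..., 0, :]
    sp = np.hypot(a1[..., 0], a1[..., 1])
    return a1[..., 2] / np.maximum(sp, 1e-12)
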