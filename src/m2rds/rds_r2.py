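"""Planar regularised diffusion-shock filtering (the R2 baseline).

Combines homogeneous diffusion with a coherence-enhancing shock filter
driven by the dominant eigenvector of a structure tensor:

    du/dt = g(|grad u_nu|^2) Lap u - (1 - g(|grad u_nu|^2)) S(d_ww u_sigma) |grad u|

with w the dominant structure-tensor eigenvector, the same Charbonnier
switch g and soft sign S as on M2, central differences for the diffusion,
Rouy-Tourin upwind differences for the morphological term, and reflective
boundaries.  Because the filter lives on the image plane it cannot
disentangle crossings: completing two crossing lines through a hole, it
connects them without a crossing, which is exactly the failure mode the M2
lift removes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .grid import GAUSS_TRUNCATE
from .rds_m2 import charbonnier_switch, shock_sign

__all__ = [
    "structure_tensor",
    "dominant_eigenvector",
    "r2_stable_timestep",
    "r2_rds_evolve",
]


def _gauss(a: np.ndarray, sigma: float, order=0) -> np.ndarray:
    if sigma == 0 and order == 0:
        return a
    # derivatives at scale zero fall back to a minimal regularisation scale
    s = max(sigma, 0.5) if order != 0 else sigma
    return ndimage.gaussian_filter(a, s, order=order, mode="reflect", truncate=GAUSS_TRUNCATE)


def structure_tensor(f: np.ndarray, sigma: float, rho: float) -> np.ndarray:
    """J_rho(grad u_sigma) = K_rho * (grad u_sigma grad u_sigma^T).

    Returns an (H, W, 2, 2) array of symmetric PSD matrices; sigma is the
    inner (derivative) scale, rho the outer (integration) scale, in pixels.
    """
    if sigma < 0 or rho < 0:
        raise ValueError("scales must be non-negative")
    f = np.asarray(f, dtype=float)
    gx = _gauss(f, sigma, order=(1, 0))
    gy = _gauss(f, sigma, order=(0, 1))
    J = np.empty(f.shape + (2, 2))
    J[..., 0, 0] = _gauss(gx * gx, rho)
    J[..., 0, 1] = J[..., 1, 0] = _gauss(gx * gy, rho)
    J[..., 1, 1] = _gauss(gy * gy, rho)
    return J


def dominant_eigenvector(J: np.ndarray, iso_tol: float = 1e-12):
    """Unit eigenvector of the largest eigenvalue, per pixel (closed form).

    The sign is fixed to the upper half-plane (w_y >= 0, ties towards
    w_x >= 0).  Pixels whose eigenvalue gap is below ``iso_tol`` are
    isotropic: they default to (1, 0) and are flagged in the returned mask.
    """
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 1, 1]
    half_gap = np.sqrt(((a - c) * 0.5) ** 2 + b * b)
    isotropic = 2.0 * half_gap < iso_tol
    lmax = (a + c) * 0.5 + half_gap
    # two candidate eigenvector expressions; pick the better-conditioned one
    v1 = np.stack([b, lmax - a], axis=-1)
    v2 = np.stack([lmax - c, b], axis=-1)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    w = np.where((n1 >= n2)[..., None], v1, v2)
    n = np.maximum(np.linalg.norm(w, axis=-1), 1e-300)
    w = w / n[..., None]
    s = np.sign(w[..., 1])
    s = np.where(s == 0, np.sign(w[..., 0]), s)
    s = np.where(s == 0, 1.0, s)
    w = w * s[..., None]
    w = np.where(isotropic[..., None], np.array([1.0, 0.0]), w)
    return w, isotropic


def r2_stable_timestep(dxy: float = 1.0) -> float:
    """min(dxy^2/4, dxy/sqrt(2)): the planar specialisation of the M2 bound
    (two spatial axes, unit diffusivity, unit morphological speed)."""
    return min(dxy * dxy / 4.0, dxy / math.sqrt(2.0))


def _shift(a: np.ndarray, axis: int, d: int) -> np.ndarray:
    pad = [(1, 1), (1, 1)]
    ap = np.pad(a, pad, mode="symmetric")
    sl = [slice(1, 1 + a.shape[0]), slice(1, 1 + a.shape[1])]
    sl[axis] = slice(1 + d, 1 + d + a.shape[axis])
    return ap[tuple(sl)]


def r2_rds_evolve(
    f: np.ndarray,
    lam: float = 10.0,
    nu: float = 2.0,
    sigma: float = 2.0,
    rho: float = 4.0,
    epsilon: float | None = None,
    tau: float | None = None,
    T: float = 10.0,
    dxy: float = 1.0,
    mask: np.ndarray | None = None,
    change_tol: float = 1e-5,
):
    """Forward-Euler planar diffusion-shock evolution.

    With ``mask`` given (boolean, True = known) the known pixels are reset to
    their initial values after every step (Dirichlet inpainting) and the
    evolution may stop early once the relative per-step change in the unknown
    region drops below ``change_tol``.  Returns (image, log dict).  Aborts
    with a diagnostic if the extrema ever leave the initial range.
    """
    u = np.asarray(f, dtype=float).copy()
    if u.ndim != 2:
        raise ValueError("expected a 2D image")
    bound = r2_stable_timestep(dxy)
    if tau is None:
        tau = 0.9 * bound
    elif tau > bound * (1 + 1e-9):
        raise ValueError(f"timestep {tau} exceeds the planar stability bound {bound}")
    if epsilon is None:
        epsilon = max(1e-12, 0.01 * float(np.ptp(u)))
    lo, hi = float(u.min()), float(u.max())
    scale = max(hi - lo, 1e-12)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != u.shape:
            raise ValueError("mask and image shapes differ")
        known_vals = u[mask].copy()

    n_steps = math.ceil(T / tau - 1e-12)
    log = {"tau": tau, "n_steps": n_steps, "min": [], "max": []}
    converged = False
    for _ in range(n_steps):
        u_nu = _gauss(u, nu)
        gx = (_shift(u_nu, 0, 1) - _shift(u_nu, 0, -1)) / (2 * dxy)
        gy = (_shift(u_nu, 1, 1) - _shift(u_nu, 1, -1)) / (2 * dxy)
        g_w = charbonnier_switch(gx * gx + gy * gy, lam)

        J = structure_tensor(u, sigma, rho)
        w, _ = dominant_eigenvector(J)
        # Gaussian-derivative Hessian of u at the inner scale
        hxx = _gauss(u, sigma, order=(2, 0)) / dxy**2
        hyy = _gauss(u, sigma, order=(0, 2)) / dxy**2
        hxy = _gauss(u, sigma, order=(1, 1)) / dxy**2
        d_ww = w[..., 0] ** 2 * hxx + 2 * w[..., 0] * w[..., 1] * hxy + w[..., 1] ** 2 * hyy
        S = shock_sign(d_ww, epsilon)

        lap = (
            _shift(u, 0, 1) + _shift(u, 0, -1) + _shift(u, 1, 1) + _shift(u, 1, -1) - 4 * u
        ) / dxy**2

        norms = []
        for mode in ("dilation", "erosion"):
            acc = np.zeros_like(u)
            for ax in (0, 1):
                dp = (_shift(u, ax, 1) - u) / dxy
                dm = (u - _shift(u, ax, -1)) / dxy
                if mode == "dilation":
                    d = np.maximum(np.maximum(dp, -dm), 0.0)
                else:
                    d = np.maximum(np.maximum(-dp, dm), 0.0)
                acc += d * d
            norms.append(np.sqrt(acc))
        morph = np.where(S < 0, norms[0], norms[1])

        new = u + tau * (g_w * lap - (1.0 - g_w) * S * morph)
        if mask is not None:
            prev = u
            new[mask] = known_vals
            residual = float(np.max(np.abs((new - prev)[~mask]))) / scale
        u = new
        log["min"].append(float(u.min()))
        log["max"].append(float(u.max()))
        if u.max() > hi + 1e-9 * scale or u.min() < lo - 1e-9 * scale:
            raise FloatingPointError(
                f"extrema left the initial range [{lo}, {hi}]: "
                f"[{u.min()}, {u.max()}] — instability detected"
            )
        if mask is not None and residual < change_tol:
            converged = True
            break
    log["converged"] = converged
    return u, log
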