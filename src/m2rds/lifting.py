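"""Cake wavelets, orientation-score lifting and projection.

An image f is lifted to M2 by cross-correlating it with N rotated copies of a
cake wavelet: filters whose Fourier supports tile the frequency plane like
slices of a cake.  Because the angular windows form a partition of unity over
the pass band, summing the score over the orientation axis approximately
reconstructs the image, which is the projection used throughout.

The construction is carried out in the Fourier domain: angular B-spline wedges
of width 2*pi/N, a smooth radial low-pass taper so that frequencies near the
Nyquist ring carry (essentially) no energy, and a DC bump that is split evenly
over the orientations so constants reconstruct exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import BSpline

from .grid import M2Grid, OrientationScore

__all__ = ["CakeWaveletStack", "build_cake_wavelets", "lift", "project"]


def _bspline(order: int):
    """Centred cardinal B-spline of the given order (unit knot spacing).

    Integer translates of this function sum to one, which gives the angular
    partition of unity of the wavelet stack.
    """
    knots = np.arange(order + 2, dtype=float) - (order + 1) / 2.0
    return BSpline.basis_element(knots, extrapolate=False)


@dataclass
class CakeWaveletStack:
    """N complex spatial kernels of odd size K x K plus their design parameters."""

    kernels: np.ndarray  # (N, K, K) complex
    N: int
    size: int
    spline_order: int
    radial_pass: float    # flat pass band edge, cycles/pixel
    radial_stop: float    # taper reaches zero here, cycles/pixel
    dc_sigma: float       # width of the low-frequency bump split over orientations

    def fourier_stack(self, shape: tuple[int, int]) -> np.ndarray:
        """The stack's transfer functions on an arbitrary (H, W) DFT grid."""
        return _fourier_wedges(
            self.N, shape, self.spline_order, self.radial_pass, self.radial_stop, self.dc_sigma
        )


def _fourier_wedges(N, shape, spline_order, radial_pass, radial_stop, dc_sigma):
    H, W = shape
    fx = np.fft.fftfreq(H)[:, None]
    fy = np.fft.fftfreq(W)[None, :]
    rho = np.hypot(fx, fy)
    phi = np.arctan2(fy, fx)

    # smooth radial low-pass: flat to radial_pass, cos^2 rolloff to radial_stop
    radial = np.ones_like(rho)
    ramp = (rho - radial_pass) / (radial_stop - radial_pass)
    t = np.clip(ramp, 0.0, 1.0)
    radial = np.where(rho <= radial_pass, 1.0, np.cos(0.5 * np.pi * t) ** 2)

    # low-frequency bump where the angular coordinate degenerates; its share
    # of the spectrum is distributed evenly so the wedges still sum to one
    dc = np.exp(-0.5 * (rho / dc_sigma) ** 2)

    spline = _bspline(spline_order)
    dtheta = 2.0 * np.pi / N
    out = np.empty((N, H, W), dtype=np.complex128)
    for k in range(N):
        # a line with spatial direction theta has its spectrum perpendicular
        # to theta, so the wedge for orientation theta_k is centred at
        # theta_k + pi/2; slice k then responds to structures *along* theta_k,
        # making A1 point along the lifted data
        d = (phi - k * dtheta - 0.5 * np.pi + np.pi) % (2.0 * np.pi) - np.pi
        wedge = spline(d / dtheta)
        wedge = np.nan_to_num(wedge, nan=0.0)
        out[k] = radial * ((1.0 - dc) * wedge + dc / N)
    return out


def build_cake_wavelets(
    N: int,
    size: int = 33,
    spline_order: int = 3,
    radial_pass: float = 0.30,
    radial_stop: float = 0.45,
    dc_sigma: float = 0.03,
) -> CakeWaveletStack:
    """Construct the stack of N rotated cake wavelets.

    Parameters
    ----------
    N : int
        Orientation count (>= 4).  The wedges cover the full circle, so a line
        structure responds in the two slices theta and theta + pi.
    size : int
        Odd spatial support of the returned kernels (>= 9).
    spline_order : int
        Order of the angular B-spline window.
    radial_pass, radial_stop : float
        Pass-band edge and stop frequency of the radial taper, in cycles per
        pixel (Nyquist = 0.5).  Defaults keep the Nyquist ring below 1% energy.
    dc_sigma : float
        Standard deviation (cycles/pixel) of the DC bump shared uniformly over
        orientations, so constant images reconstruct exactly.
    """
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    if size < 9:
        raise ValueError("kernel size must be at least 9")
    if N < 4:
        raise ValueError("need at least 4 orientations")
    if N < spline_order + 1:
        raise ValueError("orientation count too small for the spline order")
    # Build on a finely sampled frequency grid and crop the centred K x K
    # window: constructing directly on a K x K DFT grid would periodise the
    # slowly decaying tails back into the support (aliasing).
    big = max(257, 4 * size + 1)
    hat = _fourier_wedges(N, (big, big), spline_order, radial_pass, radial_stop, dc_sigma)
    full = np.fft.fftshift(np.fft.ifft2(hat, axes=(1, 2)), axes=(1, 2))
    c, r = big // 2, size // 2
    kernels = np.ascontiguousarray(full[:, c - r : c + r + 1, c - r : c + r + 1])
    return CakeWaveletStack(
        kernels=kernels,
        N=N,
        size=size,
        spline_order=spline_order,
        radial_pass=radial_pass,
        radial_stop=radial_stop,
        dc_sigma=dc_sigma,
    )


def lift(f: np.ndarray, wavelets: CakeWaveletStack, dxy: float = 1.0) -> OrientationScore:
    """Orientation score of an image: per-slice cross-correlation with the
    conjugate wavelets, reflective boundaries, real part retained.

    The transform is linear in ``f``; slice k responds maximally to structures
    at angle theta_k = 2*pi*k/N.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.all(np.isfinite(f)):
        raise ValueError("image contains non-finite values")
    K = wavelets.size
    if K > min(f.shape):
        raise ValueError(f"kernel size {K} exceeds image extent {f.shape}")
    r = K // 2
    fp = np.pad(f, r, mode="symmetric")
    grid = M2Grid(f.shape[0], f.shape[1], wavelets.N, dxy=dxy)
    out = np.empty(grid.shape)
    for k in range(wavelets.N):
        # cross-correlation with conj(psi) == convolution with conj(psi(-x))
        h = np.conj(wavelets.kernels[k][::-1, ::-1])
        resp = signal.fftconvolve(fp, h, mode="same")
        out[:, :, k] = resp.real[r : r + f.shape[0], r : r + f.shape[1]]
    return OrientationScore(out, grid)


def project(U: OrientationScore) -> np.ndarray:
    """Approximate reconstruction: pixelwise sum over the orientation axis."""
    if not np.all(np.isfinite(U.values)):
        raise ValueError("orientation score contains non-finite values")
    return U.values.sum(axis=2)
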