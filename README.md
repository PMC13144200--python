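# m2rds — crossing-preserving diffusion–shock filtering via orientation scores

`m2rds` denoises and inpaints 2D grayscale images of line-like structures —
retinal vessels, fibres, contours — by processing them in *position–orientation
space* M₂ ≅ ℝ² × S¹ instead of the image plane. Overlapping structures that
are indistinguishable in the plane separate cleanly once each orientation gets
its own layer, so the filter can smooth along lines, sharpen across them, and
restore *crossings* that planar filters inevitably merge.

## The method

1. **Lift.** The image f is correlated with N rotated *cake wavelets* ψ
   (filters whose Fourier supports tile the frequency plane like cake slices),
   giving a real orientation score
   U(x, θₖ) = (f ⋆ ψ̄ₖ)(x), θₖ = 2πk/N.
   Because the angular windows form a partition of unity, summing U over θ
   approximately reconstructs f (≤1% error on band-limited images).

2. **Evolve.** U obeys a regularised diffusion–shock PDE built from the
   roto-translation invariant frame A₁ = cos θ ∂x + sin θ ∂y (along the local
   orientation), A₂ = −sin θ ∂x + cos θ ∂y (lateral), A₃ = ∂θ:

       ∂ₜU =  g(‖∇_{G_g} U_ν‖²) · Δ_{G_D} U
            − (1 − g(‖∇_{G_g} U_ν‖²)) · S_ρ(Δ⊥_{G_S} U_σ) · ‖∇_{G_M} U‖

   with the Charbonnier weight g(s²) = (1 + s²/λ²)^{−1/2} switching between
   diffusion (flat regions) and shock (edges), the soft sign S of the
   Laplacian perpendicular to the orientation deciding dilation vs erosion,
   and Gaussian-regularised guidance terms U_ν, U_σ, S_ρ. All metrics are
   diagonal, parameterised as g₁₁ = ξ², g₂₂ = (ξ/ζ)², g₃₃ = 1 (ξ = 0.1; ζ is
   the spatial anisotropy). The explicit scheme uses central differences for
   the diffusion and Rouy–Tourin upwind stencils for the morphology, and
   satisfies a maximum–minimum principle for timesteps below

       τ ≤ min{ τ_D, τ_S },   τ_D⁻¹ = 2((g_D¹¹+g_D²²)/Δxy² + g_D³³/Δθ²),
                              τ_S⁻¹ = √((g_M¹¹+g_M²²)/Δxy² + g_S³³/Δθ²).

   Optionally the invariant frame is replaced by a data-adapted *gauge frame*
   fitted per voxel from the score's Hessian energy, which corrects the
   deviation from horizontality and encodes local curvature.

3. **Project.** The filtered score is summed over orientations and clipped to
   the display range.

A planar baseline (`m2rds.rds_r2`) implements the same diffusion–shock idea
on ℝ² with a structure-tensor shock direction, for head-to-head comparisons.

## Worked example

```python
import numpy as np
from m2rds import (DiagMetricParams, RDSParams, build_cake_wavelets,
                   denoise_sweep, make_spirals, add_correlated_noise,
                   NoiseSpec, psnr)

clean = make_spirals(128, 128)                       # crossing spiral arms
noisy = add_correlated_noise(clean, NoiseSpec(sigma=255.0, rho=2.0, seed=1))
print(f"noisy input: {psnr(noisy, clean):.2f} dB")

params = RDSParams(metric_D=DiagMetricParams(0.1, 0.5),
                   metric_M=DiagMetricParams(0.1, 0.5),
                   lam=2.0, sigma_reg=2.0, nu_reg=2.0)
wavelets = build_cake_wavelets(32, 33)
for T, out in denoise_sweep(noisy, params, [0.15, 0.25, 0.35], wavelets=wavelets):
    print(f"T = {T}: {psnr(out, clean):.2f} dB")
```

prints (seed 1):

```
noisy input: 17.26 dB
T = 0.15: 20.60 dB
T = 0.25: 20.18 dB
T = 0.35: 19.52 dB
```

— a gain of 3.3 dB at the best stopping time (the planar diffusion–shock
baseline tops out at 19.0 dB on the same input), with the crossings of the
two spiral arms intact. A command-line interface wraps the same
pipeline:

```sh
m2rds fixtures --name crossing --seed 1 --out fixtures/
m2rds denoise fixtures/crossing.png --out out.png --n-orientations 16 --end-time 0.1
m2rds inpaint image.png mask.png --out filled.png --frame gauge
```

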