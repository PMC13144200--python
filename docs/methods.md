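# Methods

## Model

Images f: ℝ² → ℝ on the 0–255 display scale are lifted to position–orientation
space M₂ ≅ ℝ² × S¹ by cross-correlation with N rotated cake wavelets
(Fourier-domain construction: angular B-spline wedges of width 2π/N that form
an exact partition of unity over the full circle, a radial cos² taper from
0.30 to 0.45 cycles/px so the Nyquist ring carries essentially no energy, and
a DC bump of width 0.03 cycles/px split evenly over orientations so constants
reconstruct exactly). The evolved state is the real part of the complex
score, following the convention of the orientation-score literature; a real
score is π-periodic in θ, so slices k and k + N/2 coincide and a line appears
in the two slices matching its (unsigned) orientation. Projection is the sum
over the orientation axis; on images whose spectrum lies in the wavelet pass
band the lift–project round trip is accurate to ≤1% relative L₂ in the
interior.

The filter evolves U by a diffusion–shock PDE written in the invariant frame
A₁ = cos θ ∂x + sin θ ∂y, A₂ = −sin θ ∂x + cos θ ∂y, A₃ = ∂θ (or in a
data-adapted gauge frame, below). Diffusion is generated by the second-order
operator Σᵢ gᴰⁱⁱ Aᵢ² U; on a unimodular group this coincides with the
Laplace–Beltrami operator of the invariant metric — the package verifies the
underlying facts numerically (structure constants [A₃,A₁] = A₂,
[A₃,A₂] = −A₁, [A₁,A₂] = 0 with vanishing trace). The shock term moves mass
along the steepest ascent/descent of the metric gradient at unit metric
speed; which of dilation or erosion applies is decided by a smoothed soft
sign of the Laplacian perpendicular to the local orientation
(gₛ²² A₂² + gₛ³³ A₃²) U_σ: negative (concave, a bright ridge) ⇒ dilation,
positive ⇒ erosion. A Charbonnier weight g(s²) = (1+s²/λ²)^{−1/2} of the
regularised gradient gates diffusion against shock.

All four metrics are diagonal with g₁₁ = ξ², g₂₂ = (ξ/ζ)², g₃₃ = 1. ξ = 0.1
(appropriate for 32 orientations) converts between spatial and angular units;
ζ = 1 is fixed for the two switch metrics, while the diffusion and
morphological anisotropies ζ_D, ζ_M are the tunables (ζ < 1 favours motion
along the local orientation — the "car that cannot move sideways").

## Discretisation

Spatial steps are Δxy = 1 px with reflective (symmetric) extension; the
orientation axis is periodic with Δθ = 2π/N. Frame derivatives sample
U(p ± e) along the frame direction: one step along A₁/A₂ moves Δxy spatially
and never in θ, one step along A₃ moves Δθ and never spatially, so stencils
decouple per axis. Off-grid samples are bilinear, which keeps every stencil a
convex combination of neighbours.

Two facts about the bilinear directional second difference shaped the scheme:

* It is **monotone** (non-negative weights), which is what the
  maximum–minimum proof of the explicit scheme needs.
* It is **biased**: interpolation contributes an O(1) excess of axis-aligned
  diffusion, |cθ|(1−|cθ|) ∂xx + |sθ|(1−|sθ|) ∂yy, at orientations not aligned
  with the grid (up to 41% extra at 45°). One stencil cannot be both
  monotone and consistent here — a rank-one anisotropic operator has no
  monotone consistent 3×3 discretisation.

The package therefore uses the corrected (bias-subtracted, O(h²)-consistent)
stencil wherever only accuracy matters — `directional_derivative(order=2)`
and the perpendicular Laplacian feeding the shock sign — and a monotone
splitting inside the diffusion term: the spatially isotropic part
min(g¹¹, g²²)(A₁² + A₂²) is discretised with the exact 5-point Laplacian and
only the anisotropic remainder uses the uncorrected directional stencil.
Both pieces have non-negative neighbour weights bounded by the same per-axis
constants, so the timestep bound

    τ ≤ min{τ_D, τ_S},  τ_D⁻¹ = 2((g_D¹¹+g_D²²)/Δxy² + g_D³³/Δθ²),
                        τ_S⁻¹ = √((g_M¹¹+g_M²²)/Δxy² + g_S³³/Δθ²)

and the max–min principle carry over unchanged, while the isotropic case is
exactly the unbiased heat stencil (the pure-diffusion evolution matches the
heat kernel to 0.3% at t = 2). The bound is sharp in practice: at twice the
bound, random initial scores exhibit extrema growth within a few steps.

The morphological term uses Rouy–Tourin upwind selection per axis —
dilation |AᵢU| ≈ max(Dᵢ⁺U, −Dᵢ⁻U, 0), erosion with the roles of the one-sided
differences swapped — and the dilation/erosion stencil is chosen voxelwise by
the sign of the *smoothed* shock switch, so the sampled neighbours are the
ones the stability argument requires. Regularisations (U_ν, U_σ, S_ρ) are
spatially isotropic Gaussians per orientation slice (truncation radius 6σ;
θ-smoothing exposed via `theta_reg` but 0 by default). Time stepping is
forward Euler with τ = 0.9 × the bound unless set explicitly; the soft-sign
steepness ε defaults to 1% of the score's dynamic range at evolution start
(a *data-dependent* convenience — fix `epsilon_S` explicitly when exact
equivariance under input transformations matters).

For the closed-form diffusion checks a smaller τ (0.2 × the bound) is used:
at 0.9 × the bound the forward-Euler amplification error on the slowest θ
mode is ~1.7% at t = 2, larger than the 1% comparison band; this is a solver
accuracy choice, not a property of the scheme.

## Gauge frames

The first gauge vector at a voxel minimises ‖∇⁰_X ∇U‖² over unit-G_ξ
directions X, where ∇⁰ differentiates gradient components in the invariant
frame; writing the objective as XᵀSX with S the Gram matrix of the frame
derivatives of the gradient components reduces the fit to the 3×3
generalized eigenproblem S X = μ G_ξ X per voxel (smallest eigenvalue,
G_ξ-normalised, sign fixed so the A₁ component is ≥ 0, ties towards A₃ ≥ 0;
degenerate voxels — flat regions — fall back to the invariant frame and are
flagged). Derivatives are taken on a slightly smoothed score (1 px
spatially, one step in θ) so the fit is not noise-dominated. The second
gauge vector is the purely spatial 90° rotation of the first's spatial part;
the third completes a right-handed G_ξ-orthonormal frame.

Stored rows are G_ξ-unit (so a nearly spatial row has Euclidean length
~1/ξ). Inside the PDE the rows are rescaled by (ξ, ξ, 1), which makes the
frame reduce *exactly* to {A₁, A₂, A₃} on flat data; without this the dual
metric weights would double-count the 1/ξ row length and the scheme would
not contain the invariant scheme as a special case. Gauge directional
derivatives use a per-voxel parameter step h = min(Δxy/|c_sp|, Δθ/|c³|),
capping the trilinear stencil at one grid cell and reducing to the
invariant-frame convention for coordinate directions. The frame is fitted
once on the initial condition and held fixed during the evolution.

The angular component of the first gauge vector encodes curvature:
κ = c³/|c_spatial|, exact for the tangent of a lifted circle
(tangent ∝ A₁ + κA₃). On rendered circles of radius 8–32 px (N = 32,
ξ = 0.1) the median recovery error is 10–19%; on straight lines at grid
orientations the fitted frame is within numerical zero of the invariant
frame. On straight-line images the gauge and invariant filter *outputs*
agree to ~5–6% rather than exactly: the cake-wavelet side slices hold
responses at neighbouring orientations, where the gauge frame legitimately
rotates to cancel the deviation from horizontality.

## Planar baseline

The ℝ² filter uses the same Charbonnier switch and soft sign, homogeneous
diffusion (5-point), Rouy–Tourin morphology, and the dominant eigenvector w
of the structure tensor J_ρ(∇u_σ) for the shock direction, with
∂ww u = wᵀ(Hess_σ u)w from Gaussian derivatives. Its stability bound is the
planar specialisation min(Δxy²/4, Δxy/√2). It exists for one purpose: the
side-by-side crossing experiments.

## Synthetic study conditions

All fixtures are pure functions of their parameters and seed, on the 0–255
scale:

* **Crossing lines** — anti-aliased 3 px lines through the centre; the
  rendered centrelines are returned as ground truth. The inpainting
  experiment hides a 20×20 square, runs the M₂ filter (N = 8, λ = 2,
  ζ_D = ζ_M = 0.1, T = 20, Dirichlet clamp of known pixels after every step)
  and the planar baseline (λ = 20, to convergence), and scores each line by
  the ratio of mean centreline intensity inside vs outside the hole. The M₂
  filter restores both lines (ratios ≈ 0.54); the planar filter converges to
  a structureless fill that fails both (≈ 0.37). These runs are
  deterministic.
* **Spirals** — two Archimedean arms (pitch 9 px, width 5 px, 3.5 turns) of
  *opposite chirality*, so the curves cross repeatedly: the structure whose
  preservation distinguishes orientation-aware from planar filtering.
  Degraded with additive correlated noise K_ρ ∗ n_σ, (σ, ρ) = (255, 2),
  unclipped so the degraded input's PSNR is well defined. Denoising uses
  N = 32, λ = 2, ζ_D = ζ_M = 0.5, σ_reg = ν_reg = 2 px, with PSNR read at the
  best of the stopping times {0.15, 0.25, 0.35, 0.5, 0.7}; the planar
  baseline gets its own best (λ = 8, T ∈ {4…16}). Across seeds the M₂
  filter gains 2.5–3.3 dB over the noisy input and 1.0–1.6 dB over the
  planar best.
* **Circles** of radius r with curvature label 1/r, and **square masks**,
  for the gauge-frame and inpainting experiments.
* **PSNR** is 10·log₁₀(255²/MSE) dB with an infinity sentinel for identical
  images.

What these fixtures do *not* emulate: sensor noise models beyond additive
correlated Gaussian noise, intensity inhomogeneity, textured backgrounds, or
the scale diversity of real vasculature. Passing the suite shows the scheme
has the claimed mathematical properties (stability, equivariance,
consistency, crossing preservation) and beats its planar counterpart under
these controlled conditions — not that the default parameters are optimal
for any particular imaging modality.

## Parameter summary

| Parameter | Meaning | Default |
|---|---|---|
| N | orientations (θ-resolution; real score is π-periodic) | 32 (8 for inpainting) |
| ξ | spatial-vs-angular metric weight | 0.1 |
| ζ_D, ζ_M | spatial anisotropy of diffusion / morphology | task-dependent (0.5 denoise, 0.1 inpaint) |
| λ | Charbonnier contrast, score-gradient units | 2 on the fixtures |
| ν, σ, ρ | Gaussian scales (px) for switch gradient, convexity, shock sign | 1–2 |
| ε | soft-sign steepness | 1% of score range |
| τ | timestep | 0.9 × min(τ_D, τ_S) |

## Known limitations

* The anisotropic remainder of the diffusion keeps the trilinear stencil's
  lateral bias (the price of monotonicity); strongly anisotropic diffusion
  at orientations far from the grid axes is slightly more isotropic than the
  continuous operator.
* Inpainting amplitude is capped by the lifted Dirichlet data: wavelet
  supports overlapping the hole dim the boundary scores, so restored
  structures are dimmer than their surroundings (the crossing criterion is a
  ratio for this reason).
* The gauge evolution costs roughly an order of magnitude more than the
  invariant one (per-voxel trilinear sampling) and is fitted only on the
  initial condition; for strong shocks the frozen frame can lag the evolved
  structure.
* Parameters are calibrated on the synthetic fixtures, not on real imagery.
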