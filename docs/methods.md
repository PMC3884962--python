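# Methods

## Model and assumptions

The observed stack is modelled as a two-phase piecewise-constant image
multiplied by a depth-only bias field and corrupted by additive noise:

    I(z, y, x) ≈ c_i · γ^z + n,   i ∈ {tissue, background},

with `γ ∈ (0, 1]` an exponential decay per optical slice and `n` treated as
zero-mean Gaussian *after* median smoothing (raw confocal detection noise is
Poisson-like; the median filter makes the Gaussian approximation serviceable
and removes shot outliers). The point spread function is neglected: at voxel
sizes of ~1.75 μm in-plane and ~13 μm between slices it is small relative to
the sampling. The bias depends on `z` only — lateral inhomogeneity
(vignetting, absorption shadows) is *not* modelled.

Segmentation minimises the convex relaxation

    E(c1, c2, u) = Σ|∇u| + λ Σ (I − c1 γ^z)² u + λ Σ (I − c2 γ^z)² (1 − u),
    u ∈ [0, 1],

thresholded at `α` to a binary mask. With `γ = 1` this is globally convex
Chan–Vese; the bias makes the fidelity terms depth-aware while keeping
convexity in `u`, since `γ^z` enters only through the fixed ideal images.

## Minimisation

For fixed `u`, setting the first variation with respect to `c1`, `c2` to
zero gives the bias-weighted projections

    c1 = Σ u I γ^z / Σ u γ^{2z},   c2 = Σ (1−u) I γ^z / Σ (1−u) γ^{2z}.

For fixed `(c1, c2)` only the residual `e_r = (I − c1γ^z)² − (I − c2γ^z)²`
enters, and the `u`-problem is solved by Split Bregman with `d = ∇u` and
Bregman vector `b`:

1. Gauss–Seidel sweeps on the clamped subproblem: each voxel becomes the
   average of its six face neighbours plus `div(b − d)` minus `(λ/μ) e_r`,
   all divided by 6, clamped to `[0, 1]`; sweeps run in lexicographic
   `(z, y, x)` order and use already-updated neighbours.
2. Isotropic shrinkage `d = (∇u + b)/|∇u + b| · max(|∇u + b| − 1/μ, 0)`.
3. `b ← b + ∇u − d`.

The outer loop re-estimates `(c1, c2)` and `e_r` each iteration and stops
when the relative L1 change of `u` drops below `tol`, or flags the result
unconverged after `max_outer` iterations (no exception; the best state is
returned).

Stencils: forward differences with Neumann (replicated-edge) boundaries for
every gradient (`d`, `b`, TV); the divergence in the Gauss–Seidel source
term uses backward differences with zero padding at the leading face — the
exact negative adjoint of that gradient. Neighbour reads at volume faces
replicate the edge. The shrink threshold is `1/μ`, the value that minimises
the quadratic splitting as written; a compatibility flag (`shrink_on="lam"`)
selects `1/λ` instead, and the two coincide at `μ = λ`.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `lam` (λ) | 10.0 | fidelity weight, applied to min-max-normalised intensities. Squared residuals on normalised data are O(0.1) at full contrast and decay like `γ^{2z}`; λ ≈ 10 keeps the data term competitive with boundary length down to `γ^z ≈ 0.2` (≈ 30 slices at γ = 0.95). Smaller λ lets TV erase deep, low-contrast structure; larger λ traces noise. |
| `mu` (μ) | 10.0 | constraint weight; sets the shrink threshold `1/μ`. `μ = λ` is a robust pairing. |
| `gamma` (γ) | 1.0 | decay per slice index (not per μm). 1 disables the bias. `fit_gamma` calibrates it from the stack: least-squares slope of log per-slice median intensity vs `z`, exponentiated and clamped to (0, 1]. The median resists the bimodal tissue/background mixture. |
| `alpha` (α) | 0.5 | mask threshold; the mask is the *strict* super-level set, so `u = α` is excluded. |
| `tol` | 1e-3 | relative L1 change of `u` per outer iteration. |
| `max_outer`, `inner_sweeps` | 200, 1 | one Gauss–Seidel sweep per outer iteration is standard Split Bregman practice. |
| median radius | (0, 1, 1) | in-plane 3×3 window, none across `z`: interslice spacing (~12.9 μm) is ~7× the in-plane pixel (~1.75 μm), so a 3D window would mix anatomy. |
| spacing | (12.9, 1.75, 1.75) μm | used only for volumetry; the solver stencils are grid-index (isotropic) by design, matching the 1/6 neighbour averaging. Caller-supplied spacing always overrides file metadata. |

Internally the solver min-max normalises the volume so these defaults serve
arbitrary intensity scales; the reported `c1_`, `c2_` are re-estimated from
the final `u` on the original-scale image via the closed-form projections,
which is exact and avoids pushing the affine normalisation shift through
the multiplicative bias model. Initialisation is the normalised image
itself (contrast seeding avoids the all-one-phase fixed point of a constant
start); `d⁰ = b⁰ = 0`.

## Synthetic data

The phantom generator draws binary geometry (box, ellipsoid, two-chamber,
sponge — the last an ellipsoid minus random spherical holes standing in for
trabecular tissue, not anatomically calibrated), applies the exact forward
model `(c1 or c2)·γ^z`, adds Gaussian noise and clips at zero (intensities
are photon counts; the clip slightly biases the noise when σ is comparable
to `c2`). One generator seeded from `seed` drives hole placement and noise,
so identical spec + seed is bit-identical. Defaults: 32 slices of 64×64,
`c1 = 10`, `c2 = 2`, `σ = 0.8` (10% of contrast).

What passing phantom tests show: correct minimisation of the stated energy
and recovery under the model's own assumptions. What they do not show:
robustness to textured tissue, lateral bias, non-exponential decay, partial
volume at curved boundaries (the re-estimated constants carry a sub-percent
partial-volume bias there), or anisotropy-aware regularisation — real
stacks violate all of these to some degree.

## Numerical choices and degenerate inputs

* Gauss–Seidel sweeps are compiled with numba; results equal a scalar
  Python reference to 1e-12 (tested).
* A soft region whose bias-weighted mass vanishes (u ≡ 0 or ≡ 1) makes the
  corresponding intensity undefined; `estimate_intensities` raises a
  `DegeneratePartitionError` naming the collapsed phase.
* A constant volume yields `u ≡ 0.5` and an all-background mask (strict
  threshold) — single-phase, never mixed.
* Convergence is measured as `‖u⁺ − u‖₁ / max(‖u‖₁, 1e-12)`.
* The energy trace is evaluated at `(u^k, c1^k, c2^k)` on the working
  (normalised) scale. Split Bregman is not monotone early; tail
  monotonicity (final 5 iterations, relative slack 1e-6 for floating-point
  noise at the fixed point) is the asserted property.
* Empty-vs-empty Dice is defined as 1 (complete-agreement limit).
* Volumes are voxel counts × voxel volume (no surface meshing); the
  difference from mesh-based volumetry is a sub-voxel boundary-shell term.

## Known limitations

* **Discrete thresholding gap.** For the continuous TV the thresholded
  relaxed minimiser is a binary global minimiser at almost every threshold;
  for the *isotropic discrete* TV used here this fails on a small fraction
  of adversarial instances (the relaxed minimum can sit strictly below
  every binary labelling, with gaps on the order of `3 − 2√2` from diagonal
  configurations, and exactly balanced two-phase patterns make every
  constant `u` an energy tie). The tiny-grid acceptance test therefore uses
  noiseless two-valued instances with unbalanced phases, where exhaustive
  enumeration confirms exact optimality across 1000 random instances.
* The bias is depth-only and exponential in slice index; physical-depth
  (μm) parameterisation would require resampling metadata the formats do
  not reliably carry.
* Two phases only; multi-phase partitions and 4D (time) stacks are out of
  scope, as are proprietary microscope formats (convert to TIFF upstream)
  and spacing-aware TV stencils.
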