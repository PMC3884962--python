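# dcac — depth-aware convex active contour segmentation

`dcac` segments 3D confocal microscopy stacks in which fluorescence
intensity falls off with imaging depth — the situation faced when imaging
optically cleared embryonic hearts (or any thick cleared specimen) slice by
slice. Standard two-phase piecewise-constant segmentation (Chan–Vese)
assumes one intensity per tissue class throughout the volume; with depth
attenuation that assumption fails and deep structures are lost. `dcac`
multiplies each phase constant by a depth-dependent bias field, keeping the
problem convex, and solves it with the Split Bregman method.

It is aimed at researchers quantifying 3D morphology from confocal z-stacks
(e.g. myocardium vs. luminal space across developmental stages) who need
automatic, reproducible masks and physical volumes instead of weeks of
manual labelling.

## The model

Let `I(z,y,x) ≥ 0` be the (median-smoothed) stack, `z` the slice index with
`z = 0` nearest the objective. Each phase is modelled as a constant times a
depth bias `g(z) = γ^z`, `γ ∈ (0,1]`, giving ideal images `I₁ = c₁ γ^z`
(tissue) and `I₂ = c₂ γ^z` (background). Segmentation minimises, over a
relaxed partition `u ∈ [0,1]`,

```
E(c₁, c₂, u) = Σ |∇u|  +  λ Σ (I − c₁γ^z)² u  +  λ Σ (I − c₂γ^z)² (1 − u)
```

(isotropic discrete total variation, forward differences, Neumann
boundaries). For fixed `u` the intensities have closed forms —
bias-weighted projections `c₁ = Σ u·I·γ^z / Σ u·γ^{2z}` (likewise `c₂` with
`1−u`) — and for fixed `(c₁,c₂)` the problem is convex in `u` and is solved
by Split Bregman: an auxiliary field `d = ∇u` and Bregman vector `b`
decouple the TV term, alternating clamped Gauss–Seidel sweeps for `u`,
isotropic shrinkage `d = shrink(∇u + b, 1/μ)`, and the update
`b ← b + ∇u − d`. The final mask is the strict super-level set
`Σ = {u > α}` (default `α = 0.5`). At `γ = 1` the method reduces exactly to
globally convex Chan–Vese.

## Worked example

Generate a two-chamber phantom (32 slices of 64×64, intensities 10 vs 2,
depth decay γ = 0.95, noise σ = 0.8), segment it, and evaluate against the
known truth:

```
$ dcac phantom --shape 32 64 64 --geometry two_chamber --gamma 0.95 \
      --sigma 0.8 --seed 42 --out-image heart.tif --out-truth truth.tif
{"shape": [32, 64, 64], "foreground_voxels": 17160}

$ dcac segment --input heart.tif --output-mask seg.tif --gamma 0.95 \
      --report report.json
{"c1": 9.816228327888762, "c2": 2.0203147265384733, "iterations": 32,
 "converged": true, "mask_voxels": 16991}

$ dcac evaluate --mask-a seg.tif --mask-b truth.tif --image heart.tif
{"dsc": 0.9944657550291353, ...,
 "volume_per_mask_mm3": {"mask_a": 0.00067125069375, "mask_b": 0.00067792725},
 "voxel_counts": {"mask_a": 16991, "mask_b": 17160},
 "gamma_fit": 0.9506404815425202}
```

The solver converged in 32 outer iterations and recovered the phase
intensities (9.82 and 2.02 against the true 10 and 2) despite the deepest
slice retaining only `0.95³¹ ≈ 20%` of its surface brightness. The mask
overlaps the ground truth at Dice 0.994; volumes are voxel counts times the
physical voxel size (here the default 12.9 × 1.75 × 1.75 μm), and
`gamma_fit` recalibrates the decay constant from the stack itself (0.951 vs
the true 0.95).

The same pipeline is available as a scikit-learn-style estimator:

```python
from dcac import DepthAwareChanVese, read_volume

volume = read_volume("heart.tif")
est = DepthAwareChanVese(gamma=0.95).fit(volume)
est.mask_      # boolean (z, y, x) segmentation
est.c1_, est.c2_, est.n_iter_, est.converged_
```

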