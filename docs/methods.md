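# Methods

## The spiking cortical model

The SCM is a single-layer, locally connected lattice with one neuron per
pixel. Neuron `(i,j)` receives the normalized intensity `O ∈ [0,1]` as
feeding input plus linking input from its neighbours' previous pulses,
weighted by inverse squared distance. Its internal activity `F` leaks with
factor `f` per iteration; a pulse is emitted when `F` strictly exceeds the
dynamic threshold `Θ`, which decays with factor `g` and is recharged by `h`
after a pulse. The model needs no training; its pulse sequence encodes
segment and edge structure of the input.

Choices the update equations leave open, and how this package resolves them:

* **Initial state** `F = Θ = Y = 0`. Nothing else is canonical; zeros make
  every neuron with positive stimulus fire at the first iteration, the usual
  behaviour of SCM/PCNN implementations.
* **Update order.** Within iteration `n` the threshold is charged by the
  *previous* pulse (`Θ[n] = g·Θ[n−1] + h·Y[n−1]`) and the firing comparison
  uses the *previous* threshold (`Y[n] = [F[n] > Θ[n−1]]`). Many
  implementations instead charge the threshold from the current pulse; that
  variant is available as `ScmParams(threshold_uses_current_pulse=True)` but
  is not the default. For an isolated, fully driven neuron with the default
  parameters the default ordering gives the pulse train `1,1,0,0,0,1,1` over
  seven iterations (the second pulse occurs because the threshold lags one
  step).
* **Linking locality.** The inverse-square weight formula is formally global;
  we restrict it to a `(2r+1)²` window with default radius 1. The weights
  decay as `1/d²`, so the truncation error is small, and local linking is
  what the model's design intends.
* **Boundaries.** The linking correlation is zero-padded: neurons outside
  the image never fire, so border neurons receive less linking input. A
  consequence worth knowing: a perfectly uniform image does *not* keep all
  neurons synchronous forever — border desynchronization propagates inward
  at one pixel per iteration. Every frame retains the full symmetry of the
  lattice (rotations/flips commute with the dynamics).
* **Ties do not fire** (strict inequality), and all arithmetic is double
  precision with pulses stored as integers.

## Fusion rule and weight

Firing maps `T` are the per-pixel pulse counts. All patch statistics
(entropy, local energy `Σ T²`, differential excitation) use 3×3 patches
(`l_p = 1`) with **symmetric (mirror) padding**, so border statistics stay
in-range and homogeneous regions remain exactly homogeneous. The fusion
itself runs on the original 8-bit intensity scale — the weighting is
invariant to the global 1/255 factor — and the output stays floating point,
quantized (round half away from zero, clip to [0,255]) only when saved.

The entropy feature treats each 3×3 pulse patch as a Bernoulli source: with
`K` ones among 9 cells, `H = −p·log₂p − (1−p)·log₂(1−p)` at `p = K/9`, in
bits, with `0·log₂0 = 0`. Across `N_max` iterations these form a per-pixel
feature vector; the plain Euclidean distance between the two images'
vectors, scaled by `CS₁ = 3·N_max`, gives the entropy similarity. Since each
entry lies in [0,1], the distance is at most `√N_max` and
`S_En ≥ 1 − √N_max/(3N_max) ≈ 0.9255` at the defaults. Similarities are not
clamped; a user-supplied small `CS₁` can push them below the default band.

The WLD differential excitation `ξ = arctan(R/T)` is computed on the raw
integer firing times, not the display-rescaled FMI; `ξ` is invariant to
positive rescaling wherever `T > 0`, so the choice only matters at
zero-firing pixels, where the denominator is floored at `ε = 1e−6`
(equivalent to saturating toward ±π/2 for nonzero `R`). The arctangent keeps
`|ξ| < π/2`, so `|ξ_A − ξ_B| < π` and `S_WLD > 1 − π/CS₂ = 0.8` at the
default `CS₂ = 5π`. The combined weight `ω = S_En·S_WLD` therefore lies in
`(0.74, 1]`: the locally more energetic source always dominates, and the
weight softens the selection where the two modalities genuinely disagree.

On the energy tie `E_A = E_B` the rule's second branch applies (source B
receives weight `ω`); no randomization. Swapping the inputs reproduces the
fused image exactly at every non-tied pixel.

## Quality metrics

* **QM** — `MI(A,U) + MI(B,U)` from 256-bin joint histograms, log base 2;
  empty cells contribute nothing.
* **QE** — Xydeas–Petrović edge preservation. Sobel gradients give per-pixel
  edge strength and orientation; strength preservation is the min/max ratio,
  orientation preservation uses the wrapped axial distance
  `min(|Δα|, π−|Δα|)` (orientation is defined mod π, which also makes the
  metric invariant to transposing all three images). Both are passed through
  the standard sigmoids (Γg=0.9994, κg=−15, σg=0.5; Γα=0.9879, κα=−22,
  σα=0.8), and the product is normalized by its peak value so that perfect
  edge transfer scores exactly 1. Per-pixel scores are averaged with the
  source edge strengths as weights; if the sources carry no edges at all the
  score is defined as 0.
* **QS / QL / QT** — sliding-window metrics, default 8×8 windows with
  stride 1 (both configurable); window statistics use the unbiased `N−1`
  normalization, and intensities are normalized to [0,1] so the SSIM/UIQI
  stabilizers `C1 = C2 = 2e−6` act on the intended scale. The local salience
  weight is the variance ratio `λ = s_A/(s_A+s_B)` (0.5 when both windows
  are flat). QS gates on source agreement: windows with `SSIM(A,B) ≥ 0.75`
  use the λ-combination of `SSIM(A,U)` and `SSIM(B,U)`, others take the
  maximum. QL multiplies the saliency-weighted combination
  (`C(w) = max(s_A, s_B)`) on the intensity images with the same quantity on
  Sobel edge-magnitude images (jointly peak-normalized). QT mixes per-window
  quality scores against each source by the clipped covariance ratio
  `sim = σ_AU/(σ_AU+σ_BU)` (0.5 when both covariances vanish) and averages
  per window. The window quality in QT uses the stabilized SSIM form, which
  coincides with the universal image quality index away from degenerate
  (constant) windows but remains defined on them.
* **STD** — sample standard deviation with `N−1` denominator.

## Synthetic phantoms

`make_pair(seed, size, noise_sigma)` renders a CT-like and an MR-like image
of one seed-derived head layout (jittered centre, outer radius ≈ 0.42·size,
rim width ≈ 0.055·size, 3–5 dense blobs, 4–7 soft-tissue bumps, one texture
orientation), so a pair is co-registered by construction and zero outside a
common support disk. The CT-like image is piecewise constant — bright rim,
faint uniform interior, sharp bright blobs — with its salient gradients on
region boundaries. The MR-like image is smooth — Gaussian bumps plus an
oriented sinusoid confined to the deep interior, fading to a dark rim — with
its salient gradients in the interior texture. Gaussian noise (default
σ = 2 intensity units, a mild acquisition-noise level) is added inside the
support only, emulating atlas images with masked air, then clipped and
rounded to 8 bits. All randomness comes from numpy's PCG64 generator seeded
with explicit `(seed, stream)` tuples, so outputs are bit-identical across
platforms.

What the phantoms deliberately do **not** model: MR physics (bias fields,
relaxation contrast), CT Hounsfield calibration, partial-volume effects,
registration error, or pathology. Tests passing on these phantoms establish
the correctness and the qualitative behaviour of the pipeline — that the
fusion is convex, symmetric, deterministic and preserves more information
and structure than pixel averaging — not clinical performance on real
scanner data.

## Problem sizes and defaults

Unit and property tests run on 16×16–64×64 images, where brute-force scalar
oracles (per-pixel SCM iteration, patch counting, per-window metric loops)
are affordable; the comparative study against the averaging baseline uses
20 pairs at 128×128, and the demonstration pair is 256×256, the typical
slice size for this task. Default parameters (`f=0.9, g=0.3, h=20,
N_max=20, l_p=1, CS₁=3·N_max, CS₂=5π`, 8×8 stride-1 windows) are the
standard operating point of the method; all are exposed through
`RunConfig`/CLI flags.

## Known limitations

* Two sources only, single-channel, pre-registered; no color/PET/SPECT
  fusion, no registration or intensity standardization.
* The SCM iteration count is fixed (default 20), not adapted per image;
  representation quality degrades for much smaller or larger counts.
* Window-based metrics are O(windows × window area); stride 1 on large
  images is memory-heavy (~30 MB per statistic at 256×256). Increase the
  stride for big images.
* Float comparisons between the optimized pipeline and the scalar reference
  agree to ~1e−9 (summation order), not bit-for-bit; pulse series, being
  binary, do agree bit-for-bit.
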