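# Methods

This note documents the models implemented in `cdtikit`, the conventions
and defaults they use, and what the synthetic experiments do and do not
establish.

## Phantom model

A short-axis left-ventricle slice is modelled as an annulus on a 2-D voxel
grid (row-major, voxel centers at integer coordinates, 0-based). Blood pool
is the disc ρ < r_endo around the LV center, myocardium the ring
r_endo ≤ ρ ≤ r_epi; the slice is treated as a single plane (the 8 mm slice
thickness is not modelled). Transmural depth is
d = (ρ − r_endo)/(r_epi − r_endo) ∈ [0, 1].

Local cardiac frame at each voxel, in (x = +column, y = +row, z = slice
normal): radial **r** (unit in-plane vector from the center),
longitudinal **l** = ẑ, circumferential **c** = ẑ × **r**. Frames are
orthonormal to 1e−10 by construction.

Prescriptions: helix angle linear in depth between endo- and epicardial
values (defaults +60° → −60°), sheetlet angle E2A constant (default 20°),
MD default 1.0×10⁻³ mm²/s, FA default 0.45. These are conventional,
physiologically plausible defaults, not estimates of any particular
cohort. A mirrored-chirality (situs inversus) variant negates HA
everywhere; MD/FA are unchanged.

Tensor construction inverts the map computation exactly. Eigenvalues solve
trace/3 = MD and the FA closed form with the secondary anisotropy pinned at
λ₂/λ₃ = 1.5 (needed so the second eigenvector — hence E2A — is well
defined); the remaining 1-D problem in λ₃ is monotone and solved by Brent's
method (xtol 1e−18, rtol 1e−15) once per distinct FA (the solve is
scale-invariant, so results are cached and rescaled by MD). FA = 0 is
special-cased to the isotropic tensor. FA below the floor imposed by the
shape ratio (≈0.213 at 1.5) is rejected as infeasible. Eigenvectors are
assembled from the frame so that e₁ sits in the tangential plane at the
helix angle and e₂ at the sheetlet angle in the cross-myocyte plane; the
phantom→maps round trip reproduces all four prescribed maps to better than
1e−6 (tested).

An infarct analogue rebuilds an angular sector of the annulus with lesion
MD/FA (defaults in the tests: lesion MD 1.25×10⁻³ vs remote 1.05×10⁻³
mm²/s, giving a ΔMD contrast of 0.20×10⁻³); remote voxels are bit-identical
to the base phantom.

## Signal simulation

Monoexponential diffusion signal S = S₀·exp(−b·gᵀDg) per image, with the
acquisition structure of a STEAM protocol: b = 0, plus b = 150 and
b = 600 s/mm² in the same fixed 6-direction dual-gradient scheme (stored as
constants; any rank-sufficient set works, fixing one makes runs
reproducible). Repetition counts per regime:

| regime | b0 | b600 | b150 | images |
|--------|----|------|------|--------|
| full   | 12 | 10   | 2    | 84     |
| 5BH    | 4  | 4    | 1    | 34     |
| 3BH    | 2  | 2    | 1    | 20     |
| 1BH    | 1  | 1    | 0    | 7      |

Magnitude noise is Rician: S_noisy = √((S+n₁)² + n₂²) with n₁, n₂ ~
N(0, σ²). Every image draws from its own substream of the master seed
(`SeedSequence([seed, index])`), so series are bit-reproducible and
subsetting never perturbs retained images. SNR is defined as S₀/σ on the
b0 image; the default σ puts single-repetition SNR at 25, a regime where
the 1BH maps are visibly degraded but fittable. Breath-hold datasets are
built by keeping the first/central/last N repetitions per (b, direction)
group (central starts at ⌊(R−N)/2⌋); repetitions are then averaged
arithmetically per group (b ascending, direction index order).

Not simulated: EPI distortion, motion, eddy currents, partial volume,
parallel-imaging reconstruction, co-registration error.

## Tensor fitting

Ordinary (unweighted) least squares on the log signal,
ln S = ln S₀ − b·gᵀDg, one solve per masked voxel via a shared
pseudoinverse; design rows [1, −b gx², −b gy², −b gz², −2b gx gy,
−2b gx gz, −2b gy gz]. The fit uses all available averaged images (b150
rows included when the regime provides them). No positivity constraint or
eigenvalue repair anywhere — indefinite tensors flow through the pipeline
unchanged. Masked voxels with nonpositive averaged signal are excluded,
zero-filled, and counted in the fit report. Without noise the model is
exact: recovery is at machine precision (tested < 1e−9 relative). Weighted
or robust fitting is deliberately out of scope.

Two normalization schemes condition tensors for the network: global
scaling by 1500 s/mm² (mapping ~10⁻³ mm²/s diffusivities into roughly
[−1, 1]) and per-channel z-scoring with statistics fitted on the training
split (background zeroed). De-normalization inverts either exactly.

## Maps

Batched symmetric eigen-decomposition, eigenvalues descending, eigenvector
signs fixed deterministically (first nonzero component positive). HA flips
e₁ so its circumferential component is non-negative, then
HA = atan2(e₁·l, e₁·c) ∈ (−90°, 90°]; voxels with exactly radial e₁ are
flagged. E2A uses the cross-myocyte axis m = normalize(r − (r·e₁)e₁) and
in-wall axis k = e₁ × m, E2A = |atan2(e₂·m, e₂·k)| folded into [0°, 90°]
(absolute-angle convention); degenerate λ₂ = λ₃ voxels are flagged. These
conventions are explicit package choices — the literature states them in
several equivalent forms — and are exactly consistent with the phantom
construction, which is the testable contract (round-trip and 90°
rotational-equivariance tests).

## De-noiser

Tensor-to-tensor: 6-channel normalized grid in, 6-channel out, spatial
size preserved. The generator is U-shaped with window-restricted
self-attention blocks (pre-norm attention + MLP, both residual), stride-2
convolutional downsampling, nearest-neighbour + convolution upsampling and
skip concatenation. The network predicts a residual correction added to
its input; the output projection is zero-initialized so the untrained
generator is exactly the identity — training starts from the LLS answer
and can only improve on it, and the contract is testable.

Presets. `reference` mirrors the full-scale model: base width 112, three
encoder scales + bottleneck with two blocks each, window 8, 8 heads, MLP
ratio 4 — ~4.2×10⁷ parameters (counted analytically, never trained in the
test suite; full-scale training is far beyond desk scale). `tiny` is the
desk-scale working model: base width 16, one encoder scale + bottleneck,
window 4, 2 heads, MLP ratio 2 — 24 534 parameters. Attention internals
are presets, not contracts.

The critic is a PatchGAN-style stack of three stride-2 convolutions
(widths 16/32/64, LeakyReLU 0.2, no normalization) with a final 1-channel
convolution: a spatial grid of unbounded scores, one per receptive patch
(128×128 → 16×16). Losses follow the Wasserstein-gradient-penalty scheme:
critic loss E[c(fake)] − E[c(real)] + λ_gp·E[(‖∇ₓc(x̃)‖₂ − 1)²] on convex
interpolates, generator adversarial loss −E[c(fake)]. The penalty requires
exact second derivatives; the bundled autodiff engine builds backward
passes out of traced primitives, so double backprop is exact (verified
against analytic gradients of a linear critic).

Training: decoupled-weight-decay Adam, loss MAE + λ_adv·adversarial.
The `reference` schedule keeps the full-scale settings (lr 1e−4,
β₁ 0.9, β₂ 0.999, weight decay 0, 500 epochs, batch 8, λ_adv > 0). The
`tiny` schedule is the package's desk-scale choice: lr 2e−3, 20–30 epochs,
batch 8, λ_adv = 0 (pure MAE regression — at this model/data scale the
adversarial term adds runtime and variance without measurable benefit; the
WGAN-GP path remains fully implemented, tested, and switchable via
λ_adv). Checkpoint selection: lowest validation MAE across epochs.
Everything is seeded; identical configs give identical loss curves.

Augmentation: repetition-subset resampling (first/central/last, tripling
the training set), in-plane rotation with tensor reorientation
D′ = R D Rᵀ (omitting the reorientation would corrupt the targets — the
channel mixing is derived from the conjugation and sign-matched to the
grid-rotation convention), and content-aware cropping: the window is
centered on the myocardium's bounding box, guaranteed to contain it, and
padded to the target size. The experiment pipeline trains on 48×48 crops
of 64×64 phantoms and predicts full-size fields by crop-and-paste.

Splitting is at the patient level, 80:10:10 with largest-remainder
rounding, seeded (10 subjects → 8/1/1). The ensemble is bagging:
independently seeded members, elementwise-mean prediction, then
de-normalization. By convexity the ensemble MAE never exceeds the mean
member MAE.

## Evaluation

Per-subject errors are voxel means over the myocardial mask: HA by MAAE
(|x−y| if < 90°, else 180°−|x−y| — axes 180° apart are identical, 90° is
maximal), E2A by MAE on absolute angles, MD and FA by MAE (MD reported in
10⁻³ mm²/s). Cohort summaries are median [IQR] across subjects with
linear-interpolation quantiles (IQR = Q3 − Q1); voxels are never pooled
across subjects.

Transmural HA profiles cast one ray per epicardial border pixel from the
LV center, sample bilinearly every 0.25 voxels, discard blood-pool and
background samples, and length-normalize to [0, 1]. Samples keep at least
half a voxel clear of the wall boundaries (bilinear values there would be
biased toward the interior) while positions are normalized by the full
wall extent; non-myocardial voxels are nearest-filled before
interpolation. The median across rays is reported with both sd and IQR
dispersion bands. Three-zone FA statistics split the wall by depth thirds.
ΔMD is mean lesion MD minus mean remote MD. The patch-level comparison
tiles the mask bounding box with non-overlapping 5×5 patches (≥1 masked
voxel to qualify, mean error over masked voxels, strict inequality for a
win). Significance testing is intentionally left to standard statistics
packages; the reports store per-subject values for that purpose.

## Desk-scale experiment conditions

The default experiment: 50 phantom subjects (64×64 grid, per-subject
jitter in center, radii, HA endpoints, E2A, MD, FA drawn from seeded
substreams), SNR 25, 1BH regime, z-score normalization, tiny preset,
two-member ensemble, 30 epochs. This trains in a few minutes on one CPU
and reproducibly yields 40–50% median reductions in HA/E2A/MD/FA errors
versus plain LLS on held-out subjects. Problem sizes were chosen so the
whole suite runs comfortably on a laptop-class machine; larger cohorts and
longer schedules only widen the margins.

## What passing tests do and do not show

The phantoms are smooth, piecewise-analytic, and noise is spatially
uncorrelated, so de-noising them is easier than de-noising clinical maps:
real acquisitions add registration error, motion, partial volume at the
blood interface, wall-thickness variation, papillary muscles, and
pathology-induced heterogeneity, none of which are simulated. Results here
validate the machinery (fitting, metrics, training dynamics, ensembling,
out-of-distribution chirality behavior) — not clinical performance. The
mirrored-chirality check is likewise an artifact-level robustness
contract, not a clinical claim.

## Numerical choices

- Networks run in float32; analysis code (fitting, maps, metrics) in
  float64.
- Eigen-decomposition ties are broken by the sign convention; flagged
  voxels (radial e₁, degenerate e₂, all-zero eigenvalues) propagate NaN
  and are excluded from masked means.
- Geometry boundary conditions: myocardium includes both boundary radii
  (r_endo ≤ ρ ≤ r_epi); depth is monotone in ρ.
- Lesion sectors are half-open [start, stop) in degrees, measured
  counter-clockwise from +x, wrap-around allowed.
- The patch grid anchors at the mask bounding-box origin.
- All master seeds expand through `numpy.random.SeedSequence`; derived
  seeds stay below 2³¹.
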