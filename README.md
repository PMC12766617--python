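# cdtikit

Tools for studying **accelerated cardiac diffusion tensor imaging (cDTI)**
on synthetic data: analytic left-ventricle phantoms with known
microstructure, forward simulation of STEAM diffusion-weighted images under
reduced breath-hold protocols, linear least-squares tensor fitting,
adversarially trainable tensor-space de-noising, and the full map-quality
evaluation suite.

## The problem

cDTI probes myocardial microstructure through water diffusion anisotropy,
yielding four scalar maps per slice from the fitted diffusion tensor
**D** (per-voxel symmetric 3×3, six unique elements):

- **MD** = (λ₁+λ₂+λ₃)/3 — mean diffusivity (mm²/s),
- **FA** = √(3/2)·√(Σᵢ(λᵢ−MD)²)/√(Σᵢλᵢ²) — fractional anisotropy,
- **HA** — helix angle: the angle of the primary eigenvector's tangential
  projection against the circumferential direction, varying roughly
  linearly from positive at the endocardium to negative at the epicardium,
- **E2A** — absolute second-eigenvector (sheetlet) angle in the
  cross-myocyte plane.

One STEAM repetition (a b=0 image plus 6 diffusion directions) costs 18
heartbeats; enough repetitions for good SNR at two cardiac phases amount to
16 min per slice and around 192 min for whole-heart coverage — the main
obstacle to clinical use. Cutting repetitions (the 5BH/3BH/1BH breath-hold
regimes, down to a single b0+b600 repetition) saves time but floods the
maps with noise. This package implements the de-noising strategy that makes
the reduced acquisitions usable: fit tensors by ordinary linear least
squares on the averaged log-signal, then refine the 6-channel tensor grid
with an ensemble of U-shaped windowed-attention networks trained with an
MAE + Wasserstein-adversarial objective (gradient penalty, patch critic,
residual learning, identity at initialization).

Because clinical cDTI data are private, everything here runs on synthetic
short-axis phantoms: an annular myocardium with a prescribed transmural HA
ramp, constant E2A, uniform MD/FA, Rician magnitude noise, and exact
ground-truth tensors — so every stage of the pipeline can be validated
against closed-form oracles.

## Worked example

```python
from cdtikit import workflow

cfg = workflow.ExperimentConfig(seed=1)   # 50 subjects, 1BH regime, SNR 25
report = workflow.run_experiment(cfg)
r = report["regimes"]["1BH"]
print(r["lls"]["median"])
print(r["denoised"]["median"])
```

prints (median over the held-out test subjects; HA/E2A in degrees, MD in
10⁻³ mm²/s, FA dimensionless):

```
{'ha_maae': 7.85, 'e2a_mae': 13.57, 'md_mae': 0.068, 'fa_mae': 0.071}
{'ha_maae': 3.92, 'e2a_mae': 7.26,  'md_mae': 0.032, 'fa_mae': 0.042}
```

Reading: with a single breath-hold the raw least-squares helix-angle maps
are off by ~8° on average; the trained two-member tiny ensemble halves
that, and improves E2A, MD and FA errors by 40–50% as well. The run takes a
few minutes on one CPU (it trains the ensemble from scratch, seeded and
fully reproducible).

The same pipeline is available from the shell:

```sh
cdtikit run --seed 1 --out results/experiment
cdtikit simulate --seed 1 --out results/subject0
cdtikit train --seed 1 --out results/ckpts
cdtikit denoise --checkpoints results/ckpts \
    --tensors results/experiment/subject_001/1BH/tensor_lls.nii.gz \
    --out denoised.nii.gz
```

Tensor fields, masks and maps are NIfTI; reports, gradient tables and
sidecars are JSON; configs are YAML.

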