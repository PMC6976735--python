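# mr2sct

Synthetic-CT generation from multi-sequence brain MR with a conditional GAN,
plus the full image-quality and dosimetric QA stack needed to judge whether
the synthetic CT is good enough to calculate radiotherapy dose on.

## The problem

MR-only radiotherapy planning needs a CT-like map of electron density, because
dose engines trace photon attenuation through tissue and MR intensity carries
no such information. One route is to *translate* the MR volumes into a
synthetic CT (sCT): a generator network maps co-registered T1w, T2w and FLAIR
images, stacked as a 3-channel input, to a Hounsfield-unit volume, and an
adversarially trained discriminator pushes the output toward realistic CT
texture. Whether the translation is clinically usable is then a dosimetric
question: water-equivalent path lengths, dose-volume histogram (DVH)
parameters and gamma pass rates must agree with the real-CT plan, not just
the voxel-wise error.

`mr2sct` implements that entire workflow so it can be exercised end-to-end on
procedurally generated digital head phantoms — no patient data, scanners or
commercial planning system required:

- **`mr2sct.phantom`** — seeded head phantoms (nested-ellipsoid scalp / skull /
  brain / CSF / lesion / optional metal clip), three MR sequences with
  tissue-dependent contrast, Rician noise and smooth multiplicative bias
  fields, and analytic dose grids.
- **`mr2sct.preprocess`** — polynomial bias-field correction, Nyul–Udupa
  histogram-landmark standardization to [0, 4095], Gaussian + Otsu +
  morphology body masking, background fills (CT −1000 HU, MR 0), 3-channel
  stacking, seeded 128×128 patch extraction, flip/shift/zoom/rotate
  augmentation.
- **`mr2sct.cgan`** — pix2pix-style conditional GAN: U-Net generator
  (strided 4×4 convolutions, batch norm, skip connections, tanh scaled to
  HU), PatchGAN discriminator with a ≈32 px receptive field, BCE adversarial
  loss + λ·L1, He initialization, Adam, 5-fold cross-validation splitting,
  9:1 train/validation split, fully-convolutional full-size inference. Built
  on `mr2sct.nn`, a compact numpy layer library with hand-written
  backpropagation (finite-difference-verified).
- **`mr2sct.sct`** — missing-slice compensation: slices outside the predicted
  range are filled from the real CT with each CT number replaced by the
  median predicted HU observed at that CT number over the predicted region.
- **`mr2sct.imageqa`** — mean absolute error for the whole body, soft tissue
  (−100 HU < rCT < 150 HU) and bone (rCT ≥ 250 HU), and signed-difference
  percentile profiles in 20-HU bins of rCT.
- **`mr2sct.dosimetry`** — HU → relative electron density calibration,
  equivalent path length by exact Siddon voxel traversal with a 180-beam
  (181°→179°, 2° steps) sweep, global 2D gamma analysis (3%/3 mm, 2%/2 mm,
  1%/1 mm), DVH metrics (D2%, D50%, D98%, V95%, Dmax, Dmean), and
  paired t / Wilcoxon signed-rank comparison chosen by a Shapiro–Wilk
  normality check.
- **`mr2sct.pipeline` / `mr2sct.cli`** — NIfTI-based orchestration:
  `simulate → preprocess → train → predict → assemble → evaluate`.

## The model

The generator G minimizes

    L(G) = E[ −log D(x, G(x)) ] + λ · MAE(y, G(x)),
    MAE  = (1/n) Σᵢ |rCTᵢ − sCTᵢ|,

with λ = 100, where x is the 3-channel MR patch, y the real CT (rCT) patch
and D the PatchGAN discriminator trained with binary cross-entropy on
real/fake patch scores. Training uses 128×128 patches (64×64 in the desk
test profile); inference runs the same fully-convolutional network on whole
slices. The equivalent path length of a beam is EPL = ∫ ρₑ(CT(s)) ds from the
body surface to the isocenter along the beam central axis, with ρₑ the
relative electron density from a piecewise-linear calibration anchored at
(−1000 HU, 0.0) and (0 HU, 1.0). A dose point passes gamma at criterion
(ΔD%, dta) when min over the search disc of
√((ΔD/(ΔD%·D_norm))² + (r/dta)²) ≤ 1.

## Worked example

```python
from mr2sct import pipeline

study = pipeline.learning_study(seed=1)   # ~7 min on one CPU core
rep = study["heldout_report"]
print(f"epoch-1 val L1 : {study['epoch1_val_l1']:.1f} HU")
print(f"final   val L1 : {study['final_val_l1']:.1f} HU")
print(f"held-out MAE   : body {rep.mae_body:.1f} / "
      f"soft {rep.mae_soft:.1f} / bone {rep.mae_bone:.1f} HU")
```

prints (seed 1):

```
epoch-1 val L1 : 266.9 HU
final   val L1 : 37.1 HU
held-out MAE   : body 52.5 / soft 52.6 / bone 51.4 HU
```

Five noise-free phantom subjects are simulated; the desk-profile cGAN
(depth-3/width-16 U-Net, 64×64 patches, 50 epochs) trains on four of them and
predicts the fifth. Validation L1 falls from 267 HU to 37 HU — the network
recovers the deterministic MR→HU mapping — and the held-out whole-body MAE of
52 HU shows the mapping generalizes across anatomies. On real patient data
errors are substantially larger (partial-volume voxels, registration error,
anatomy the phantom lacks); see `docs/methods.md` for what phantom results do
and do not establish.

The same study drives the dosimetric QA: a 180-beam EPL sweep between the
real and synthetic CT, gamma pass rates on a toy pencil-beam dose
recalculation, and DVH differences. The command-line interface exposes each
stage (`mr2sct simulate`, `preprocess`, `train`, `predict`, `assemble`,
`evaluate-image`, `evaluate-dose`, `run-all`); run `mr2sct --help`.

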