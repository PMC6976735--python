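# Methods

This note records the modeling choices, defaults and numerical conventions of
`mr2sct`, and what its phantom-based results do and do not establish.

## Digital head phantom

The phantom is built from nested ellipsoids: an outer scalp ellipsoid, a
skull shell, a brain compartment, an ellipsoidal CSF ventricle, a spherical
lesion inside the brain and an optional small metal clip. Analytic shapes
were chosen deliberately: their voxel memberships are exact, so census-style
oracles (voxel counts per tissue, HU histograms) can be asserted without
tolerance. Per-subject anatomy is jittered ±5 % (seeded) so cross-validation
subjects differ.

Default tissue CT numbers (HU): air −1000, scalp 40, bone 900, brain 30,
CSF 10, lesion 35, metal 3000. These are plausible configurable defaults,
not measurements. MR tissue means are chosen per sequence so that the
clinically familiar contrast ordering holds (fat-bright T1w, CSF-bright T2w,
CSF-suppressed/lesion-bright FLAIR) and — importantly for the learning study
— so that every pair of tissues with different HU also has a different
(T1w, T2w, FLAIR) triple. With noise and bias off, CT is then an exact
deterministic function of the MR triple, which is what makes small-scale
generator training a meaningful parameter-recovery experiment.

MR degradation: a multiplicative bias field exp(a·P(x)) with P a random
polynomial of total degree 2 in normalized coordinates, rescaled to unit
peak so the amplitude `a` (default 0.15) bounds the log-field excursion; and
Rician noise formed as the magnitude of a complex Gaussian (the physics of
magnitude MR images; default σ = 15 image units, ≈2–3 % of tissue signal).
The analytic dose grid superposes Gaussian-profile beams with exponential
depth attenuation, normalized to deliver the prescription at the isocenter,
so gamma and DVH code can be tested against closed forms.

What the phantom does **not** emulate: partial-volume voxels (tissue
boundaries are hard), anatomical texture beyond optional Gaussian HU noise,
susceptibility/geometric distortion, inter-sequence misregistration, and
realistic pulse-sequence physics. Every error source the translation network
faces in patients beyond pure intensity mapping is therefore absent, and
phantom MAE values must be read as a lower bound / correctness check, not a
performance claim.

## Preprocessing

*Bias correction.* The log-image inside the body mask is fitted by a
least-squares polynomial of total degree 3 (degree 2 in the pipeline, whose
simulated fields are degree 2), iterated twice with Cauchy-style outlier
down-weighting so edges and lesions influence the fit less; the estimated
smooth field is divided out and the output rescaled so the masked mean is
preserved exactly. This is a deliberately simple estimator behind the same
contract as a full N4 implementation (smooth multiplicative field removed);
any such implementation can be substituted.

*Intensity standardization.* Histogram-landmark standardization with
landmarks p1, d10…d90, p99 (robust percentiles instead of min/max). Fitting
maps each training volume's [p1, p99] onto [0, 4095] and averages the mapped
landmarks; application is piecewise-linear between the volume's landmarks
and the standard ones, with end-segment linear extrapolation and clipping to
[0, 4095]. Piecewise-constant phantoms can tie decile landmarks; ties are
collapsed on the input side (mean of their mapped targets) and the standard
scale is forced strictly increasing by a minimal epsilon. Standardizers are
fitted per sequence, per training fold.

*Body mask.* Gaussian blur (default one voxel per axis; a mm-valued sigma is
accepted), Otsu threshold on a 256-bin histogram, binary closing with an
in-plane radius of 2 voxels (z-scaled by the spacing ratio), hole filling,
largest connected component. The pipeline masks CT and MR with the CT-derived
mask since phantom volumes are perfectly co-registered; the function itself
is source-agnostic.

*Patches.* Sampling is uniform with replacement over all admissible
positions — patch fully inside the slice and body fraction ≥ 0.5 by default
— enumerated exactly via per-slice integral images, with an integer RNG
protocol pinned by seed. Augmentation applies one shared geometric transform
(horizontal flip p = 0.5, shift ≤ 10 % of the side, zoom 0.9–1.1, rotation
≤ 10°, bilinear for both modalities) to the MR channels and the CT patch,
filling exposed pixels with the background values (MR 0, CT −1000).

## Conditional GAN

The generator is a U-Net: encoder of 4×4 stride-2 convolutions
(LeakyReLU 0.2; batch norm on all but the first level), decoder of 4×4
stride-2 transposed convolutions (ReLU, batch norm) with channel-concatenated
skip connections, final tanh mapped linearly from [−1, 1] to
[−1024, 3071] HU. The discriminator is a PatchGAN over the 4-channel
(MR, CT) concatenation; its layer stack is derived from the requested
receptive field (n stride-2 4×4 layers plus two unit-stride 4×4 layers:
16/34/70 px for n = 1/2/3), so the default of 32 px realizes 34 px, within
the ±2 px contract. Weights are He-initialized, biases zero.

Losses: BCE-with-logits adversarial terms (discriminator: mean of real→1 and
fake→0; generator: fake→1) plus λ·L1 with λ = 100. The L1 term inside the
generator objective is computed on the tanh scale, as in standard pix2pix
practice — λ = 100 is calibrated for unit-scaled images and would be
meaningless against raw HU — while all reported L1/MAE numbers are in HU.
The evaluation MAE function itself, (1/n)Σ|rCT−sCT|, operates on HU volumes.

Two named profiles fix the unprinted architecture sizes:

| profile | depth | base width | patch | epochs | batch | lr |
|---|---|---|---|---|---|---|
| `paper` | 5 | 64 | 128 | 500 | 32 | 2e−4 |
| `desk` | 3 | 16 | 64 | 50 | 16 | 1e−3 |

The full-scale profile keeps the pix2pix optimizer conventions
(Adam β₁ = 0.5, lr 2e−4, batch 32). The desk profile exists to make
convergence observable in minutes on one CPU core; at that scale 2e−4 with
batch 32 yields only ~450 Adam steps in 50 epochs and leaves the network far
from converged, so the desk profile pins lr 1e−3 and batch 16. These are
test-profile design choices, not claims about the full-scale system.

Training splits patches 9:1 into train/validation (seeded, at the patch
level within the training folds); subjects are partitioned for
cross-validation by seeded round-robin after shuffling, giving fold sizes
that differ by at most one (15 IDs at k = 5 → five triples). Inference is
slice-wise and fully convolutional; sides not divisible by 2^depth are
reflect-padded and cropped back. All layers run in float32 (each layer
accepts a dtype for float64 finite-difference verification, which the test
suite performs on every layer type and on the assembled networks).

The noise-free learning study (five subjects, four for training) bypasses
per-volume landmark standardization in favor of one global linear MR scale:
with noiseless piecewise-constant histograms the decile landmarks tie in
subject-dependent ways, which would corrupt the cross-subject consistency of
the MR→CT mapping that the study is designed to probe. Nyul–Udupa remains
the default for noisy inputs.

## Synthetic-CT assembly

When the predicted range misses top/bottom slices, missing slices are copied
from the real CT with each voxel's CT number replaced through a lookup built
on the predicted overlap: real-CT values are binned to integer HU and each
observed value maps to the median (even counts: mean of the two central
values) of the predicted HU at those voxels. Queries between observed values
are resolved by linear interpolation and beyond the covered range by
constant extrapolation — a monotone, deterministic fallback the source
procedure leaves unspecified. Background voxels (−1000 HU) pass through
unchanged.

## Evaluation

*Image quality.* Region MAE uses the real CT for region membership inside
the body mask: soft tissue strictly −100 < HU < 150 (the interval notation
of the reference table is taken over the looser prose), bone ≥ 250 HU.
Binned difference profiles group voxels by rCT into 20-HU bins anchored at
−1000 HU and report 25th/50th/75th percentiles (linear interpolation between
order statistics) of the signed difference sCT−rCT; absolute-difference
percentiles are emitted alongside, signed being primary.

*EPL.* Relative electron density comes from a piecewise-linear calibration
with anchors (−1000, 0.0), (0, 1.0), (1000, 1.52), (3000, 2.5) — a pinned,
configurable stand-in for a scanner-specific curve; values are clipped to 0
below the first anchor and to the last RED above the last. The ray runs in
the axial isocenter plane from the body-surface entry point to the
isocenter (entry = outer face of the outermost masked voxel along the ray),
using exact voxel-boundary (Siddon) traversal; physical depth is the
entry–isocenter distance. Gantry angles follow IEC 61217 with image rows
increasing posteriorly. The sweep covers 181°→179° in 2° steps (180 beams)
and reports mean ± SD, range and the fraction of beams within ±5 mm.

*Gamma.* Global normalization to the prescription dose; the evaluated
distribution is bilinearly upsampled ×3 and searched over a disc of radius
3×DTA; the low-dose cutoff defaults to 0 (flag for the clinical 10 %
convention). A point with γ = 1 exactly passes (tolerance 1e−6), so a
uniform dose offset equal to the dose criterion reports a 100 % pass rate at
γ = 1, the documented boundary case.

*DVH.* D_x% is the dose exceeded by x % of the structure volume, computed as
the (100−x)th percentile of voxel doses with linear interpolation; V95 % is
the fraction of structure voxels at or above 95 % of prescription.

*Statistics.* Differences are tested for normality with Shapiro–Wilk at
α = 0.05; normal → paired t-test, otherwise Wilcoxon signed-rank (exact null
for n ≤ 25 nonzero differences, normal approximation with continuity
correction above; zero differences discarded). All-zero differences are
degenerate and report p = 1.

*Toy dose engine.* `simple_dose_2d` is a deliberately crude
water-equivalent-depth pencil-beam model (rotate RED map, cumulative WED,
exponential attenuation, Gaussian lateral profile) whose only purpose is to
propagate CT differences into dose so the gamma/DVH machinery has a
non-trivial, density-sensitive input on phantoms. It is not a clinical dose
algorithm and no result computed with it should be read as one.

## Problem sizes and determinism

The standard study uses five subjects of 16×96×96 voxels at 2.5×1×1 mm,
120 patches per training subject and 50 desk-profile epochs; evaluation uses
180 EPL beams and a five-beam toy dose on the central slice. Every random
choice — anatomy jitter, noise, bias coefficients, patch positions, weight
initialization, shuffling, fold assignment — derives from a single integer
seed, and identical seeds reproduce bit-identical phantoms and training
trajectories on a fixed platform.

## Known limitations

- Phantom realism as listed above; in particular the absence of
  partial-volume boundaries makes both the translation task and the body
  masking easier than on patient data.
- The bias estimator models log-bias as a global low-order polynomial and
  will under-fit fields with more structure than its degree.
- EPL is central-axis only (no divergence/fan) and 2D in the axial plane of
  the isocenter slice.
- Gamma search resolution is the upsampled grid (×3); γ values carry the
  corresponding discretization of the distance term.
- The adversarial component at desk scale mainly regularizes; with λ = 100
  the L1 term dominates, and no claim is made that the desk-scale
  discriminator has learned a meaningful texture prior.
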