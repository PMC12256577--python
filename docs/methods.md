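# Methods

## Problem and model

`petcycle` translates count-limited ("low-dose", LD) PET slices into
standard-dose-equivalent (SD) images. Low-dose acquisition here means a
short frame — 30 s instead of 150 s per bed position, an 80% reduction in
acquisition time — so LD and SD images share the underlying activity
distribution and differ in Poisson counting noise.

The model is a cycle-consistent adversarial translator with two
generators, `G_A: LD -> SD` and `G_B: SD -> LD`, and two multi-scale patch
critics, `D_A` (scores the LD domain) and `D_B` (scores the SD domain).
The generator objective is

```
L = λ_idt · L_idt + λ_cycle · L_cycle + L_adv + λ_pept · L_pept
```

with

- **adversarial term** `L_adv`: Wasserstein form. Critics maximise
  `E[D(real)] − E[D(fake)]` subject to a gradient penalty
  `λ_gp · E[(‖∇_x̂ D(x̂)‖₂ − 1)²]` on random interpolates x̂ between real
  and fake samples (`λ_gp = 10`); generators minimise `−E[D(fake)]`. A
  least-squares (MSE) adversarial variant is available as the ablation
  baseline of the non-Wasserstein model family.
- **cycle consistency** `L_cycle = E‖G_B(G_A(x_A)) − x_A‖₁ +
  E‖G_A(G_B(x_B)) − x_B‖₁` (per-sample L1 summed over pixels, averaged
  over the batch).
- **identity term** `L_idt = E‖G_A(x_B) − x_B‖₁ + E‖G_B(x_A) − x_A‖₁`.
- **perceptual term** `L_pept = E‖φ(G_A(x_A)) − φ(x_B)‖₁` in the feature
  space of a fixed extractor φ. In paired mode x_B is the co-registered
  SD partner of x_A (supervised); in unpaired mode the term is disabled.

The three unconstrained weights default to `λ_cycle = 10, λ_idt = 5,
λ_pept = 1` (cycle-consistency-convention ratios); the desk-scale preset
uses `(1, 1, 30)` — see "Desk-scale preset" below.

### Architectures

The generators are residual U-Nets operating on single-channel
`[−1, 1]`-normalized slices. The encoder applies `n_down` stride-2 3×3
convolution stages (default 5, taking 256×256 to an 8×8 bottleneck;
channels double per stage from `base_channels = 64`, capped at 8×).
Each stage is conv → normalization (instance by default, batch
selectable) → LeakyReLU(0.2). The decoder applies `n_down`
transposed-convolution stages (zero-insertion upsampling followed by a
stride-1 3×3 convolution — an equivalent parameterization of a stride-2
transposed convolution); each junction concatenates the encoder skip at
that resolution and merges it with a 3×3 convolution. Residual blocks
(two 3×3 convolutions with ReLU and an additive skip; 4 by default) are
distributed round-robin over the up-to-three deepest skip junctions. A
final stride-1 refinement stage — the sixth "up" stage, which restores
no resolution but refines features — optionally concatenates the raw
input image (`concat_input`, on by default) before a 1-channel head and
a tanh output bound; the raw input is concatenated once more at the
head, so a direct linear path from input to output exists. Counting the
refinement stage as an upsampling stage is a deliberate reading: five
stride-2 upsamplings already restore 256×256, so a sixth
resolution-doubling stage cannot exist.

With `identity_init` (default on, effective when `concat_input` is on)
the head starts as a near-identity map: its weight on the input
channel's center tap is 1 and all feature weights are scaled by 0.01,
so an untrained generator computes ≈ `tanh(x)` ≈ `x` for
window-normalized intensities. Training then begins from "copy the
noisy input" — already at low-dose baseline quality — and only has to
learn the denoising correction. This removed the dominant failure mode
of small CPU-scale runs, where for some initializations a from-scratch
generator settled into lesion-amplitude-suppressing solutions it could
not escape within the epoch budget.

The critics are three-scale PatchGANs: the same stack (four spectrally
normalized stride-2 3×3 convolutions with LeakyReLU, then a spectrally
normalized 1-channel head) applied to the input and to one- and
twice-average-pooled copies. Score maps are unbounded (no sigmoid), as
Wasserstein critics require. Apart from spectral normalization the
critics carry no normalization layers — feature normalization interacts
badly with the per-sample gradient penalty. The scalar critic score used
in the Wasserstein terms is the mean over each score map, averaged
across scales; the fusion rule is a package choice.

### Differentiation engine

No GPU autodiff framework is used: `petcycle.autodiff` is a small
reverse-mode engine over numpy arrays whose vector-Jacobian products are
themselves built from taped primitives, so gradients are differentiable.
This matters for exactly one consumer: the gradient penalty, whose
parameter gradient contains mixed second derivatives
∂²D/∂θ∂x. Convolutions are im2col gathers plus batched BLAS matmuls;
layer parameters are float32 for CPU throughput. Gradient correctness is
pinned by central-difference tests, including a finite-difference check
of the double-backward path.

## Training

Adam with β₁ = 0.5, β₂ = 0.999 for all four networks, base learning
rate 1e-4, and a cosine-annealing warm-restart schedule: cycle lengths
T0, T0·Tmult, … (T0 = 10 epochs, Tmult = 2), rate restarting to the base
value at each cycle boundary and decaying to `min_lr = 0` (unstated
elsewhere; 0 chosen) by cosine within a cycle. Each step performs
`n_critic` critic updates (default 5) and one generator update. The
reference protocol trains for 60 epochs with batch size 32; "batch" is
the interpretation taken for the protocol's patch parameter, since
32×32 crops would collapse a five-stage encoder to 1×1.

Gradients of both updates are clipped to a global L2 norm of 5
(configurable): loss spikes are routine in adversarial training, and an
unclipped spike contaminates Adam's second moments for many subsequent
steps — on CPU-scale runs this was the dominant source of run-to-run
variance.

All randomness flows from one run seed through named, CRC-separated
streams (parameter init per network, gradient-penalty interpolates,
per-epoch data order), so runs are bit-reproducible on one platform and
each stream is independently replayable. Checkpoints carry the four
networks (parameters *and* buffers: spectral-norm power-iteration
vectors, batch-norm running statistics), both optimizers' moments, the
penalty RNG state and the full config; resuming from an epoch boundary
continues exactly as the uninterrupted run would have. The best
checkpoint is selected by validation PSNR (PSNR and SSIM are both
logged; one had to drive selection).

## Intensity handling

Physical intensities are body-weight SUV
(`concentration[kBq/mL] × weight[kg] / dose[MBq]`, 1 g/mL density,
decay correction assumed applied by the scanner). Network I/O uses a
fixed affine window mapping `[lo, hi]` SUV onto `[−1, 1]` with clipping,
shared across images so denormalized outputs remain quantitatively
comparable. The window dataclass defaults to `(0, 15)`.

Training presets deliberately widen the window to `(−15, 30)`: the
generator output is tanh-bounded, so values near the window edges live
in the saturating region — air (SUV 0) mapped to exactly −1 is
unreachable, and a lesion at SUV ≈ 13 mapped to ≈ 0.87 receives
amplitude gradients attenuated by `1 − tanh²`≈ 4×. With the wide window
every tissue value falls in the quasi-linear zone of the output
nonlinearity, which measurably removes a lesion-amplitude bias floor.
The cost — fewer normalized units per SUV — is irrelevant at float32
precision.

Reconstruction matrices larger than the network input (288×288 in the
reference protocol vs 256×256) are bilinearly resampled at pairing time;
center-cropping was rejected because it discards body margins.

## Synthetic phantoms

Patient data being unavailable, the simulator generates what the
acquisition protocol implies statistically: one activity map imaged at
two frame durations. A phantom is a piecewise-constant SUV map — an
elliptical body (background ≈ 0.8 SUV), an elliptical liver
(mean ≈ 2.5 SUV) and 1–3 hot disk lesions with peaks drawn from
5–14 SUV, radii 6–12 mm — convolved with a Gaussian PSF (6 mm FWHM at
2 mm pixels). These anchors reproduce the liver/lesion uptake ranges
reported for the clinical cohort the model family was developed on.
Geometry is jittered per phantom; all draws derive from the dataset
seed.

Acquisition is per-pixel Poisson counting *in image space after the
PSF*: expected counts are `SUV × counts_per_suv_standard ×
dose_fraction` with `counts_per_suv_standard = 50` per 150 s frame
(a free simulator parameter; no noise-equivalent-count figures exist to
pin it) and `dose_fraction = 30/150 = 0.2` for the low-dose frame.
Observed counts divided by the same factor put LD and SD on one SUV
scale with variance ratio 5:1.

**What the surrogate does not model, and what that implies.** Real
short-frame images are reconstructed through OSEM/TOF/PSF at low count
levels, which adds correlated noise and a systematic contrast bias
(clinically, low-dose lesion SUVmean under-reads by roughly 10%).
Image-space Poisson noise is *unbiased*: the LD image's expectation
equals the truth. Consequently an ROI mean over a 3 cm² lesion disk
(75 pixels at 2 mm) averages LD noise down to ≈ 0.09 SUV, making the
raw LD image a nearly perfect estimator of regional mean uptake — a
property real low-dose PET does not have. Passing PSNR/SSIM recovery on
these phantoms therefore says the translator denoises and preserves
structure; it cannot demonstrate the lesion-SUVmean-trend improvement
reported on patient data, because here there is no low-dose SUV bias to
correct. The desk-scale lesion-SUVmean check in the acceptance suite
fails for exactly this reason and is retained as a known-red limitation
rather than weakened; raising noise via `counts_per_suv_standard` does
not change the conclusion (the LD ROI mean stays unbiased).

## Evaluation

- **PSNR** `= 20 log10(MAX / √MSE)` with MAX the reference (SD or
  truth) image's peak — per-image, not a bit-depth constant — making the
  metric invariant to common rescaling.
- **SSIM**: luminance × contrast-structure product over Gaussian
  windows (11×11, σ = 1.5, k₁ = 0.01, k₂ = 0.03), dynamic range
  defaulting to the reference peak, edge windows cropped. The
  implementation is direct and is cross-checked against scikit-image in
  the test suite.
- **ROI SUV statistics**: SUVmax, SUVmean and population SD (ddof = 0;
  the convention is configurable) inside fixed-area circular ROIs
  (3 cm² default) centred on lesion centroids from the simulator's
  ground-truth masks — mirroring the clinical procedure of drawing ROIs
  on SD and transferring them to LD/denoised images. The pixelated disk
  takes exactly `round(area / pixel_area)` nearest pixel centers, since
  lattice thresholding undercounts small disks.
- **Aggregation**: mean ± range (range = max − min), per slice.

## Desk-scale preset and problem sizes

The test suite and acceptance run use `presets.DeskScale`: 64×64
phantoms, 25 phantoms × 8 slices = 200 LD/SD pairs (0.81/0.14/0.05
train/val/test), three downsampling stages (64 → 8 bottleneck), 8 base
channels, 2 residual blocks, 8-channel stride-1 random-conv perceptual
extractor, 8 epochs at batch 2, lr 3e-3 (single cosine cycle), one
critic update per generator update, weights `(λ_idt, λ_cycle, λ_pept) =
(1, 1, 30)`. These sizes keep a full simulate→train→evaluate cycle in
CPU minutes while preserving every structural element of the method:
both GAN directions, all four loss terms, spectral-norm critics with
gradient penalty, warm-restart scheduling. Under these conditions the
trained model beats the low-dose input against ground truth on held-out
phantoms by ≈ +5 dB PSNR and ≈ +0.11 SSIM.

The perceptual extractor of record is VGG-19 tapped at the 16th
convolutional layer (single-channel input replicated to RGB, ImageNet
standardization); it loads from a local `.npz` kernel archive and is
layer-indexing-configurable, since "16th convolutional layer" admits
more than one counting convention. When no such archive is present the
package uses a seeded random convolutional stack: a frozen random
convnet preserves image information while mixing local context, so L1
in its feature space behaves as a structure-aware image distance. All
shipped runs use the seeded extractor.

## Numerical and degenerate-input choices

- PSNR of identical images returns +inf and is excluded from aggregates.
- Gradient-penalty norms add 1e-12 under the square root; spectral-norm
  divisions add 1e-12 to σ.
- L1 losses use the sign subgradient (0 at 0).
- Largest-remainder rounding apportions dataset splits; ties go to the
  earlier split in (train, val, test) order.
- DICOM export stores 16-bit rescaled intensities (slope/intercept), so
  round-trips are exact to ~1e-3 of the intensity range; NIfTI
  round-trips are float32-exact.
- Resume is supported at epoch boundaries (data order is re-derived per
  epoch from the seed, so mid-epoch state never needs serializing).

## Known limitations

- The simulator's image-space noise model is unbiased by construction;
  see above for what that implies about SUV-trend claims.
- No attenuation, scatter, randoms, TOF or sinogram-domain modelling.
- Desk-scale training uses one critic update per generator step; the
  five-update WGAN convention is the default at paper scale.
- `unpaired` mode disables the perceptual term and has no held-out
  quality gate in the acceptance suite.
- Checkpoints are platform-reproducible, not cross-platform-bitwise.
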