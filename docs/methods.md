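# Methods

This note records the scientific model implemented by `hifutherm`, the
assumptions behind the synthetic data generator, and the numerical and
design choices made where the method description leaves the design open.

## Problem setting

High-intensity focused ultrasound (HIFU) therapy concentrates acoustic
energy into a millimetre-scale ellipsoidal focal zone, heating tissue to
coagulative necrosis (onset ≈ 52 °C). Treatment planning needs the focal
temperature *field* in real time, but the direct measurement device — a
thermocouple array — is invasive, and MR thermometry is too slow and
restrictive. The approach implemented here learns a mapping from
ultrasound-derived images to temperature: during training, three derived
modalities (B-mode/UBI, elastography/UEI, Doppler/UDI) are available
together with thermocouple readings; at inference only one modality (UBI)
is required.

## Teacher: multimodal knowledge extraction

Inputs are aligned patch sets `x*_m ∈ R^{S×H×W}` (default `H = W = 16`)
for `m = 1..M` modalities, labels `Y ∈ R^S` in °C.

1. **Encoders.** One MLP per modality with widths
   `H·W → c·H·W → c·H·W → d′` and ReLU after every affine map (a 4-layer
   network read as input, two hidden layers, output; the uniform recursion
   applies the activation to the output layer too, so embeddings are
   non-negative). Defaults `c = 2`, `d′ = 64`.
2. **Self-expressive layer.** A trainable `Z ∈ R^{S×S}` with `diag(Z)=0`
   enforced *structurally*: the diagonal is masked out of the
   parameterisation rather than penalised, so the constraint is exact at
   every step and the trivial identity solution is unreachable. Its loss is
   `λ₁‖Z‖²_F + λ₂ Σ_m ‖Z f_m − f_m‖²_F`.
3. **DCCA layer.** With `O_m = Z f_m`, the ridge projection
   `P_m = O_m (O_mᵀO_m + r_m I)⁻¹ O_mᵀ` is symmetric with spectrum in
   `[0, 1)` for `r_m > 0`; the aggregate `P = Σ_m P_m` is summed as-is (an
   orthogonality side-constraint on `P` cannot hold for such a sum and is
   deliberately not enforced or normalised away). The common space `D` is
   the top-`r` left singular factor of `P`; the DCCA loss is
   `l_d = −Σᵢ sᵢ`. Note the residual identity
   `Σ_m‖D − O_m R_m‖²_F = M·r − Tr(DᵀPD)` with
   `R_m = (O_mᵀO_m + r_m I)⁻¹O_mᵀD` holds exactly only as `r_m → 0`; for
   `r_m > 0` it carries a residual `Σ_m r_m‖(O_mᵀO_m + r_m I)⁻¹O_mᵀD‖²_F`.
   The test suite therefore checks the identity at a vanishing ridge
   (1e-10) and the structural spectrum properties at the working ridge.
4. **Head and total loss.** A single linear layer maps rows of `D` to
   temperature (the "projection mapping" is otherwise unspecified; linear
   is the simplest faithful choice). Total loss: the three terms above
   plus `λ₄·MSE`, λ defaults all 1.0.

**Differentiating through the SVD.** Each training step recomputes `D` by
SVD and holds it constant while the encoders, `Z`, and the head take one
Adam step. At fixed `D`, the gradient of `Tr(DᵀPD)` w.r.t. `O_m` is

    2 C O_m A⁻¹ − 2 O_m A⁻¹ O_mᵀ C O_m A⁻¹,   A = O_mᵀO_m + r_m I,  C = DDᵀ,

which for a simple spectrum coincides with the exact subgradient of the
singular-value sum (Danskin-type argument) while avoiding the instability
of SVD backpropagation near degenerate singular values. The formula is
verified against finite differences in the tests.

**Freezing.** After the last epoch, `Z` and `D` are recomputed once from
the final encoder state on the full training set, marked read-only, and
hashed; student training asserts the hash afterwards.

**Out-of-sample monitoring.** `Z` and `D` are training-set-sized, so
validation samples have no rows in them. For monitoring only, a validation
embedding is mapped into the common space by the per-modality ridge maps
`R_m` (skipping `Z`), averaged over modalities, and passed through the
head. This choice affects logging, never the trained parameters.

## Student: unimodal distillation

The frozen pair `(Z, D)` is combined — Hadamard product when shapes match,
matrix product `Z·D` otherwise (the only reading well-defined for all
`(S, r)`; the rule is configurable and never resolved silently when forced
to `elementwise`) — then passed through a width-3 same-padded 1-D
convolution along the feature axis, mean-pooled over samples, and linearly
resized to a length-`d′` prior vector. Since the source matrices are
fixed, the prior is a constant vector at inference: the distilled student
is a pure single-modality model. The student MLP is `H·W → c·H·W → d′`
(3-layer: one hidden layer), the head is linear on
`concat(MLP_t(x), prior)`, and the loss is MSE. Only the MLP, mapping
(conv + resize) and head update. An identically trained `distill=False`
ablation (zero prior, frozen mapping) quantifies the value of
distillation; its MAE is reported alongside, not asserted.

## Field reconstruction

Inference tiles a target-modality frame with 16 × 16 windows. A 90%
overlap implies stride 1.6 px, which is not realizable on an integer
grid; stride 2 (87.5% overlap) is the default and stride 1 is available.
Windows flush with each border are appended so every pixel is covered.
Overlapping scalar predictions are fused by the arithmetic mean over each
pixel's covering windows (uniform weighting chosen over distance weighting
for testability); the coverage map is returned, and
`Σ field·coverage = Σ prediction·window-area` holds exactly. Fields can be
min-max normalized to `[0, 1]` (constant fields map to zeros; the original
range is stored for inversion). Focal profiles are the row and column
through the field maximum (ties: first in row-major order),
cubic-spline-resampled at `interpolation_factor`-times finer pitch with
endpoints preserved, so every original pixel — including the maximum — is
sampled exactly.

## Synthetic data generator

The generator defines the study conditions; no public quantitative model
links these modalities to temperature, so its components are explicit
stand-ins with the statistical structure the learning method relies on.

* **Heat model.** `T(x, t) = T₀ + ΔT·G(x)·e(t)` with a Gaussian-ellipsoid
  footprint `G` (σ = 2.5 mm axial, 1.5 mm lateral — the semi-axes of the
  nominal 3 × 3 × 5 mm focal zone reduced to the axial–lateral imaging
  plane, the longer axis mapped to depth) and an envelope `e(t)` that rises
  as `1 − e^{−t/τ_heat}` while the transducer is on and decays as
  `e^{−t/τ_cool}` after it stops. This is the simplest model reproducing
  the sigmoidal heat-up and exponential cool-down of measured thermocouple
  traces; it ignores perfusion, nonlinear absorption and conduction
  anisotropy. The 200 ms native sampling interval matches the acquisition
  loop of the real system; desk-scale runs resample at 2 s (10×).
* **Probes.** Four virtual thermocouples 3 mm apart along the lateral
  axis, the first at the focal centre; readings are bilinear
  interpolations of the frames at the mm positions (probes sit at mm
  coordinates, not pixel centres), and this equality is exact by linearity.
* **Modalities.** Each modality applies a strictly monotone map of an
  effective temperature `v(T)` (identity below the 52 °C denaturation
  threshold, slope doubled above — a continuous stand-in for the altered
  echo response of necrotic tissue): affine (UBI-like), saturating tanh
  (UEI-like), accelerating exponential (UDI-like), plus i.i.d. Gaussian
  pixel noise. With zero noise each map is analytically invertible, which
  the tests exploit as an oracle. Optionally the UBI channel's pattern
  drifts axially while the field exceeds the threshold (saturating at
  `displacement_max_mm`), mimicking tissue displacement by coagulative
  necrosis.
* **Presets** (chosen once as realistic study conditions): *in vivo* —
  37 °C baseline, ΔT = 15 °C (peak at the 52 °C onset), heat 0–900 s, cool
  to 2500 s, τ = 200/300 s, noise σ = 0.02; *phantom* — 25 °C baseline,
  ΔT = 18 °C (no regime switch), heating-only 600 s, σ = 0.005; *in
  vitro* — 25 °C baseline, ΔT = 32 °C (well past the switch), 700 s
  heating of a 900 s run, displacement on, σ = 0.015. Noise is expressed
  on the unit-scale image intensities (σ = 0.02 ≈ 1 °C per-pixel
  equivalent on the UBI slope, far less after patch averaging).

**What passing tests do and do not show.** The synthetic modalities are
noisy monotone point transforms of the true field; they lack speckle,
attenuation, shadowing, scatterer decorrelation and motion. Held-out
errors here therefore validate the learning machinery, data plumbing and
reconstruction logic under controlled conditions — they do not certify
accuracy on clinical RF-derived images.

## Training scale and numerics

* Labels and patch intensities are standardized per modality using
  training-set statistics (stored in the artifacts; predictions are
  returned in °C). With Adam at the reference lr of 1e-3, regression on raw
  °C targets cannot move the initial head bias to body temperature within
  the step budget; standardization is the standard remedy.
* The `desk` profile subsamples frames to at most 500 patch samples,
  trains 20 epochs, and the teacher runs full-batch (the self-expressive
  and DCCA terms are defined over the full training set; the batch-16
  setting of the reference schedule is kept as metadata and used by the
  student's minibatching). The `full` profile keeps 80 epochs and batch
  16. All benchmark and acceptance runs use the desk profile.
* SVD sign convention: each column of `D` is flipped so its
  largest-magnitude entry is positive, making artifacts reproducible.
* Degenerate inputs: constant fields normalize to zeros and yield flat
  profiles with a warning; a singular scatter matrix at `r_m = 0` raises
  with guidance to set `r_m > 0`; non-finite losses abort naming the
  component; rendering without an explicit seed is an error.
* Default hyperparameters where the method description is silent:
  `c = 2`, `d′ = 64`, `r = min(32, S)`, `r_m = 1e-3` — small, stable
  values, all exposed in the configs.

## Known limitations

* The teacher's supervised head trains on `D` at fixed common space, so
  the label signal reaches the encoders only through the alternating DCCA
  update; with few full-batch epochs the teacher is a structural prior
  provider rather than an accurate regressor on its own.
* The distilled prior is constant across samples; its value lies in
  shaping the student's head/feature geometry, and on these synthetic
  conditions the measured advantage over the no-prior ablation is modest.
* 2D only: the imaging plane through the focus; no temporal fusion across
  frames; no raw-RF simulation or beamforming.
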