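# Methods

`slicereg` registers a 3D CT kidney volume to a 2D ultrasound (US) frame
sequence acquired during free breathing: for every US frame it finds the
rigid pose of the CT such that the CT's sagittal cutting plane matches the
frame ("sliced" 3D–2D registration — no projective geometry).  The kidney
is treated as rigid; it barely deforms under posture change and
respiration.

## Pipeline

1. **Feature networks** (`featurenet`).  Two 5-level residual U-Nets with
   local-binary-convolution (LBC) skip layers produce per-voxel kidney
   probability maps: one for CT volumes, one for windows of 5 consecutive
   US frames (US kidneys are hard to see in a single noisy frame; motion
   across a short window disambiguates them, so the US net consumes a
   256×192×5 stack and never downsamples the time axis).  Training
   minimises the negative soft set-Dice with Adam at learning rate 1e-4,
   batch size 1.
2. **Preprocessing** (`preprocess`).  Everything is brought to RAI
   orientation and an isotropic grid (0.8 mm in the full clinical profile); CT is
   cropped to 128×224×288 about its kidney-feature centroid; US frames are
   cropped in-plane to 224×288, windowed (Nw = 5, stride 1) and the window
   embedded at the RL centre of a zero 128×224×288 volume (frames at RL
   indices 62–66).  The CT is then translated so the kidney centroids of
   the two feature maps coincide (centroid pre-alignment).
3. **Registration network** (`regnet`).  The concatenated CT/US feature
   volumes pass through a stride-2 conv encoder (8, 16, 16 filters) and an
   upsampling decoder (16, 16, 16, 16, 8, 8 filters).  Four decoder scales
   (1/8, 1/4, 1/2, 1/1) each emit 6·Nw rigid parameters through a
   zero-initialised dense tanh head, so the untrained network performs an
   exact identity warp.  Per-scale predictions are merged by averaging
   rotations and weighted-summing translations with weights {8,4,2,1}/4
   (translations are predicted in the emitting scale's voxels, so a
   coarse voxel is worth proportionally more full-resolution
   displacement).  The decoder lists six convolution stages but only four
   combination weights; we emit at the four resolutions and treat the two
   extra finest-scale stages as refinement convolutions.
4. **FIM loss** (`losses`).  The unsupervised objective is
   `L = L_f + 0.01·L_i + 0.001·L_d`: a windowed Dice feature term on the
   probability maps (middle RL slice of the warped CT map vs each US
   frame's map), a MIND image term (mean absolute difference of 6-channel
   modality-independent neighbourhood descriptors on the middle slice, CT
   masked by its feature map before warping), and a motion term
   `0.01·‖D−I‖/Nw + 0.99·gradD` where `gradD` is the mean Frobenius norm
   of second differences of consecutive frame transforms — breathing
   motion should be smooth in time.
5. **Learning strategy** (`learning`).  Training pairs are generated by
   sampling rigid transforms parameter-by-parameter from Gaussians
   truncated at 2σ (rejection sampling, preserving the in-band shape) and
   applying their inverses to a reference-aligned CT.  The model is
   pretrained on such pairs, then adapted to each new sequence by
   "one-cycle transfer learning": exactly two further unsupervised epochs
   on the windows of the sequence's first breathing cycle (detected as
   the second zero crossing of the mean-centred IS centroid trajectory of
   the US feature maps) before inference on the remainder.

## Which Dice drives the feature loss

Two windowed Dice forms are implemented.  The *elementwise* form,
`mean(2xy/(x+y+ε))`, follows the printed definition and is the default of
`fim_loss`; the *set* form, `2Σxy/(Σx+Σy+ε)`, is the default of the
training loops.  The reason is a measurable defect of the elementwise
form as a registration objective: for fixed `y` it is monotonically
increasing in `x` wherever `y > 0` and indifferent where `y = 0`, so it
rewards *covering* the fixed kidney rather than matching it.  On desk
phantoms this bias is two orders of magnitude stronger than the MIND
term's counter-signal at λ₁ = 0.01, and the loss at the identity pose can
beat the loss at the true pose.  The set form's denominator penalises
excess mass and restores the true pose as the optimum (verified by
converged direct optimisation of the pose parameters, which lands within
a few degrees / a couple of mm of ground truth).

## Head choice and adaptation mode

The transform heads support two poolings.  Global average pooling is
cheap but its features are largely translation invariant — trained this
way the network's predictions are nearly input independent, as pooling
discards exactly the spatial information a translation regressor needs.
The `flatten` head (dense layer over the full feature map, the plausible
source of the architecture's very large parameter count) regresses pose
reliably and is the benchmark default.

One-cycle transfer exposes three trainable sets: all layers, heads only,
or head biases only.  All-layer adaptation of a flatten head is unstable
at useful learning rates: Adam steps are sign-coherent across the ~16k
dense inputs, so the raw tanh input moves by roughly `n_in · lr` per
step and saturates.  Head-only adaptation at a moderate rate is stable,
and — because the frozen trunk makes the head inputs constant per window
— those inputs are computed once and cached, making adaptation steps an
order of magnitude cheaper.  The same caching serves inference and an
optional second pretraining phase (`pretrain(..., trainable="heads")`).

## Conventions and numerical choices

* Axis order (RL, AP, IS); sagittal planes are constant-RL slices.  Euler
  angles are intrinsic rotations in order RL→AP→IS about the grid centre;
  the convention is isolated in two functions and configurable.
* `resample_rigid` uses pull-back sampling (`out(x) = in(T⁻¹x)`), voxel
  centres as grid points, zero fill outside the volume (the US window
  volume is itself zero-padded, so zero is the neutral background), and
  trilinear (or nearest) interpolation.  The same sampler backs the
  differentiable spatial-transformer path, so training and evaluation
  agree exactly.
* In the motion-loss matrices, translations are divided by a reference
  length (default: one voxel spacing) so rotation and translation entries
  are commensurate in the Frobenius norms.
* MIND: 3×3×3 patches, six face-neighbour displacements, variance
  `V(x)` = mean of the six patch distances floored at `1e-6 ×
  (dynamic range)²`, channels divided by their per-voxel maximum.  Two
  deliberate details: boundary samples are edge-replicated (a constant
  image then yields a unit descriptor everywhere), and inside the
  training loss the variance floor is computed from the *unwarped* masked
  CT — a warp-dependent floor would add an untracked term to the true
  objective's gradient.
* Image and feature losses only ever need warped values on the middle RL
  slice (plus a ±2 slab for MIND's 3D neighbourhoods), so the spatial
  transformer samples slabs rather than full volumes inside the loss.
* tanh head ranges: ±30° rotation; translation range in emitting-scale
  voxels (benchmark: ±4).

## Networks without a deep-learning framework

All networks, the spatial transformer and the losses run on a compact
reverse-mode automatic-differentiation core (`engine`) written on numpy:
broadcast-aware elementwise ops, im2col-based 3D convolution (with a
transposed-convolution fast path for stride-1 input gradients),
nearest-neighbour upsampling, differentiable trilinear volume sampling,
and Adam.  Gradients of every primitive are verified against central
finite differences in the test suite.

## Synthetic phantoms and what they do (not) show

No public paired 3D CT / 2D US kidney data exists, so the pipeline is
exercised end to end on phantoms (`phantom`): an ellipsoidal kidney
(default semi-axes 20×25×45 mm, mildly varied per "patient") with smooth
internal texture inside a darker background; breathing is a per-axis
sinusoid (defaults: translation amplitudes 0.5/1.5/5 mm RL/AP/IS,
rotations 2/0.5/0.5°) — the simplest periodic model with a dominant
inferior–superior excursion and a smaller anterior–posterior component.
US appearance applies a gamma remap (γ = 0.7, so CT and US intensities
are not linearly related and the multimodal machinery has real work to
do), Gaussian blur (σ = 0.6 px) and multiplicative log-normal speckle
(σ = 0.15).  Ground-truth poses are recorded exactly.

A geometric subtlety matters for pose recovery: a *pure* ellipsoid leaves
the sign of out-of-plane tilts unobservable from a single sagittal
cross-section (mirror symmetry in RL maps a +θ tilt onto −θ without
changing the centre slice), and even with the sign fixed the tilt
magnitude only enters through second-order foreshortening of the section.
Real kidneys are bean-shaped; `PhantomSpec.asymmetry` adds an off-axis
protrusion (off by default, on in the benchmark) that makes the full
pose identifiable in principle.  In practice large tilts remain the
method's weak direction: wrong-tilt poses can reproduce the observable
slice contour almost exactly (sub-millimetre contour distance at tens of
degrees of tilt error), so contour metrics saturate long before pose
metrics do.  Not emulated: acoustic shadowing, rib occlusion, organ
deformation, scan-conversion geometry.  Passing phantom tests shows the
machinery optimises correctly and recovers known poses under
multiplicative noise and a nonlinear intensity map — not clinical-grade
accuracy.

Misalignment magnitudes follow the small-transformation study group:
per-axis zero-mean Gaussians whose σ is chosen so the expected L2 norms
are ≈10.4° rotation and ≈3.7 mm translation (σ = L2/1.596, the mean of a
χ₃ distribution); a large-transformation variant (≈24.7°, ≈5.0 mm) is
also provided.  In the registration benchmark the feature maps are the
exact phantom masks softened by a half-voxel Gaussian — probability-map
stand-ins that decouple registration accuracy from segmentation quality
(the feature networks are trained and validated separately, on the
phantom overfit task).

## Desk profile and benchmark sizes

All grid dimensions divide by 4 relative to the full clinical profile
(32×56×72 voxels at 3.2 mm); feature-net filters scale to 4…64 and the
registration network to encoder 4, 8, 8 / decoder 8, 8, 8, 4, 2, 2 (the
full-resolution convolutions dominate CPU cost, hence the lean tail).
Benchmark defaults (`BenchmarkConfig`): 2 aligned reference phantoms,
40 generated training pairs, 12 pretraining epochs at learning rate
3e-3, breathing cycles of 40 frames (so one-cycle transfer sees 36
windows, 72 unsupervised steps at rate 1e-2 on the heads), and 10
misaligned test patients of 46 frames each.  Desk learning rates are
higher than the full-profile defaults (1e-4/3e-4) to match the much
smaller problem scale; every size is a configuration field.

## Known limitations

* Phantom ellipsoids are far simpler than real kidneys; contour metrics
  on them are optimistic, and out-of-plane tilt recovery is the weak
  direction (above).
* Rotation recovery depends on the transfer phase landing in the correct
  loss basin; with desk-scale pretraining the starting prediction is
  sometimes on the wrong side for large tilts, which caps the fraction
  of frames with small rotation error well below what contour metrics
  suggest.
* The respiration model is strictly periodic; drift and irregular
  breathing are untested.
* CPU-scale training budgets mean the benchmark measures "does the
  two-step strategy recover poses and improve over pretraining-only",
  not ceiling accuracy.
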