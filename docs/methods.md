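# Methods

This note documents the models, the defaults and the reasoning behind the
design choices; it is written for users who want to know what the package
computes and what passing its tests does and does not establish.

## Augmentation model

Training pairs are augmented on the fly so the network never sees the same
sample twice. The chain, in fixed order:

1. **Elastic deformation.** A coarse velocity field (default grid
   10x10x10x3) is drawn with i.i.d. Gaussian components, trilinearly
   upsampled to image size, and integrated by scaling-and-squaring
   (u <- u + u(x + u(x)), 7 steps after halving the field 7 times). The
   integration of a smooth stationary field yields an invertible
   (diffeomorphic) deformation: integrating the negated field gives the
   numerical inverse, and the composition of the two deviates from the
   identity by well under 0.05 voxel (mean) at realistic smoothness — the
   residual shrinks as the ratio of image size to coarse-grid size grows,
   i.e. as the per-voxel field gets smoother.
2. **Affine.** The product T·Rx·Ry·Rz·Shear·Scale with parameters uniform
   on configurable ranges (defaults: ±15° rotation, 0.85–1.15 scaling,
   ±0.1 shear, ±10 voxel translation), rotations about the volume centre.
   The factor order is a convention; the distribution widths are exposed in
   `AugmentConfig` because only the grid sizes, the flip probability and
   the crop size are canonical.
3. **Single resampling.** The elastic and affine transforms are composed
   into one target-to-source map x -> A·x + u(x) and applied in a single
   trilinear pass, to both the image and the one-hot label channels —
   repeated resampling would smooth the data twice. Outside the field of
   view the image takes 0 and the labels take background probability 1;
   with linear interpolation against those constant exteriors the label
   channels remain an exact partition of unity.
4. **Bias field.** exp of a trilinearly upsampled coarse Gaussian field
   (default grid 4³, log-σ drawn uniformly from [0, 0.3]), multiplied into
   the image: a smooth, strictly positive intensity inhomogeneity of the
   kind MR coils produce.
5. **Brightness/contrast.** out = gain·(v − mean) + mean + shift with gain
   uniform on [0.75, 1.25] and shift uniform on ±10% of the intensity
   range.
6. **Lateral flip** with probability 0.5; the left/right label channels are
   permuted by the taxonomy's involutive swap table.
7. **Crop** to 160³ by default, with the crop origin uniform among
   positions that keep the entire foreground bounding box inside — the
   structure of interest is never cut.
8. **Min–max normalisation** to [0, 1] (a constant image maps to zeros).

Noise scales (SVF σ, bias log-σ) are themselves drawn per sample from
[0, max], so the network sees a continuum from mild to strong corruption.

## Network and training

A standard 3-level 3D U-net: per level two 3x3x3 convolutions (conv →
batch norm → ELU), 24 features at the top, doubled after each 2³
max-pooling, halved after each 2³ transposed convolution, skip
concatenations, 1x1x1 head, softmax over 11 labels (background + 5
subunits x 2 sides). Same-padding keeps output and input grids equal;
prediction pads any input symmetrically to the pooling divisor and crops
back. Two convolutions per level and the conv→norm→activation order are
the conventional choices where several variants would be defensible.

The loss schedule addresses a real optimisation failure, which the
implementation reproduces if the schedule is disabled: from random weights
the mean-soft-Dice loss sits in a region of nearly flat gradients, and a
structure that collapses into a large false-positive blob has a
vanishingly small per-channel gradient (its denominator Σp² is huge while
the overlap is tiny). Training therefore starts with an SSD phase on the
pre-softmax activations, teaching the truncated network to output
+T_target on the correct channel and −T_target elsewhere, and only then
switches to 1 − mean SDC over all channels (background included; a config
flag excludes it). Two numerical points matter:

- **Optimiser reset at the phase switch.** The summed SSD loss and the
  Dice loss differ by ~7 orders of magnitude; ADAM's second-moment
  estimates carried across the switch suppress the Dice gradients almost
  completely. A fresh optimiser state at the switch restores the intended
  behaviour.
- **T_target and learning rate must let the SSD phase finish.** T_target
  is arbitrary in principle; in a short pre-training budget a smaller
  target (desk default 2.0, paper-scale default 5.0) and a learning rate
  large enough to traverse it are required, otherwise the Dice phase
  starts in exactly the flat region the pre-training was meant to avoid.

Defaults mirror the published schedule: ADAM, lr 1e-4, inverse-time decay
lr/(1 + 0.01·step), 100,000 steps with the first 5,000 on SSD, batch size
1, model selection by lowest validation Dice loss on un-augmented pairs,
and score-averaged evaluation over 5 training repeats. The **desk
profile** (`desk_profile(32)`) keeps the architecture family and schedule
shape but uses 32³ phantoms, 8 base features, 2,000 steps (200 SSD),
lr 3e-3, decay 1e-3, T_target 2 — it reaches whole-structure Dice ≥ 0.7 on
held-out phantoms in about ten CPU-minutes. Problem sizes in the test
suite (16³–32³ volumes, cohorts of 16–60, 30 null replicates) were chosen
so the full suite runs in tens of minutes on one CPU.

## Metrics

Hard Dice 2|X∩Y|/(|X|+|Y|) on binary masks; average boundary distance
(mean of the two directed mean nearest-neighbour distances between
surfaces) and Hausdorff distance (max of the two directed maxima).
Surfaces are the centres of mask voxels with at least one 6-neighbour
outside the mask (volume borders count as outside), scaled to mm — a
voxel-centre convention appropriate at ~1 mm resolution; sub-voxel surface
models are out of scope. Policies for degenerate inputs: Dice is 1 when
both masks are empty and 0 when exactly one is; distances on an empty mask
are undefined and flagged rather than silently zero, so an empty
prediction can never look perfect. "Whole" structures are unions of
subunit labels (bilateral, plus per-side unions).

## Volumetry

Volumes are integrated from the softmax output (Σ probability × voxel
volume), which retains partial-volume information that hard assignment
discards. Volumes are corrected for age and ICV by OLS regression over
all subjects jointly (the study groups share one model; fitting on
controls only would be an alternative), with the grand mean added back to
keep mm³ units. Cohen's d uses the pooled sample standard deviation
(n−1 variances); the t-test is pooled-variance, one-tailed in the
control > disease direction (the atrophy hypothesis). Raw p-values are
reported and the report records the number of tests run; no multiplicity
correction is applied.

## Phantoms

Each phantom is a brain sphere in empty background with two mirrored
ellipsoidal "hypothalami", each split into the five subunits by two
coronal planes (anterior/tubular/posterior thirds) and one axial plane
(superior/inferior halves of the anterior and tubular parts). Intensities
are per-class means plus Gaussian noise, lightly smoothed; the
structure-to-tissue contrast gap defaults to a small value because low
contrast is the defining difficulty of the real task. Atrophy removes the
outermost voxels of a subunit (ranked by ellipsoidal radius) down to a
requested volume fraction, so simulated effects are exact by construction.
Cohorts add per-subject scale jitter (±10%, which also drives the
simulated ICV), centre jitter, ages with a mild global age-atrophy slope,
and group-specific atrophy factors.

What the phantoms do *not* emulate: realistic cortical anatomy and
texture, partial-volume mixtures at boundaries, acquisition artefacts
beyond smooth bias and stationary noise, or inter-subject shape
variability beyond affine-like jitter. Passing the desk-scale learning and
atrophy-recovery tests therefore shows that the pipeline's mechanics —
augmentation, optimisation, metrics, statistics — work end to end; it does
not certify segmentation accuracy on clinical MRI.

## Known limitations

- The NumPy engine trains on a single CPU at desk scale; the paper-scale
  profile (160³ crops, 24 features, 100k steps) is expressed in the same
  configuration objects but is not practical without accelerator support.
- Batch size is fixed at 1 (as in the published schedule); batch norm
  therefore normalises over spatial statistics and keeps running averages
  for inference.
- `evaluate_repeats` is exercised for its contract (single-repeat
  identity, mean boundedness); the full 5-repeat variance-reduction
  experiment is not asserted in the suite for runtime reasons.
- No DICOM input, no resampling/registration, no multi-contrast (T2)
  support; label maps are assumed to share the image grid.
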