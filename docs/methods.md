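# Methods

## The quantity being measured

The pipeline quantifies how strongly two fluorescent stains co-occur in 3D
super-resolution (STED) stacks of brain endothelial cells grown on
Transwell polycarbonate filters — in the motivating application, an
α-synuclein stain (green, STAR ORANGE detection) against an endo-lysosomal
marker such as Rab7 or VPS35 (red, STAR RED detection), sampled at 40 or
60 nm in x, y and z.  The readout is a per-cell Pearson correlation
coefficient (PC): 1 for perfect colocalization, ~0 for none, −1 for
mutual exclusion.

Two properties of these data make a naive whole-stack PC misleading:

1. the polycarbonate filter fluoresces inhomogeneously, adding a smooth
   bright layer to *both* channels at the bottom of the stack, which by
   itself produces strongly positive correlation; and
2. the structures of interest are sparse sub-diffraction puncta, so
   correlating the raw volume dilutes their signal with empty voxels and
   out-of-focus light.

## The scoring procedure

For each channel independently:

1. **3D median filter**, 3×3×3 voxels, to suppress shot noise.
2. **Per-xz-slice background correction.**  For every y index, the 2D
   xz-slice is greyscale-eroded then dilated (a morphological opening)
   with a flat disk of radius 5 pixels (membership dx² + dz² ≤ r²).  By
   default the opening — an estimate of the locally smooth background — is
   subtracted from the slice (white top-hat), which removes the membrane
   autofluorescence exactly where it is smooth on scales larger than the
   disk while passing puncta smaller than the disk through unchanged.
   Replacing the slice by its opening is available as an explicit
   alternate mode (`replace_with_opening`), but that mode deletes
   sub-disk puncta and is not the default.  The opening alone cannot be
   the intended correction for punctate stains, since it would erase the
   very structures being correlated; subtracting it is the reading that
   preserves them.

Then, per cell (ROI):

3. **400-nm sectioning along y.**  The y axis is divided into consecutive
   intervals of `w = round(400 / pixel_size_y)` pixels; a final residual
   shorter than w/2 is merged into the last full interval, otherwise it
   stands alone.  At 40 nm pixels this gives exact 10-pixel sections; at
   60 nm, 7-pixel sections with the residual rule deciding the tail.
4. **Maximum-intensity projection** along y of the in-ROI voxels of each
   section, producing a pair of (z, x) images per section.  The ROI is
   applied *before* projection, so neighbouring cells cannot leak into a
   section's maxima.
5. **Pearson coefficient per section** over the projected pixels with at
   least one in-ROI voxel:

   p = Σ(R_i − R_av)(G_i − G_av) / sqrt( Σ(R_i − R_av)² · Σ(G_i − G_av)² )

   with R the red-channel and G the green-channel pixel intensities and
   R_av, G_av their section means.  Sections on which either channel is
   constant (zero denominator — e.g. empty after the top-hat) are
   *excluded and counted* rather than scored 0, because a zero-variance
   section carries no colocalization information and scoring it 0 would
   bias cell means toward zero.
6. **Per-cell score:** the unweighted mean of the section coefficients
   ("the mean for the slices"); a pixel-count-weighted mean is not the
   default but section pixel counts are reported so it can be formed.

Degenerate limit used as a self-check: with preprocessing disabled, a
whole-cell ROI and a single section spanning all of y, the per-cell score
equals the Pearson coefficient of the global y-MIPs exactly.

## Numerical and boundary choices

- Arrays are (z, y, x); pixel sizes are (x, y, z) in nm and converted from
  other units only at ingest; negative intensities are clipped to zero at
  ingest with a logged count.
- Both the median filter and the morphological operators reflect the
  array symmetrically across each boundary (edge sample repeated).  With
  a symmetric structuring element this keeps the opening exactly
  anti-extensive and idempotent, and avoids the artificial bright/dark
  rims a constant-pad would create in edge sections.
- "Disk size of five pixels" is interpreted as a *radius* of 5; the
  setting is exposed (`disk_radius`) because either reading is defensible.
- Section boundaries are voxel-aligned (no partial-voxel weighting); the
  residual rule above makes the partition deterministic.
- Pearson values are clamped to [−1, 1] against floating-point overshoot
  of order 1e-16; the clamp is inert on every oracle comparison.

## The synthetic-data generator

`simulate_stack` is the ground-truth oracle for the pipeline.  It renders,
in a fixed RNG order (red centers → pairing → green centers → membrane
field → noise) from a single seeded stream:

- **Puncta** as anisotropic Gaussian spots, lateral sd 50 nm and axial sd
  150 nm by default — a convenient stand-in for the STED point-spread
  function at 40–60 nm sampling; exact PSF shape is irrelevant to the
  scoring arithmetic being validated.  Default 60 puncta per channel in a
  32×128×128 stack at 40 nm pixels, peak amplitude 1000 counts.
- **Planted colocalization:** a fraction `f` of red puncta receive a green
  partner at the same position plus isotropic Gaussian jitter
  (default sd 20 nm, well below the PSF width, emulating two stains on
  one vesicular carrier).  Remaining green puncta are rejection-sampled
  at least 2·psf_sigma_lateral from every red center, so `f = 0` is a
  sharp spatial-independence(-plus-repulsion) baseline.  The planted
  pairing count is exactly `round(f · n_puncta_red)`.
- **Membrane autofluorescence:** a layer occupying z ∈ [0, 480 nm) in
  *both* channels, with intensity `mean · (1 + contrast · S(y, x))` where
  S is Gaussian-smoothed white noise scaled to zero mean and unit sd.
  Its lateral correlation length (autocorrelation half-maximum width,
  default 400 nm) sets the smoothing kernel via σ_k = L / (2√ln 2).  The
  layer is 12 voxels thick at 40 nm sampling — comfortably thicker than
  the radius-5 correction disk, as a real filter's autofluorescent band
  is thick relative to vesicular puncta.  No published numeric
  description of the autofluorescence exists, so mean 150, contrast 0.5
  and the 480 nm/400 nm scales are this package's own realistic choices,
  fixed once.
- **Noise:** per-voxel Poisson resampling of the rendered intensity plus
  additive Gaussian read noise (sd 5), clipped at zero.

What the generator does **not** emulate: depletion/optical-sectioning
physics, bleaching, drift, chromatic offset between channels, vesicle
size variation, or clustered (non-uniform) carrier placement.  Passing
recovery tests therefore demonstrate that the *scoring arithmetic* tracks
planted co-positioning under realistic noise and background — not that
any particular biological PC value is correct.

## Parameter recovery and the background-correction benefit

`run_recovery_experiment` simulates replicate stacks over a grid of
planted fractions and scores each stack twice: the full pipeline
(`pipeline_pc`, whole-volume ROI) and a naive whole-stack Pearson on raw
voxels (`naive_pc`).  At the default study conditions (10 replicates per
fraction, noise and membrane on) the mean pipeline PC rises strictly and
roughly linearly from ≈0.01 at f = 0 to ≈0.95 at f = 1, while the naive
score starts near 0.64 at f = 0 — the membrane layer alone accounts for
that offset, and the correction removes essentially all of it (see
`analysis/04_background_correction_benefit.py`).  Replicate seeds are
derived from one master seed via `numpy.random.SeedSequence`, making every
table reproducible byte-for-byte.

Problem sizes throughout (32×128×128 voxels, 60 puncta per channel,
10 replicates) were chosen as the smallest stacks that contain many
400-nm sections, a realistic puncta density and a resolvable membrane
layer; they run on a laptop-class single core in under a minute per
condition.

## Spot-based co-occurrence (stand-in)

The object-based score used alongside the PC (`spotcoloc`) is a
transparent reimplementation, not a reproduction of commercial spot
segmentation: Laplacian-of-Gaussian detection at the expected spot scale
(converted per axis to voxels), relative thresholding against the maximum
response, greedy merging of maxima closer than twice the spot scale, and
a directional co-occurrence fraction — the fraction of reference-channel
(by convention α-syn) spots with at least one partner within a physical
pairing radius in nm.  On noise-free simulations it recovers the planted
pairing fraction within ±0.1 using radius 3·jitter_sd + psf_sigma_lateral.
Its absolute values are not comparable to any proprietary software's
score axis.

## Transwell transport arithmetic

The ELISA helper fits an ordinary least-squares line to the standard
curve (a 4-parameter logistic is deliberately omitted: at the
bookkeeping level addressed here the assay is used in its linear range),
inverts it with a configurable extrapolation margin, and reports
transport as

  % transported = 100 · (acceptor_conc · acceptor_volume) / (added_conc · donor_volume)

referenced to the amount *added* to the donor compartment (100 nM in a
500 µL insert against a 1.5 mL well in the motivating assay).  A
mass-balance field (recovered / added) flags recoveries above 1.05 as
inconsistent input.  No correction is applied for sampling losses or
residual donor volume.

## Known limitations

- Cell delineation is an input (label image or polygon JSON), not a
  segmentation method; vendor ROI formats are unsupported.
- The per-section reading of "each slice" (score the 400-nm section MIPs,
  not individual xz-planes) follows directly from sectioning + projection
  preceding the coefficient; the alternative reading would make the
  projection step inert.
- Channels are preprocessed independently with identical parameters;
  no chromatic registration or per-channel tuning is attempted.
- The simulator's membrane parameters are free choices (see above); only
  relative comparisons against planted truth, not absolute PC values,
  should be read from synthetic results.
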