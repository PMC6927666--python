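# Methods

This note documents the models, parameter choices, numerical dialects and
known limitations of the two analysis pipelines and the synthetic-data
generators that verify them.

## PLA quantification

### Pipeline and assumptions

The punctum counter assumes diffraction-limited spots (Gaussian-like, σ of
order 1–2 px) on a smooth background, and nuclei that are bright, roughly
convex, and separable after watershedding.  The processing chain is fixed:

| stage | operation | parameter | default |
|---|---|---|---|
| nuclei | Gaussian blur | σ (px) | 2 |
| nuclei | Huang threshold | 256-bin histogram | — |
| nuclei | binary watershed | h-maxima depth (px) | 0.5 |
| nuclei | size filter | min area (px) | 200 |
| puncta | rolling ball | radius (px) | 50 |
| puncta | difference of Gaussians | σ (px) | 2 |
| puncta | isodata threshold | 256-bin histogram | — |
| puncta | binary median | radius (px) | 2 |
| puncta | size filter | min area (px) | 2 |

The nucleus minimum area (200 px) rejects debris at typical 63× sampling
(a 10 px-radius nucleus already covers ~314 px).  The punctum floor of 2 px
removes the single-pixel residuals the median filter can emit; it must not
be raised, because with a high auto-threshold (noise-free fields, where only
punctum pixels populate the histogram) genuine puncta legitimately shrink to
2 px after the majority filter.  Border-touching particles are excluded from
punctum counts: frame-edge objects are partial by construction, and
edge-replicated filtering of a gradient background leaves a thin strip at
the frame edge that would otherwise be counted.

A punctum is **nuclear** iff its centroid pixel (nearest-integer rounding)
carries a positive nucleus label; this containment rule makes the
nuclear/cytosolic counts an exact partition of the total.  An optional
nucleus-mask dilation (off by default) is exposed for sensitivity analyses.
The nuclear:cytosolic ratio is reported as undefined — not infinity — when
no cytosolic puncta exist.  Batch tables report counts per frame and per
nucleus, since frames may hold different numbers of cells.

### Threshold dialects

Both auto-thresholds operate on a 256-bin histogram spanning `[min, max]`
(native levels for 8-bit input); foreground is `pixel > threshold`.

* **Huang**: fuzzy-membership `1/(1 + |g − μ_class|/C)` with `C` the
  populated gray range, Shannon fuzzy entropy, exhaustive minimisation; ties
  resolve to the lowest candidate.  This is the Shannon-entropy Huang
  variant; the alternative "Huang2" dialect is not implemented.
* **Isodata (default dialect)**: an upward scan from the lowest populated
  bin that stops at the first index crossing of the intermeans midpoint
  `(mean(≤t) + mean(>t))/2` — the lowest intermeans fixed point, in bin
  index space, as the common desktop tool's default computes it.  The first
  and last histogram bins are excluded before iterating, so clipped or
  erased areas (e.g. the zero spike left by a clipped background
  subtraction) cannot drag the threshold into the noise floor; if trimming
  empties the histogram (two-valued images) the full histogram is used.

Constant images raise a degenerate-input error rather than returning an
arbitrary threshold.

### Rolling-ball background

The background is the grayscale **opening** with a spherical-cap structuring
element `b(y) = sqrt(R² − |y|²)`, computed exactly (no image shrinking) by a
vectorised min/max scan over the cap footprint with edge replication; it is
bit-identical to `scipy.ndimage` grey opening with the same non-flat
structure and several times faster at radius 50.  Note that a non-flat
opening commutes with additive offsets but *not* with intensity scaling —
the subtraction result is DC-invariant, not scale-equivariant.

### Watershed

Binary watershed: Euclidean distance transform inside the foreground,
regional maxima after h-maxima suppression (depth 0.5 px, configurable) as
seeds, flooding of the inverted distance map with 8-connectivity.  Every
foreground pixel receives exactly one label; components whose maxima were
all suppressed keep one label each so foreground area is conserved.

### Spreading area

Cell spreading is measured as blur (σ = 2) → Huang threshold → hole filling
→ particle areas, excluding border-touching cells.  The threshold sits low
on the blurred edge, adding roughly one pixel of radius per cell; for
realistically sized spreading cells (radius ≳ 100 px at high-magnification
sampling) this halo stays below 2% of area, and fold-change comparisons
between conditions are accurate to a few percent.

## AFM force spectroscopy

### Units and calibration

`z` in nm (increasing toward the sample), deflection in V (or nm with
sensitivity 1), spring constant k in N/m, force in nN, moduli in Pa
(1 nN/nm² = 1 GPa).  Deflection sensitivity (nm/V) is the inverse contact
slope of a curve on a rigid substrate, with the contact region auto-selected
as the samples in the upper half of the deflection range; a non-linear
contact region or a flat trace raises a calibration error.  Spring constants
are taken as metadata (thermal calibration is instrument-side).

### Baseline and contact point

The non-contact baseline (default: the 30% of samples farthest from the
sample) is fitted linearly and subtracted; a quadratic check flags curves
with no free-of-contact region.  Contact is detected as the first deflection
excursion above 3× the baseline noise SD that persists for 10 samples
(both configurable), then refined by back-extrapolating a linear fit of
`F^(1/q)` against tip-sample separation to zero force, where `q` is the
contact-law exponent (3/2 for spheres, 2 for cones).  The transform is
exactly linear in separation for the matching geometry, so on noiseless
curves the refined contact is exact, and using the whole contact region
minimises extrapolation variance on noisy curves — with soft samples the
threshold crossing can sit tens of nm past true contact, and a short
extrapolation window would bias moduli upward severalfold.

### Elasticity fits

Both fits are ordinary least squares through the origin on the linearized
law (`F^(2/3)` vs δ for spheres, `F` vs δ² for cones), over
`0 < δ ≤ fit_depth`.  Defaults: 50 nm for spherical CFS (small-deformation
bound, ~10% of a colloidal probe's radius is far larger); the full
indentation range for QI cones (the acquisition's 2 nN load limit bounds the
depth).  At least 5 in-range samples are required; non-positive slopes raise
fit errors; maximum in-range indentation below 0.5 nm (sub-resolution) is
reported as "not indentable" rather than returning a meaningless huge
modulus.  An optional free-intercept fit exists for diagnostics but is not
the default (the contact laws have no intercept).  The cone half-angle has
no silent default — it must be supplied (quoted half-angles for common
sharp biological probes are of order 15–25°).

CFS fits use the approach segment, QI the retract segment (both
configurable; analysis routines only require monotone z and reorder
internally).  QI reconstruction is per-pixel independent and
order-invariant; failed pixels are NaN in both stiffness and height maps,
never zero, so map statistics are unbiased.  Group summaries report mean,
SD, median and n of E, with mean/median ratios relative to the first group.

## Synthetic data

The generators emulate what the pipelines key on, not photorealism:

* **PLA scenes** (default 256×256 px): 12 axis-aligned elliptical nuclei
  (radii 10–16 px, intensity 120) blurred with σ = 3 px to emulate optics;
  15 nuclear + 25 cytosolic Gaussian puncta (σ = 1.5 px, peak 100 = 5× the
  background base of 20) on a planar background gradient; optional additive
  Gaussian noise (Poisson available).  Nuclear puncta are placed within 75%
  of a nucleus's axes; cytosolic puncta at least `3σ_blur + 2` px outside
  every nucleus ellipse, because the thresholded nucleus mask extends a few
  pixels beyond the true ellipse on the blurred skirt; nuclei keep a
  `4σ_blur + 2` px gap so their skirts never merge.  Placement is rejection
  sampling with a 10,000-attempt cap.
* **Force curves**: pre-contact linear baseline; post-contact force from the
  sphere or cone law solved self-consistently with cantilever bending
  (`z − z₀ = δ + F/k`, scalar root found to 1e-9 nm), truncated at the
  maximum load (1 nN CFS / 2 nN QI defaults); additive force noise with SD
  proportional to the maximum force, or a multiplicative variant with SD
  proportional to the local force.  Defaults mirror a colloidal acquisition:
  R = 11,500 nm, ν = 0.5, k = 0.03 N/m, sensitivity 50 nm/V, 2 nm sampling.
* **QI grids**: one curve per pixel with pixel-wise modulus and optional
  contact-height topography; per-pixel seeds are splitmix-mixed from
  (base seed, row, col), keeping pixels independent and reproducible.

Every generator is a pure function of its spec including the seed.  What
passing tests show — and what they do not: recovery on these scenes
validates the algorithmic chain (segmentation, detection, partition,
calibration, contact, fitting) against exact truth; it does not certify
performance on real micrographs with textured cytoplasmic autofluorescence,
clustered puncta, or viscoelastic, drifting force curves, none of which are
modelled.

## Problem sizes and tolerances

The test suite runs desk-scale problems: 256×256 scenes (20 noisy seeds for
the recovery study), 30 force curves per condition, 16×16 QI grids, 50
synthetic cells per spreading condition.  Oracle comparisons use exact
equality for histogram thresholds and component counts, 1e-6 absolute for
separable-convolution parity, 1e-9 for the ball opening, and 0.1–0.5%
relative for noiseless elasticity recovery.  The acceptance script
(`scripts/acceptance.py`) reruns the two fold-change experiments at these
sizes in a few seconds.

## Known limitations

* No 3D morphology, colocalization beyond the nuclear/cytosolic split, or
  per-cell assignment of cytosolic puncta to their parent cell.
* At punctum signal-to-noise near 5, the intermeans threshold sits about
  one noise SD above background and occasional two-pixel noise clusters
  survive the median filter; compartment count errors of a few percent are
  then expected even with the published parameters.
* No vendor binary formats; no viscoelastic, bottom-effect-corrected or
  tip-deconvolved contact models; k and sensitivity are trusted metadata.
* The linearized fits assume the printed contact laws hold over the fit
  range; depth-dependent stiffening shows up only in the r² diagnostic.
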