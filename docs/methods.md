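# Methods

This note documents the models behind `mitoquant`'s synthetic generators
and quantifiers, the parameters that matter, the numerical choices, and
what the test suite does and does not establish about real data.

## Scope and design

The package quantifies single-organelle and well-level readouts from a
mitochondrial transplantation workflow. The image analysis assumes
stationary fields (the dish is not moved between frames), so no motion
tracking or drift correction is performed; positions detected on the
reference frame are reused across the whole acquisition.

All intensities are in arbitrary units. No absolute intensity scale is
meaningful anywhere in the pipeline: every decision rule is a ratio or a
difference of ratios (fractional calcein drop, blank-normalised
transmittance, TMRE-over-background, I_cell/I_mit), and the tests verify
the corresponding scale invariances explicitly.

## Synthetic image model

**Fluorescent spots.** A mitochondrion (or intracellular punctum) is a
2-D Gaussian whose FWHM equals the particle diameter — a deliberate
simplification of the microscope PSF convolved with a sub-resolution
object. Each discrete kernel is renormalised to unit sum over its
truncated support (3.5 σ), so a particle with amplitude *A* contributes
exactly *A* integrated counts wherever its sub-pixel centre falls. This
makes integrated-intensity estimators exactly invertible and is the
basis of all zero-noise recovery tests. Consequences: peak brightness
falls as 1/d² at constant amplitude, and there is deliberately no
photon-counting (Poisson) statistics — noise is additive Gaussian with
configurable SD, plus optional per-object amplitude dispersion
(`intensity_cv`) modelling biological heterogeneity in dye loading or
GFP content.

**Calcein release.** MPT appears as a single-frame step loss of a
specified fraction of the spot amplitude ("abrupt" release); a linear
`ramp` mode with the same total loss serves as the negative control that
the per-interval rule must ignore. The Ca²⁺ trigger is added at t =
5 min, between the 4- and 6-min frames, so generated events occur only
at frames ≥ 6 min. Defaults follow the acquisition protocol the rules
were designed for: 11 frames at 2-min intervals, 0.325 µm/pixel (20×
objective with 2×2 binning — the camera pixel size is not part of the
protocol, so a typical value was chosen and is configurable).

**Transmitted-light z-stacks.** A particle attenuates a uniform
illumination field (I₀ = 1000 a.u.) with a radially symmetric opacity
profile: a flat core of the requested transmittance (radius 0.75 r) and
a cosine rim (width 0.45 r), scaled along z by a Gaussian defocus
envelope (σ = 0.6 µm) centred on a per-particle focus slice. The flat
core guarantees that the darkest fixed-area region read by the
quantifier returns the requested transmittance exactly at zero noise —
provided the averaging square (side √0.46 µm ≈ 0.68 µm, i.e. 4 px at
the 40× pixel size of 0.1625 µm) fits inside the core, which holds for
particles ≳ 1.4 µm. The swelling presets therefore use 1.5–3 µm
particles. Swelling raises the core transmittance from baseline to its
post value as a step at the onset time; stacks are acquired at 0 and
10 min by default.

**Cell fields.** Cells are convex polygons (convex hull of 12 jittered
radial vertices, radius ≈ 12 µm) with uniform autofluorescence over a
flat background — sufficient for integrated-intensity estimators, not a
morphological model. Implanted GFP puncta and free extracellular
particles share one amplitude distribution so the counting estimator is
unbiased by construction. Placement enforces separations such that a
measurement window around any particle (bounding box padded by the
render-kernel radius, corners included) contains no other object's
support and no cell interior; a manifest-recorded puncta-free disk
inside each cell guarantees a valid background region exists. The TMRE
channel renders polarized objects only; by default free mitochondria
are polarized and internalized puncta are not, reflecting the
observation that internalized mitochondria lack membrane potential.

**Plate tables.** Wells are Gaussian draws around per-condition true
means; count-type assays are rounded to whole cells when noisy. The
generator emits a tidy table (well, condition, replicate, assay, value)
plus the truth table.

**Determinism.** Every generator draws all randomness from one
`numpy.random.Generator` seeded by the config; identical seed + config
reproduce outputs byte-for-byte, including written TIFFs.

## Quantifiers

**Detection.** Connected components above a threshold (Otsu by default;
the pipeline uses a robust alternative: median + max(5 MAD-sigmas, 10%
of the peak excursion), which behaves sensibly on zero-noise renders
where Otsu's bimodality assumption degenerates). Particle size is the
equivalent diameter of the half-maximum contour, which matches the
generator's FWHM definition to about a pixel; the 0.5–3 µm gate is
inclusive at both ends. Coordinates are 0-based, row-major, pixel
centres.

**Traces and cell fluorescence.** Integrated intensity over the ROI
minus mean blank (an adjacent annulus excluding all detections) times
the ROI area. Adding any constant offset to an image leaves all outputs
unchanged. Negative background-subtracted totals are clipped to zero
and flagged. Free-particle calibration intensities are measured over
padded bounding boxes (capturing the full blur) against annulus
backgrounds placed beyond every kernel's support — a global median
background would be biased upward by the blur tails themselves. For
per-cell GFP totals, the background region is the punctum-free part of
the same cell (detected puncta dilated by the kernel radius, plus a
4-sigma robust intensity cut against merged or missed puncta); the
annotated puncta-free disk is the fallback when little area remains.
Maximising the background area matters because background error is
amplified by the full cell area.

**Decision thresholds.** The MPT rule reads "decreased by more than 20%
of its initial value within any 2-min interval" as a per-consecutive-
frame drop exceeding 0.2 · F(0); anchoring to the current frame's value
instead is available via `mpt_relative_to="current"`. The transmittance
computation applies a single minimum over slices of blank-normalised
darkest-region means — the slice-minimum and ratio-minimum formulations
coincide here because the blank is per-slice. Swelling uses the
absolute change from baseline (the generator produces increases, but
the rule is sign-free). The polarization ratio threshold (default 2.0)
is a free parameter with no canonical value; cohort-level results are
validated by manifest recovery, not by the absolute threshold. The ETC
response is mean(frames after the malate frame) − mean(frames before
it), skipping the addition frame itself to avoid the mixing transient,
normalized to an untreated control set to 100.

**Internalization.** Counts are reported as real numbers; cohort means
like "6–8 per cell" are fractional by nature. Calibration warns below
50 particles. Colocalization calls a GFP punctum polarized when more
than 50% (configurable) of its area overlaps TMRE-positive regions.

## Statistics

One-way fixed-effects ANOVA (the classical F test; the two-tailed
phrasing of the protocol is interpreted as this standard test, since
the variance-ratio test is inherently one-sided on its own scale). SNK
uses the studentized-range distribution from `scipy.stats`
(numerically integrated CDF, tolerance ≤ 1e-6); critical values
reproduce the standard published q tables to two decimals. Unequal
group sizes use the harmonic-mean (Kramer) denominator. The stepwise
gate declares a range untested-and-non-significant when any enclosing
range failed; under the complete null only the widest range is tested,
so the familywise error equals α — verified by Monte Carlo. With two
groups the procedure reduces exactly to the two-sided pooled t test at
level α (q = |t|·√2). Report annotations grade pairs by re-testing at
α and α/5 (the procedure yields decisions, not exact p values).

## Problem sizes

Image experiments default to 3 replicate simulations of 50 mitochondria
(256²–512² fields) per condition; uptake fields hold 10 cells and 55
calibration particles; Monte-Carlo nulls use 1000–2000 replicates of
3–4 groups × 6 observations. These sizes match the cohort sizes the
procedures were designed around while keeping a full run of the suite
and the acceptance script in the minutes range.

## What passing tests show — and what they do not

Zero-noise recovery tests show the estimators invert the generator's
forward model exactly; noisy-recovery tests show cohort fractions stay
within binomial sampling error and count bias stays under the imposed
intensity dispersion. None of this certifies performance on real
micrographs, where PSF structure, uneven illumination, photobleaching,
moving or overlapping organelles, autofluorescence texture and
segmentation ambiguity all exceed the generator's assumptions. The
synthetic model validates the arithmetic and decision logic of the
procedures, not their robustness to real-world imaging artefacts.

## Known limitations

* No optical realism: no Poisson noise, aberrations, photobleaching or
  3-D PSF; defocus only rescales attenuation depth.
* Transmittance inversion is exact only for particles ≳ 1.4 µm at the
  40× pixel size; smaller particles are rendered but recovered with
  pixelization error.
* Cell segmentation is out of scope: cell outlines come from the
  experiment annotation (manifest), only particles are detected.
* One-way ANOVA only; condition × experiment two-way designs are not
  modelled.
* EIPA inhibition and treatment timing are experimental metadata; the
  estimators themselves are time-agnostic.
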