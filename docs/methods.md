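# Methods

This note documents the models, parameter choices and numerical details
behind `cytoborder`, and what the synthetic test material does and does
not establish about real histology.

## Synthetic histology

**What is emulated.** A section is a cortical ribbon between an outer
(layer I/II) and an inner (layer VI/white matter) contour. Six laminar
bands occupy fixed fractions of the local cortical depth; each band has a
target cell-body coverage (area fraction) in [0, 1]. Cell bodies are
rendered as dark anti-aliased disks (intensity 0.1) on a light background
(0.9) with additive Gaussian noise (σ = 0.02) — contrasts chosen so that
Otsu segmentation is unambiguous while still being exercised. Areas own
consecutive arc-length intervals of the outer contour; a pixel belongs to
the area of its nearest outer-contour point, and its laminar position is
the normalized distance ratio d_outer/(d_outer + d_inner) computed by
Euclidean distance transforms. Serial sections share contours; their true
border positions jitter independently and uniformly within a configurable
±range.

**Disk placement.** Disks are placed by a Boolean (Poisson germ–grain)
model: germ intensity λ is solved from the target coverage ρ via
ρ = 1 − exp(−λπE[R²]), with disk radii N(5 µm, 1 µm) truncated at 30 % of
the mean. This makes the expected foreground fraction of a homogeneous
band *exactly* the specified density, which the tests verify to ±0.03.
We deliberately use this instead of minimum-distance (Poisson-disk)
placement: the Boolean model has a closed-form coverage, renders fully
vectorized, and reproduces the granular texture the GLI thresholding
needs. Somata morphology, staining artifacts, tissue tears and 3D
reconstruction are *not* modelled.

**Cohorts.** Label volumes are ellipsoidal blobs per area, perturbed
around a common template (centre jitter SD = `area_shape_variability`
voxels, log-normal radius jitter), painted in area-id order; sexes
alternate M/F giving the 5/5 design at n = 10. Fresh volumes are
N(1.25 × 10⁶, 1.2 × 10⁵) mm³; shrinkage factors are uniform in
[1.5, 2.5] and processed = fresh/factor.

**Scale of the study conditions.** Simulation studies use a flat ribbon
2400 µm wide and 600 µm deep at 3 µm/px with 8-px GLI fields and 90
traverses (profile spacing ≈ 26.7 µm), i.e. a ribbon thinner than real
cortex but with the same *relative* laminar geometry. The border
statistics operate on depth-normalized profiles and are invariant to this
scaling; the package defaults remain at the histological scale
(1.02 µm/px, 16-px fields). Monte-Carlo studies use 300 null stacks of 3
sections and 200 two-area stacks of 5 sections.

**What passing tests do and do not show.** The synthetic material has
i.i.d. noise between profiles, piecewise-constant laminar bands, and
abrupt areal transitions. Real sections have spatially correlated
staining variation, curved and variable-thickness cortex, and gradual
transitions; the error rates measured here are therefore best-case
calibrations of the statistical machinery, not guarantees for real
material.

## GLI mapping

Foreground = pixels darker than the threshold (cell-body stains are
dark-on-light). Default thresholding is Otsu on the intensity histogram;
a fixed threshold is available and recorded for provenance. GLI fields
are non-overlapping squares; trailing partial fields are discarded (the
simplest contract consistent with "measuring field" semantics). Values
are fractions in [0, 1], never percent. The exact conservation identity
mean(GLI) × n_fields × field² = foreground count of the covered region
holds by construction and is asserted in the tests. Any constant offset
between this segmentation and the original in-house binarization is
irrelevant to border detection, which compares profiles with each other.

## Potential field and traverses

The Laplace problem is solved on a regular grid (default resolution a few
µm, configurable) with Dirichlet values 0/1 on the rasterized contours.
The lateral open ends of a mapped region receive reflecting (zero-flux)
boundaries, realised by averaging over in-mask neighbours only; this
avoids artificial field distortion at region cut lines. The solver is
red–black successive over-relaxation with ω = 1.9, iterated until the
largest update per sweep falls below `tol` (default 10⁻⁵; non-convergence
at `max_iter` is flagged). Streamlines are integrated with a fixed-step
midpoint scheme (step = grid_res/2) on the normalized gradient,
terminating at φ ≥ 0.999; traverses whose gradient vanishes or that exit
the ribbon are excluded with a warning and the remainder re-indexed
gap-free. Closed-form checks: parallel plates (linear φ, straight
traverses of length d) and an annulus (log-radial φ within 2 %, radial
traverses of length r₁ − r₀ within 2 grid cells).

## Profiles and features

Profiles sample the GLI raster bilinearly at 101 equal arc-length
positions (0–100 % depth). The ten features treat y(x) as a weight
distribution over depth — the centre of gravity is only meaningful under
depth weighting — with s = 0 profiles assigned g₁ = g₂ = 0 by convention.
Derivative features use the absolute first derivative from central
differences (one-sided at the ends); a `signed` switch exists because the
original convention is not published, but `absolute` is the default and
the tested path. A constant profile has an identically zero derivative;
its derivative features fall back to (0, 50, 0, 0, 0). Before distance
computation the feature matrix is z-scored across the section's profiles:
features have incommensurate units, and pooled-covariance weighting alone
does not fix cross-feature scale pathologies in small blocks.

## Border detection

Block sizes span 12–30 profiles (both bounds configurable; the
published descriptions also mention a 20–30 range, reachable through the
same parameter). For each block size, every position's pooled covariance
is shrunk toward its diagonal with the smallest λ ∈ {0, 10⁻⁴, 10⁻³,
10⁻²} that brings the condition number below 10⁸ (λ recorded); a
covariance still singular after maximal shrinkage is an error, not a
silent fallback. α = 0.001 is interpreted as the family-wise level per
block size and Bonferroni-divided by the number of tested positions — the
conservative reading; dividing additionally by the number of block sizes
is not assumed. Local maxima use a ±2 window, require a strictly smaller
neighbour within the window (a flat stretch is not a peak) and resolve
plateaus to the leftmost index. Cross-scale acceptance clusters candidate
positions by single linkage at 4 profiles and requires ≥ 3 distinct block
sizes; cross-section acceptance chains candidates through *adjacent*
sections (a gap breaks the chain) and requires ≥ 3 sections.

The cross-section matching tolerance defaults to 6 profile spacings, from
an a-priori error budget: with border jitter up to ±2 profiles per
section, true positions of adjacent sections can differ by 4 profiles,
plus ~2 profiles of localization noise at the smallest block sizes.
Chain–candidate matching is one-to-one, closest pairs first, so a distant
candidate cannot steal a chain from a nearer one.

Measured behaviour under the study conditions (seeded, recomputed by the
test suite and `scripts/acceptance.py`): the end-to-end accepted-border
rate on null stacks is ≤ 1 % (in practice 0), and on two-area stacks with
layer-IV contrast 0.2 vs 0.6 the border is recovered within ±10 profiles
in ≥ 95 % of runs with ≥ 90 % of runs free of spurious borders.

## Atlas maps

Probability maps are exact subject-count fractions k/N. The MPM winner is
the area with the highest probability strictly above the threshold
(default 0); ties are broken by the higher mean probability over the
26-neighbourhood, then by the lower area id, and both tie classes are
counted in the result. The published refinements of MPM construction
(e.g. threshold logic against areas outside the map) are not reproduced.
Voxel convention everywhere: 0-based indices, world mm =
(index + 0.5) × voxel size. Registration to reference templates is out of
scope; cohort volumes share one synthetic space, and space ids are
carried so registered data could be dropped in.

## Volumetry and ANOVA

Cavalieri volumes use Σ(area × spacing) with a scalar spacing (default
1.2 mm) or explicit per-section distances; mixed spacing without explicit
distances is an error. Shrinkage factors are fresh/processed volume
ratios. Group aggregates use sample SDs (n − 1) and half-away-from-zero
integer rounding for comparison with printed tables. Two printed cells of
the packaged volume table (the male-left SFS1 and MFG1 means, 400 and
731) do not recompute from their own printed per-brain entries (401 and
729 result); they are flagged in the tests as rounding artifacts of the
published table
and excluded from exact checks. Whole-brain volumes are not published, so
normalized-volume significance values are validated by simulation and
oracle rather than reproduced; whether normalization should use fresh MRI
or histological volume is left as a caller choice (both fields are in the
cohort fixtures).

The split-plot ANOVA decomposes sums of squares from cell means: the
between factor is tested against subjects-within-groups, each within
effect (and its interaction with the between factor) against its own
effect-by-subject stratum; partial η² = SS_eff/(SS_eff + SS_err).
Unbalanced designs are rejected. Degenerate strata (SS below 10⁻¹² of the
total, i.e. float noise on constant data) yield F = 0. Sphericity
correction is off by default; a Greenhouse–Geisser option exists for
designs where the assumption is doubtful. The implementation is cross-validated against R's `aov` with
an `Error(subject/(area*hemi))` stratum, against pingouin on the
one-within reduction, and by a 2000-run type-I calibration (rate in
[0.03, 0.07] at α = 0.05).

One power check deserves a note: for a between-subject effect of exactly
d = 2 with 5 subjects per group, the exact noncentral-t power of the sex
main effect at α = 0.05 is 0.7905; the test asserts agreement with this
closed form rather than a round 80 %.

## Clustering and discriminant analysis

Ward clustering is performed on (by default) z-scored feature vectors;
reported heights are the merge cost — the increase in within-cluster sum
of squares — rather than scipy's √(2·cost) distance scale, because
conventions differ across packages and the merge cost is the quantity the
Ward criterion minimizes. Equality with an exhaustive greedy enumeration
is asserted on small fixtures. The canonical discriminant solves the
generalized eigenproblem S_b v = λ S_w v (within-scatter shrinkage ladder
as above), returns at most min(classes − 1, 2) axes orthogonal under the
within metric, and flags a degenerate between-scatter; it is descriptive
(projection and centroids), with no classification accuracy claimed.

## Known limitations

- The generator's areas are only loosely inspired by qualitative laminar
  contrasts of the mapped region; no quantitative laminar densities are
  published, so no claim of per-area fidelity is made.
- Sections are processed independently; there is no 3D traverse
  computation or histology reconstruction.
- The published stereotaxic coordinates and dendrogram cannot be
  reproduced without the original registered maps and profiles; the
  corresponding modules are validated by construction-based ground truth
  and closed-form oracles instead.
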