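# Methods

This note records the models behind `periomorph`, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do and
do not establish about real histology.

## Calibration

All physical quantities derive from one calibration: the pixel **area**
(default 17.43 μm²/px). The pixel edge length is computed as
√(area) ≈ 4.175 μm and never stored independently; quoted edge lengths such
as "≈ 4.18 μm" for the 1-px dilation are treated as rounded derived values.
This keeps a single source of truth for scale.

## Zone geometry

The peri-implant band is the set of pixels outside the implant whose exact
Euclidean distance (pixel centre to pixel centre, via a distance transform)
to the nearest implant pixel is below 300 μm, intersected with the trephine
defect. Iterated dilation is deliberately not used: 100 μm ≈ 23.95 px at
the default calibration is a non-integer number of pixel widths, and
dilation counting would quantise the three layers.

Partition conventions, chosen where the underlying protocol is open:

- **Layers** use half-open bins [0, 100), [100, 200), [200, 300) μm, so
  boundary ties are deterministic and no pixel belongs to two layers.
- **Sides** split at the implant's principal axis (PCA of implant pixel
  coordinates). The disc cross-section is an elongated trapezoid, so "both
  sides" means the two long faces; pixels beyond the short ends are
  assigned by the sign of their perpendicular offset, and a pixel exactly
  on the axis counts as upper.
- **Sections** (thirds) use the normalised projection of each band pixel
  onto the principal axis, measured against the implant's own extent and
  clipped to [0, 1] — the peripheral thirds are the ones nearest the defect
  walls because the implant ends penetrate the walls in this geometry.

All 18 region ids exist in every partition table, possibly with zero
pixels (e.g. an implant flush against a wall); disjointness and exact
conservation of the band's pixel count are tested against brute-force
enumeration.

The 1-px surface band for bone–implant contact uses 8-connectivity (a
4-connected band would leave gaps across diagonal edges) and is clipped to
the defect. The same clipped set is the BIC denominator, which keeps
BIC ≤ 100 by construction; the unclipped-perimeter variant is available via
`compute_bic(..., clip_to_defect=False)` for sensitivity analyses.

## Segmentation

Bone is thresholded in HSV (hue window wrapping through red, saturation
floor, value range); hue is robust to overall illumination scaling, and an
RGB ratio rule is provided as a fallback. Components smaller than 5 px are
removed by default (set `min_object_px=0` to obtain the raw threshold
contract). "Manually adjusted" thresholds are supported as explicit
per-image overrides that are logged when applied, so the manual step of a
real analysis stays reproducible. The implant is the largest connected
component with HSV value below 0.15, holes filled; when no dark component
exists the caller is asked for a manual mask rather than silently guessing.

Whole-defect bone density is computed over defect ∖ implant — the metal
cannot contain bone, and including it would deflate the density. Zone-level
densities are emitted for every region but are secondary to the
whole-defect value; densities of the thin 100-μm layers are dominated by
boundary pixels and should be read accordingly. Missing values (empty
region, empty band, lost disc) propagate as NaN, never zero, so the
statistics see absence rather than a spurious measurement.

## Synthetic sections

The generator emulates the morphology the analysis assumes, not bone
biology:

- **Geometry** — a symmetric horizontal trapezoid implant (7 × 1 mm,
  45° cutting edges) whose sharp ends penetrate the walls of a 5-mm-wide
  trephine slot with a semicircular bottom; all dimensions configurable.
- **Growth** — stochastic cellular dilation: bone seeds exclusively at
  defect-wall pixels and, per step, each empty defect pixel 8-adjacent to
  bone is occupied with probability 0.35, multiplied by `conduction_bias`
  (capped at 1) inside a 100-μm implant boundary band. This is the simplest
  mechanism that reproduces osteoconductive propagation along the implant
  surface originating from the walls. Growth is monotone, never enters the
  implant, and one step advances the front by roughly 0.35–1 pixel, so
  ~70 steps at full scale produce a partially healed defect.
- **Rendering** — fixed HSV class colours (magenta bone, blue soft tissue,
  near-black implant, near-white background) placed strictly inside/outside
  the default thresholds, so zero-noise rendering is exactly invertible by
  the default segmentation. Noise adds hue jitter (sd 0.03·level), value
  jitter (0.15·level), Gaussian blur (σ = 2·level px), and sensor noise
  (0.10·level), all seeded.
- **Fluorescence fields** — non-overlapping red disks with centres drawn
  toward the lower border (where the implant surface sits), over low-level
  red background and an independent blue nuclei plane; ground-truth CD31
  area is the rendered red-positive pixel count times the pixel area.
- **Release curves** — interval masses are differences of the delayed
  first-order law at the 1, 2, 3, 6, …, 21-day schedule, plus Gaussian
  noise truncated at zero (an immunoassay cannot return negative mass).
- **Studies** — one disc per (animal, condition, timepoint) over the ten
  surface conditions, 3–4 cross-sections per disc, with optional lost
  discs (flagged, never imputed) and planted effects that shift the bone
  fraction of a chosen region class by adding or removing bone pixels
  there.

What passing tests show: that the measurement chain — segmentation,
partition, counting, statistics — is correct against known truth, under a
noise model covering colour jitter, blur, and sensor noise. What they do
not show: robustness to stain variability between labs, sectioning
artefacts, tissue tearing, or non-planar implants; real analyses should
expect to use the per-image threshold overrides.

## Statistics

The battery is nonparametric by design, matching repeated-measures practice
for within-animal designs. The Shapiro–Wilk gate records whether a
parametric analysis would even have been admissible (groups with n < 3 are
skipped; a constant sample is flagged non-normal). Friedman tests run on
complete blocks only — blocks with any missing condition are dropped
listwise and logged, because imputation would invent data. The post hoc is
a Dunn-type z test on within-block mean ranks,
z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n), with Bonferroni adjustment capped at 1;
Wilcoxon signed-rank pairwise comparisons are available as an alternative.
Mann–Whitney uses the exact null distribution when both samples have n ≤ 8
and the pooled data are tie-free, otherwise the normal approximation with
tie correction. Family-wise α arithmetic (fwer/m) is exposed as a function
and never silently applied; reported tests default to α = 0.05.

At 6 blocks × 10 conditions the asymptotic chi-square Friedman test is
conservative: its true null rejection rate at nominal 5 % is ≈ 3.6 %
(measured by simulation). The calibration test asserts the 2000-replicate
rate stays within [3.5 %, 6.5 %].

## Release-law fitting

`fit_release_model` least-squares fits the cumulative per-cm² curve. The
delay parameter enters non-smoothly, so it is scanned on a 0.75-day grid
and refined by bounded scalar minimisation, refitting the smooth parameters
(total, burst, rate; bounded to total ≥ 0, burst ∈ [0, 1], rate ∈ [0, 10])
at each candidate. Any delay below the first sampled timepoint is
observationally equivalent to a larger burst fraction, so the fit reports
the **smallest** delay compatible with the data (larger delays are accepted
only on a meaningful residual improvement). An all-zero series is
non-identifiable: total is 0 and the other parameters are returned as NaN
with `identifiable=False`.

A caveat on precision: with noise on each sampled interval of the order of
5 % of the total load, the rate constant is intrinsically weakly
identified — the Cramér–Rao bound for this design gives a relative standard
deviation of ~0.4 on the rate, so individual fits at that noise level carry
rate uncertainties of tens of percent regardless of estimator. Noiseless
round trips recover all parameters to machine-level precision.

## Problem sizes used in the tests

Most tests run on a reduced-scale section (170 × 140 px at a 4×-coarser
pixel edge, same shapes and layer structure, ~100-μm layers ≈ 6 px), which
the package treats as its standard small verification geometry. Ground-truth
recovery through the full optical loop is verified once at the full default
scale (1800 × 1400 px, 17.43 μm²/px), where the tolerance of 2 percentage
points on region densities holds with an order of magnitude of margin; at
the reduced scale the boundary-to-area ratio of partially filled zones is
~4× larger and per-zone densities are correspondingly noisier. The
planted-effect power study uses 12 animal blocks, four conditions, one
cross-section per disc at the reduced scale over 200 replicates. Exhaustive
geometric oracles run on random masks up to 50–60 px across, where
brute-force enumeration is exact and fast.

## Known limitations

- The growth model produces compact fronts, not trabecular microstructure;
  texture-level segmentation behaviour is untested by design.
- The zone partition assumes an elongated, roughly convex implant
  cross-section; strongly curved or fragmented implants would need a
  different side/section convention.
- Field placement assumes the implant's long edges are close to horizontal
  in image coordinates (as produced by the generator and by standard
  mounting); arbitrarily rotated sections should be rectified first.
- Release fitting assumes a single burst + first-order process per curve;
  multi-phase releases will fit poorly and show it in the residual SD.
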