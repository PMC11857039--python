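# periomorph

Peri-implant histomorphometry for disc-implant healing studies, with the
matching nonparametric statistics and growth-factor release accounting — and
a synthetic-histology generator with known ground truth so every stage of
the pipeline is verifiable.

The package targets the quantitative workflow of trephine-defect implant
models: a titanium disc (7 × 1 mm trapezoid cross-section) is press-fit into
a 5-mm trephine cavity, sections are stained (Alizarin red marks
mineralised bone), scanned, and quantified. It is written for researchers
who need the image-derived outcome measures of such studies to be
reproducible and testable rather than bound to interactive tooling.

## What it computes

**Segmentation** (`periomorph.segmentation`) — bone masks by HSV
stain-colour thresholding (per-image manual overrides are explicit and
logged), implant masks as the largest dark component with holes filled, and
CD31-positive immunofluorescence area as thresholded red-channel area in
μm².

**Zone geometry** (`periomorph.zonegeom`) — the peri-implant region of
interest is a 300-μm band around the implant cross-section, clipped to the
defect and partitioned into **18 regions**:

- 2 **sides** (upper/lower of the implant's principal axis) ×
- 3 **layers** by exact Euclidean distance, half-open bins
  [0, 100), [100, 200), [200, 300) μm (immediate / intermediate / remote) ×
- 3 **sections** along the implant axis (peripheral-left / central /
  peripheral-right thirds).

**Morphometry** (`periomorph.morphometry`) — with the pixel-area calibration
*a* (default 17.43 μm²/px, pixel edge √a ≈ 4.175 μm):

- bone formation `BF = |bone ∩ region| · a · 10⁻⁶` mm²,
- bone density `BD = 100 · |bone ∩ region| / |region|` %,
- bone–implant contact `BIC = 100 · |S ∩ bone| / |S|` %, where `S` is the
  implant mask dilated by 1 px (8-connectivity), minus the implant, clipped
  to the defect,
- 13 fluorescence field boxes (7 upper + 6 lower, 725 × 543 μm) along the
  implant edges, and per-disc means over 3–4 cross-sections with explicit
  missing-value propagation.

**Statistics** (`periomorph.stats`) — Shapiro–Wilk normality gate; Friedman
tests over complete animal blocks with Dunn-type rank post hoc comparisons
and Bonferroni correction (`p_adj = min(1, p · m)`); two-sided Mann–Whitney
U between healing intervals (exact for small tie-free samples); Spearman
correlation grids; and family-wise α arithmetic (e.g. 0.05/14 ≈ 0.36 % per
comparison).

**Kinetics** (`periomorph.kinetics`) — loading masses (volume ×
concentration; 80 μL × 75 μg/mL = 6 μg), indirect loading efficacy from
supernatant depletion, cumulative release over the 1, 2, 3, then every-3-days
schedule to day 21, leaching fractions, and least-squares fitting of the
delayed first-order release law

```
M(t) = total · [ burst·1(t>delay) + (1−burst)·(1 − e^{−rate·(t−delay)₊}) ]
```

whose delay term captures the suppressed lower zone of a 2-zone multilayer
coating.

**Synthetic data** (`periomorph.synthdata`) — sections with stochastic
osteoconductive bone growth seeded at the defect walls, stain rendering
that is exactly invertible by the default segmentation at zero noise,
fluorescence fields, release series, and full multi-animal study tables
with planted effects — all bit-reproducible under a seed and all carrying
ground truth.

## Worked example

```python
from periomorph import morphometry, synthdata, zonegeom
from periomorph.segmentation import segment_bone, segment_implant

spec = synthdata.SectionSpec(growth_steps=70, conduction_bias=2.0, seed=1)
masks, truth = synthdata.generate_section(spec)          # ground truth kept
img = synthdata.render_stain(masks, noise_level=0.2, seed=7)

implant = segment_implant(img)
bone = segment_bone(img, implant_mask=implant)
part = zonegeom.partition_zones(implant, masks.defect, spec.pixel_area_um2)
df = morphometry.section_morphometry(bone, implant, masks.defect,
                                     spec.pixel_area_um2, partition=part)
```

Printing the headline rows of `df` for this seed gives

```
whole-defect BF = 2.68 mm^2
whole-defect BD = 15.5 %
immediate-layer BD = 12.0 %
BIC = 11.6 %  (ground truth 12.0 %)
```

i.e. 2.68 mm² of new bone filling 15.5 % of the cavity, with 11.6 % of the
implant surface band in bone contact — recovered through rendering, noise,
and re-segmentation to within 0.4 percentage points of the generator's
truth.

The same operations are scriptable from the shell:

```sh
periomorph simulate section --config spec.yaml --seed 1 --out sec/
periomorph segment --image sec/section.tiff --out seg/
periomorph zones --implant seg/implant.png --defect sec/defect.png --out zones/
periomorph quantify --bone seg/bone.png --implant seg/implant.png \
    --defect sec/defect.png --out morphometry.csv
```

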