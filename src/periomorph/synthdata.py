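"""Synthetic histology, fluorescence fields, release curves, and study tables.

Every generator carries its own ground truth so each downstream stage
(segmentation → zone geometry → morphometry → statistics) can be verified
against known values.  The emulated scene is a trapezoidal titanium disc
cross-section (7 × 1 mm, sharp 45° cutting edges) press-fit into a 5-mm
trephine defect, with mineralised bone growing from the defect walls and —
when osteoconduction is biased — propagating preferentially along the
implant surface.  Rendering at zero noise places every class strictly inside
or outside the default segmentation thresholds, so the pipeline is exactly
invertible there; noise exercises threshold robustness.

All generators are bit-reproducible under a fixed seed
(``numpy.random.default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw as skdraw

from . import morphometry, zonegeom
from .segmentation import CalibratedImage
from .zonegeom import GeometryError, pixel_edge_um

# ---------------------------------------------------------------------------
# Section geometry and bone growth
# ---------------------------------------------------------------------------

#: Per-step acceptance probability of a frontier pixel in the bulk.
BASE_GROWTH_RATE = 0.35
#: Thickness (μm) of the implant boundary band where osteoconduction applies.
CONDUCTION_BAND_UM = 100.0

#: Rendered HSV colours per tissue class (hue, saturation, value).
STAIN_HSV = {
    "bone": (0.975, 0.70, 0.55),       # Alizarin red/magenta
    "soft": (0.58, 0.40, 0.78),        # toluidine-blue soft tissue
    "implant": (0.0, 0.0, 0.05),       # titanium, near-black
    "background": (0.10, 0.02, 0.97),  # slide background / native bone walls
}


@dataclass(frozen=True)
class SectionSpec:
    """Geometry and stochastic parameters of one synthetic cross-section.

    Defaults follow the study system: 7 × 1 mm disc profile, 5-mm trephine
    defect, 17.43 μm²/pixel calibration.  The pixel edge length is derived as
    sqrt(pixel_area_um2) ≈ 4.175 μm — the single source of truth for scale.
    ``conduction_bias`` ≥ 1 multiplies the growth acceptance probability
    inside the 100-μm implant boundary band.
    """

    image_width_px: int = 1800
    image_height_px: int = 1400
    pixel_area_um2: float = 17.43
    implant_length_mm: float = 7.0
    implant_thickness_mm: float = 1.0
    defect_diameter_mm: float = 5.0
    growth_steps: int = 60
    conduction_bias: float = 1.0
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        for name in ("implant_length_mm", "implant_thickness_mm", "defect_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.growth_steps < 0:
            raise ValueError("growth_steps must be nonnegative")
        if self.conduction_bias < 1:
            raise ValueError("conduction_bias must be >= 1")
        if not 0 <= self.noise_level <= 1:
            raise ValueError("noise_level must lie in [0, 1]")

    @property
    def pixel_edge_um(self) -> float:
        return pixel_edge_um(self.pixel_area_um2)

    def mm_to_px(self, mm: float) -> float:
        return mm * 1000.0 / self.pixel_edge_um

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SectionSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def scaled(self, **kw) -> "SectionSpec":
        return SectionSpec(**{**asdict(self), **kw})


@dataclass
class MaskSet:
    """Co-registered binary masks of one cross-section on one pixel grid."""

    implant: np.ndarray
    defect: np.ndarray
    bone: np.ndarray
    pixel_area_um2: float

    def __post_init__(self):
        self.implant = np.asarray(self.implant, dtype=bool)
        self.defect = np.asarray(self.defect, dtype=bool)
        self.bone = np.asarray(self.bone, dtype=bool)
        if not (self.implant.shape == self.defect.shape == self.bone.shape):
            raise ValueError("masks are not co-registered")
        if np.any(self.bone & self.implant):
            raise ValueError("bone mask overlaps implant mask")

    def copy(self) -> "MaskSet":
        return MaskSet(self.implant.copy(), self.defect.copy(), self.bone.copy(),
                       self.pixel_area_um2)


@dataclass
class GroundTruth:
    """Generator-side truth for one section or fluorescence field."""

    masks: MaskSet | None
    true_zone_bone_fraction: dict[int, float]
    true_bic_percent: float
    true_cd31_area_um2: float | None = None

    def __post_init__(self):
        for rid, f in self.true_zone_bone_fraction.items():
            if not (0.0 <= f <= 1.0 or math.isnan(f)):
                raise ValueError(f"zone {rid} fraction {f} outside [0, 1]")
        if not (0.0 <= self.true_bic_percent <= 100.0
                or math.isnan(self.true_bic_percent)):
            raise ValueError("true_bic_percent outside [0, 100]")
        if self.true_cd31_area_um2 is not None and self.true_cd31_area_um2 < 0:
            raise ValueError("true_cd31_area_um2 must be nonnegative")


def section_geometry(spec: SectionSpec) -> MaskSet:
    """Implant and defect masks for a section (no bone yet).

    The trephine defect is a vertical slot of the defect diameter with a
    semicircular bottom (the trephine profile), opening at the image top and
    clipped to the image.  The implant trapezoid sits symmetric and
    horizontal with its vertical centre at the rectangular/semicircular
    junction; its sharp ends penetrate the defect walls, as in press-fit
    insertion.
    """
    H, W = spec.image_height_px, spec.image_width_px
    half_len = spec.mm_to_px(spec.implant_length_mm) / 2
    thick = spec.mm_to_px(spec.implant_thickness_mm)
    radius = spec.mm_to_px(spec.defect_diameter_mm) / 2
    cc = W / 2
    depth = radius  # rectangular part of the cavity, down to the semicircle centre

    top = depth - thick / 2
    bot = depth + thick / 2
    half_bot = half_len - thick  # 45° taper on both cutting edges
    if half_bot <= 0:
        raise GeometryError("implant thickness too large for its length (no trapezoid)")
    if top < 0 or bot >= H or cc - half_len < 0 or cc + half_len >= W:
        raise GeometryError("implant does not fit inside the image; enlarge the grid")
    if bot >= depth + radius:
        raise GeometryError("implant thicker than the trephine cavity")

    rows = np.array([top, top, bot, bot])
    cols = np.array([cc - half_len, cc + half_len, cc + half_bot, cc - half_bot])
    implant = np.zeros((H, W), dtype=bool)
    rr, cc_ = skdraw.polygon(rows, cols, shape=(H, W))
    implant[rr, cc_] = True

    defect = np.zeros((H, W), dtype=bool)
    r_idx, c_idx = np.mgrid[0:H, 0:W]
    rect = (r_idx < depth) & (np.abs(c_idx + 0.0 - cc) <= radius)
    disk = (r_idx - depth) ** 2 + (c_idx - cc) ** 2 <= radius ** 2
    defect[rect | disk] = True

    bone = np.zeros((H, W), dtype=bool)
    return MaskSet(implant, defect, bone, spec.pixel_area_um2)


def _wall_seed(masks: MaskSet) -> np.ndarray:
    """Defect-wall pixels: defect pixels 8-adjacent to native bone (non-defect),
    excluding the implant.  The open top of the cavity has no wall and seeds
    no bone."""
    outside = ~masks.defect
    outside[0, :] = False  # the cavity opening at the image top is soft tissue
    touch = ndimage.binary_dilation(outside, structure=np.ones((3, 3), bool))
    return masks.defect & touch & ~masks.implant


def _growth_context(spec: SectionSpec):
    """Precompute everything growth needs that depends only on the geometry.

    Growth is confined to the defect, so the stochastic loop runs on the
    defect's bounding box (plus a 1-px margin) and is pasted back afterwards.
    """
    base = section_geometry(spec)
    dist_um = zonegeom.implant_distance_um(base.implant, spec.pixel_area_um2)
    band = (dist_um > 0) & (dist_um <= CONDUCTION_BAND_UM)
    p_grow = np.where(band, min(1.0, spec.conduction_bias * BASE_GROWTH_RATE),
                      BASE_GROWTH_RATE)
    rows, cols = np.nonzero(base.defect)
    r0 = max(0, int(rows.min()) - 1)
    r1 = min(base.defect.shape[0], int(rows.max()) + 2)
    c0 = max(0, int(cols.min()) - 1)
    c1 = min(base.defect.shape[1], int(cols.max()) + 2)
    box = (slice(r0, r1), slice(c0, c1))
    return {
        "base": base,
        "box": box,
        "allowed": (base.defect & ~base.implant)[box],
        "seeds": _wall_seed(base)[box],
        "p_grow": p_grow[box],
    }


def grow_bone(spec: SectionSpec, *, keep_series: bool = True,
              _ctx=None) -> list[MaskSet]:
    """Stochastic osteoconductive bone growth; returns masks at every step.

    Bone seeds exclusively at defect-wall pixels, then advances by cellular
    dilation: at each step every empty defect pixel 8-adjacent to bone is
    occupied with probability ``BASE_GROWTH_RATE``, multiplied by
    ``conduction_bias`` (capped at 1) inside the 100-μm implant boundary
    band.  Growth is monotone and never enters the implant.  Element 0 of
    the returned series has an empty bone mask.

    ``keep_series=False`` returns a one-element list holding only the final
    state (identical to the last element of the full series under the same
    seed), skipping the per-step snapshots.
    """
    ctx = _growth_context(spec) if _ctx is None else _ctx
    base, box = ctx["base"], ctx["box"]
    allowed, seeds, p_grow = ctx["allowed"], ctx["seeds"], ctx["p_grow"]
    rng = np.random.default_rng(spec.seed)

    def snapshot(local_bone):
        step = base.copy()
        step.bone[box] = local_bone
        return step

    series = [base.copy()] if keep_series else []
    bone = np.zeros(allowed.shape, dtype=bool)
    struct = np.ones((3, 3), bool)
    for _ in range(spec.growth_steps):
        if not bone.any():
            frontier = seeds
        else:
            frontier = ndimage.binary_dilation(bone, structure=struct) & ~bone
        frontier = frontier & allowed
        accept = rng.random(size=bone.shape) < p_grow
        bone = bone | (frontier & accept)
        if keep_series:
            series.append(snapshot(bone))
    if not keep_series:
        series.append(snapshot(bone))
    return series


def section_ground_truth(masks: MaskSet,
                         partition: zonegeom.ZonePartition | None = None) -> GroundTruth:
    """Zone bone fractions and BIC computed directly from the generator masks."""
    if partition is None:
        partition = zonegeom.partition_zones(masks.implant, masks.defect,
                                             masks.pixel_area_um2)
    fractions = {}
    counts = partition.table.set_index("region_id")["pixel_count"]
    for rid, *_ in zonegeom.REGION_TABLE:
        n = int(counts.loc[rid])
        if n == 0:
            fractions[rid] = math.nan
        else:
            fractions[rid] = np.count_nonzero(partition.region_mask(rid) & masks.bone) / n
    bic = morphometry.compute_bic(masks.implant, masks.bone, masks.defect)
    return GroundTruth(masks=masks, true_zone_bone_fraction=fractions,
                       true_bic_percent=bic)


def generate_section(spec: SectionSpec) -> tuple[MaskSet, GroundTruth]:
    """Grow a section to its final step and attach ground truth."""
    masks = grow_bone(spec, keep_series=False)[-1]
    return masks, section_ground_truth(masks)


# ---------------------------------------------------------------------------
# Stain rendering
# ---------------------------------------------------------------------------

def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Vectorised HSV → RGB on float arrays in [0, 1]."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h6 = (h % 1.0) * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    rgb = np.empty(hsv.shape, dtype=float)
    for idx, (r, g, b) in enumerate([(v, t, p), (q, v, p), (p, v, t),
                                     (p, q, v), (t, p, v), (v, p, q)]):
        sel = i == idx
        rgb[..., 0][sel] = r[sel]
        rgb[..., 1][sel] = g[sel]
        rgb[..., 2][sel] = b[sel]
    return rgb


def render_stain(masks: MaskSet, noise_level: float = 0.0,
                 seed: int = 0) -> CalibratedImage:
    """Render masks as an Alizarin/toluidine-stained RGB bright-field image.

    At ``noise_level = 0`` every bone pixel's colour lies strictly inside the
    default bone thresholds and every non-bone pixel strictly outside, so
    default segmentation recovers the masks exactly.  Noise adds hue/value
    jitter, a Gaussian blur, and per-pixel sensor noise, all scaled by
    ``noise_level`` and drawn from the given seed.
    """
    if not 0 <= noise_level <= 1:
        raise ValueError("noise_level must lie in [0, 1]")
    H, W = masks.implant.shape
    hsv = np.empty((H, W, 3), dtype=float)
    classes = {
        "background": ~masks.defect & ~masks.implant,
        "soft": masks.defect & ~masks.bone & ~masks.implant,
        "bone": masks.bone,
        "implant": masks.implant,
    }
    for name, mask in classes.items():
        hsv[mask] = STAIN_HSV[name]

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        hsv[..., 0] = np.mod(hsv[..., 0] + rng.normal(0, 0.03 * noise_level, (H, W)), 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] + rng.normal(0, 0.15 * noise_level, (H, W)), 0, 1)
        rgb = _hsv_to_rgb(hsv)
        rgb = ndimage.gaussian_filter(rgb, sigma=(2.0 * noise_level,) * 2 + (0,))
        rgb = rgb + rng.normal(0, 0.10 * noise_level, rgb.shape)
        rgb = np.clip(rgb, 0, 1)
    else:
        rgb = _hsv_to_rgb(hsv)
    return CalibratedImage(data=rgb, pixel_area_um2=masks.pixel_area_um2)


# ---------------------------------------------------------------------------
# Fluorescence fields
# ---------------------------------------------------------------------------

def gen_fluorescence(field_um: tuple[float, float] = (725.0, 543.0),
                     n_blobs: int = 12, blob_area_um2: float = 1500.0,
                     pixel_area_um2: float = 17.43, seed: int = 0,
                     n_nuclei: int = 120) -> tuple[CalibratedImage, GroundTruth]:
    """Fluorescence field with red CD31-like blobs near the lower border.

    The implant surface sits at the lower border of the field, so blob
    centres are drawn with an exponential distance profile from the bottom.
    Blobs are placed without overlap (rejection sampling).  The ground-truth
    CD31 area is the rendered red-positive pixel count × pixel area.  The
    blue plane carries nuclei unrelated to the red measurement.
    """
    if field_um[0] <= 0 or field_um[1] <= 0:
        raise ValueError("field dimensions must be positive")
    if n_blobs < 0 or blob_area_um2 < 0:
        raise ValueError("n_blobs and blob_area_um2 must be nonnegative")
    field_area = field_um[0] * field_um[1]
    if n_blobs and (blob_area_um2 > field_area
                    or n_blobs * blob_area_um2 > 0.5 * field_area):
        raise ValueError("requested blob area exceeds what the field can hold")

    edge = pixel_edge_um(pixel_area_um2)
    W = max(1, int(round(field_um[0] / edge)))
    H = max(1, int(round(field_um[1] / edge)))
    rng = np.random.default_rng(seed)

    red_mask = np.zeros((H, W), dtype=bool)
    r_blob = math.sqrt(blob_area_um2 / math.pi) / edge
    placed = []
    for _ in range(n_blobs):
        for _attempt in range(200):
            col = rng.uniform(r_blob, max(r_blob + 1e-9, W - r_blob))
            d = rng.exponential(scale=H / 5.0)
            row = np.clip(H - 1 - d, r_blob, H - 1)
            if all((row - r0) ** 2 + (col - c0) ** 2 >= (2 * r_blob) ** 2
                   for r0, c0 in placed):
                break
        placed.append((row, col))
        rr, cc = skdraw.disk((row, col), max(r_blob, 0.5), shape=(H, W))
        red_mask[rr, cc] = True

    red = rng.uniform(0.0, 0.10, (H, W))
    red[red_mask] = rng.uniform(0.70, 1.0, int(red_mask.sum()))
    blue = rng.uniform(0.0, 0.08, (H, W))
    for _ in range(n_nuclei):
        rr, cc = skdraw.disk((rng.uniform(0, H), rng.uniform(0, W)),
                             max(0.8, 3.0 / edge * 4.175), shape=(H, W))
        blue[rr, cc] = rng.uniform(0.5, 0.9)
    img = CalibratedImage(np.stack([red, np.zeros((H, W)), blue], axis=2),
                          pixel_area_um2=pixel_area_um2)
    truth = GroundTruth(masks=None, true_zone_bone_fraction={},
                        true_bic_percent=0.0,
                        true_cd31_area_um2=float(red_mask.sum()) * pixel_area_um2)
    return img, truth


# ---------------------------------------------------------------------------
# Release curves
# ---------------------------------------------------------------------------

#: Sampling schedule (days): 24, 48, 72 h, then every 3 days until day 21.
RELEASE_TIMEPOINTS_DAYS = (1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)


def release_law(t, total: float, burst_fraction: float, rate_per_day: float,
                delay_days: float):
    """Cumulative release M(t) = total·[burst·1(t>delay) + (1−burst)·(1−e^{−rate·(t−delay)₊})]."""
    t = np.asarray(t, dtype=float)
    lag = np.maximum(0.0, t - delay_days)
    step = (t > delay_days).astype(float)
    return total * (burst_fraction * step
                    + (1.0 - burst_fraction) * (1.0 - np.exp(-rate_per_day * lag)))


def gen_release_series(total_ug_per_cm2: float, burst_fraction: float,
                       rate_per_day: float, delay_days: float = 0.0,
                       noise_sd: float = 0.0, seed: int = 0, *,
                       area_cm2: float = 0.35, factor: str = "BMP2",
                       sample_id: str = "synthetic",
                       timepoints_days=RELEASE_TIMEPOINTS_DAYS):
    """Interval-sampled synthetic release series.

    Interval masses are differences of the cumulative law at the sampling
    schedule, times the exposed area, plus Gaussian noise truncated at zero
    (an immunoassay cannot report negative mass).  A delay beyond the
    21-day window yields a flat zero curve — the suppressed lower-zone
    pattern of a 2-zone coating.
    """
    from .kinetics import ReleaseSeries  # local import; kinetics owns the container

    if total_ug_per_cm2 < 0 or rate_per_day < 0 or delay_days < 0 or noise_sd < 0:
        raise ValueError("release parameters must be nonnegative")
    if not 0 <= burst_fraction <= 1:
        raise ValueError("burst_fraction must lie in [0, 1]")
    tp = np.asarray(timepoints_days, dtype=float)
    cum = release_law(tp, total_ug_per_cm2, burst_fraction, rate_per_day, delay_days)
    intervals = np.diff(np.concatenate([[0.0], cum])) * area_cm2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intervals = np.maximum(0.0, intervals + rng.normal(0, noise_sd, intervals.shape))
    return ReleaseSeries(sample_id=sample_id, factor=factor, area_cm2=area_cm2,
                         timepoints_days=tuple(tp), interval_ug=tuple(intervals))


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------

#: The ten surface conditions evaluated (coating / growth-factor loading).
DEFAULT_CONDITIONS = (
    "PLL-HEP10/BMP2+PLL-HEP10/VEGF",   # 2-zone, BMP2 lower / VEGF upper
    "PLL-HEP10/VEGF+PLL-HEP10/BMP2",   # 2-zone, VEGF lower / BMP2 upper
    "PLL-HEP20/VEGF+BMP2",             # simultaneous dual loading
    "PLL-HEP20/VEGF",
    "PLL-HEP20/BMP2",
    "PLL-HEP20",                       # unloaded coating control
    "Ti/VEGF+BMP2",
    "Ti/VEGF",
    "Ti/BMP2",
    "Ti",                              # bare, unloaded control
)


@dataclass(frozen=True)
class StudyDesign:
    """Design table of the in vivo arm.

    ``planted_effects`` maps (condition, timepoint_weeks, region_class) to a
    mean shift of the bone fraction in that region class
    ('immediate' / 'intermediate' / 'remote' / 'whole'); ``lost_discs``
    lists (animal, condition, timepoint_weeks) triplets removed during
    preparation.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_animals: int = 12
    timepoints: tuple[int, ...] = (4, 13)
    planted_effects: dict = field(default_factory=dict)
    lost_discs: tuple = ()

    def __post_init__(self):
        if len(self.conditions) == 0:
            raise ValueError("conditions must be non-empty")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")


def planned_disc_count(n_conditions: int, n_animals: int) -> int:
    """Discs scheduled for preparation: one per (condition, animal)."""
    return n_conditions * n_animals


def surviving_disc_count(n_conditions: int, n_animals: int, n_lost: int) -> int:
    """Discs surviving specimen preparation."""
    n = planned_disc_count(n_conditions, n_animals) - n_lost
    if n < 0:
        raise ValueError("more discs lost than planned")
    return n


def _plant_effect(masks: MaskSet, partition: zonegeom.ZonePartition,
                  region_class: str, shift: float, rng) -> None:
    """Shift the bone fraction of a region class by adding/removing bone pixels."""
    if region_class == "whole":
        region = masks.defect & ~masks.implant
    else:
        region = partition.layer_mask(region_class)
    n_region = int(region.sum())
    if n_region == 0:
        return
    n_move = int(round(abs(shift) * n_region))
    if n_move == 0:
        return
    if shift > 0:
        cand = np.flatnonzero(region & ~masks.bone)
    else:
        cand = np.flatnonzero(region & masks.bone)
    if cand.size == 0:
        return
    chosen = rng.choice(cand, size=min(n_move, cand.size), replace=False)
    flat = masks.bone.reshape(-1)
    flat[chosen] = shift > 0


def gen_study(design: StudyDesign, spec: SectionSpec, seed: int = 0, *,
              n_sections: tuple[int, int] = (3, 4),
              render: bool = False, noise_level: float | None = None):
    """Generate the full multi-animal study with known ground truth.

    One disc per (animal, condition, timepoint) minus ``lost_discs``, each
    sampled at 3–4 cross-sections.  Planted effects shift the generated bone
    fraction in the designated region class for (condition, timepoint)
    pairs.  With ``render=True`` each section is rendered and re-segmented
    before measurement (full optical loop); otherwise morphometry runs on
    the generator masks directly.

    Returns ``(records, discs)``: a long-format measurement table with one
    row per (disc, cross-section, region, metric), and a disc index flagging
    lost discs and incomplete (animal, timepoint) blocks.
    """
    from .segmentation import ColorConfig, segment_bone, segment_implant

    rng = np.random.default_rng(seed)
    ctx = _growth_context(spec)
    geometry = ctx["base"]
    partition = zonegeom.partition_zones(geometry.implant, geometry.defect,
                                         spec.pixel_area_um2)
    surface = zonegeom.surface_band(geometry.implant, geometry.defect)
    lost = {tuple(t) for t in design.lost_discs}
    nl = spec.noise_level if noise_level is None else noise_level

    rec_frames, disc_rows = [], []
    for tp in design.timepoints:
        for animal in range(1, design.n_animals + 1):
            for cond in design.conditions:
                disc_id = f"A{animal:02d}-W{tp:02d}-{cond}"
                if (animal, cond, tp) in lost:
                    disc_rows.append({"disc": disc_id, "animal": animal,
                                      "condition": cond, "timepoint_weeks": tp,
                                      "n_sections": 0, "lost": True})
                    continue
                k = int(rng.integers(n_sections[0], n_sections[1] + 1))
                for cs in range(1, k + 1):
                    sub = spec.scaled(seed=int(rng.integers(0, 2**31 - 1)))
                    masks = grow_bone(sub, keep_series=False, _ctx=ctx)[-1]
                    for (c_eff, t_eff, rc), shift in design.planted_effects.items():
                        if c_eff == cond and t_eff == tp:
                            _plant_effect(masks, partition, rc, shift, rng)
                    if render:
                        img = render_stain(masks, noise_level=nl,
                                           seed=int(rng.integers(0, 2**31 - 1)))
                        implant = segment_implant(img)
                        bone = segment_bone(img, ColorConfig(), implant_mask=implant)
                        meas = MaskSet(implant, masks.defect, bone, spec.pixel_area_um2)
                    else:
                        meas = masks
                    df = morphometry.section_morphometry(
                        meas.bone, meas.implant, meas.defect,
                        spec.pixel_area_um2, partition=partition,
                        surface_band_mask=None if render else surface)
                    df.insert(0, "cross_section", cs)
                    df.insert(0, "timepoint_weeks", tp)
                    df.insert(0, "condition", cond)
                    df.insert(0, "animal", animal)
                    df.insert(0, "disc", disc_id)
                    rec_frames.append(df)
                disc_rows.append({"disc": disc_id, "animal": animal,
                                  "condition": cond, "timepoint_weeks": tp,
                                  "n_sections": k, "lost": False})

    records = pd.concat(rec_frames, ignore_index=True)
    discs = pd.DataFrame(disc_rows)
    incomplete = discs[discs["lost"]].groupby(["animal", "timepoint_weeks"]).size()
    discs["block_incomplete"] = [
        (a, t) in incomplete.index
        for a, t in zip(discs["animal"], discs["timepoint_weeks"])
    ]
    return records, discs
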