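"""Peri-implant zone geometry.

The peri-implant region of interest is a 300-μm-thick band around the implant
cross-section, clipped to the trephine defect.  The band is partitioned into
18 regions: two sides (upper/lower of the implant's long axis) × three
distance layers (immediate 0–100 μm, intermediate 100–200 μm, remote
200–300 μm) × three sections along the implant axis (peripheral-left,
central, peripheral-right thirds).  A separate 1-pixel surface band — the
implant mask dilated by one pixel, minus the implant, clipped to the defect —
is the denominator geometry for bone–implant contact.

Distances are exact Euclidean distances between pixel centres (computed with
a Euclidean distance transform, never iterated dilation: at the default
calibration 100 μm ≈ 23.95 px is a non-integer number of pixel widths, so
dilation counts would quantise the layers).  Layer bins are half-open,
[0, 100) / [100, 200) / [200, 300) μm, so no pixel can fall in two layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when a mask geometry cannot support the requested operation."""


SIDES = ("upper", "lower")
LAYERS = ("immediate", "intermediate", "remote")
SECTIONS = ("peripheral-left", "central", "peripheral-right")

#: μm edges of the half-open distance bins defining the three layers.
LAYER_BINS_UM = (0.0, 100.0, 200.0, 300.0)

#: Fixed region-id table: ids 1..18 in (side, layer, section) lexical order.
REGION_TABLE = tuple(
    (1 + i, side, layer, section)
    for i, (side, layer, section) in enumerate(
        (s, l, c) for s in SIDES for l in LAYERS for c in SECTIONS
    )
)


def pixel_edge_um(pixel_area_um2: float) -> float:
    """Edge length of a square pixel of the given area.

    The calibration is stated as an area per pixel (default 17.43 μm²/px);
    the edge length (≈ 4.175 μm) is derived from it so there is a single
    source of truth for physical scale.
    """
    if pixel_area_um2 <= 0:
        raise ValueError(f"pixel_area_um2 must be positive, got {pixel_area_um2}")
    return math.sqrt(pixel_area_um2)


def _as_mask(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask, got shape {a.shape}")
    return a.astype(bool, copy=False)


def _check_coregistered(implant, defect):
    implant = _as_mask(implant, "implant_mask")
    defect = _as_mask(defect, "defect_mask")
    if implant.shape != defect.shape:
        raise ValueError(
            f"masks not co-registered: implant {implant.shape} vs defect {defect.shape}"
        )
    return implant, defect


def implant_distance_um(implant_mask, pixel_area_um2: float) -> np.ndarray:
    """Euclidean distance (μm) from each pixel centre to the nearest implant pixel centre."""
    implant = _as_mask(implant_mask, "implant_mask")
    if not implant.any():
        raise GeometryError("implant mask is empty")
    dist_px = ndimage.distance_transform_edt(~implant)
    return dist_px * pixel_edge_um(pixel_area_um2)


def build_band(implant_mask, defect_mask, pixel_area_um2: float,
               thickness_um: float = 300.0) -> np.ndarray:
    """Peri-implant band: pixels outside the implant closer than ``thickness_um``.

    The band is intersected with the defect mask (the analysis never leaves
    the trephine cavity).  ``thickness_um = 0`` yields an empty band.
    """
    implant, defect = _check_coregistered(implant_mask, defect_mask)
    if thickness_um < 0:
        raise ValueError(f"thickness_um must be >= 0, got {thickness_um}")
    dist = implant_distance_um(implant, pixel_area_um2)
    return (dist > 0) & (dist < thickness_um) & defect


def surface_band(implant_mask, defect_mask) -> np.ndarray:
    """1-pixel implant surface band: dilate(implant, 1 px, 8-connectivity) \\ implant, ∩ defect.

    8-connectivity is used so the band has no gaps across diagonal edges.
    """
    implant, defect = _check_coregistered(implant_mask, defect_mask)
    if not implant.any():
        raise GeometryError("implant mask is empty")
    dilated = ndimage.binary_dilation(implant, structure=np.ones((3, 3), bool))
    return dilated & ~implant & defect


def _principal_axis(implant: np.ndarray):
    """PCA of implant pixel coordinates → (centroid, unit axis, unit normal).

    The axis is oriented toward increasing column (image-left → image-right);
    the normal is oriented toward decreasing row (image-up), so that the
    'upper' side is the one nearer the top of the image.
    """
    coords = np.argwhere(implant).astype(float)  # (row, col)
    if coords.shape[0] < 2:
        raise GeometryError("implant mask is degenerate (fewer than 2 pixels)")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if np.isclose(evals.max(), 0.0):
        raise GeometryError("implant mask is degenerate (zero spatial extent)")
    # orient: axis toward +col; tie-break toward +row
    if axis[1] < 0 or (axis[1] == 0 and axis[0] < 0):
        axis = -axis
    normal = np.array([-axis[1], axis[0]])
    if normal[0] > 0:  # point toward decreasing row = image-up
        normal = -normal
    return centroid, axis, normal


@dataclass
class ZonePartition:
    """18-region partition of the peri-implant band.

    Attributes
    ----------
    labels : int array, 0 outside the band, 1..18 for the regions.
    table : DataFrame with one row per region id (all 18 always present,
        possibly with zero pixels): region_id, side, layer, section,
        pixel_count, area_mm2.
    pixel_area_um2 : calibration used.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_area_um2: float
    thickness_um: float = 300.0

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def layer_mask(self, layer: str) -> np.ndarray:
        ids = [rid for rid, _, lay, _ in REGION_TABLE if lay == layer]
        return np.isin(self.labels, ids)

    @property
    def band_mask(self) -> np.ndarray:
        return self.labels > 0


def partition_zones(implant_mask, defect_mask, pixel_area_um2: float,
                    thickness_um: float = 300.0) -> ZonePartition:
    """Label every band pixel with one of the 18 (side, layer, section) regions.

    * layer — half-open Euclidean distance bins of 100 μm;
    * side — sign of the perpendicular offset from the implant's principal
      axis ('upper' = toward the top of the image; a pixel exactly on the
      axis counts as upper);
    * section — the pixel's normalised projection onto the principal axis,
      measured against the implant's own extent and clipped to [0, 1]:
      [0, 1/3) peripheral-left, [1/3, 2/3) central, [2/3, 1] peripheral-right.

    All 18 region ids appear in the table even when clipped to zero pixels.
    """
    implant, defect = _check_coregistered(implant_mask, defect_mask)
    if not implant.any():
        raise GeometryError("implant mask is empty")
    centroid, axis, normal = _principal_axis(implant)

    dist = implant_distance_um(implant, pixel_area_um2)
    band = (dist > 0) & (dist < thickness_um) & defect

    n_layers = len(LAYERS)
    layer_idx = np.digitize(dist, LAYER_BINS_UM[1:n_layers])  # 0,1,2 within band

    rows, cols = np.nonzero(band)
    pts = np.stack([rows, cols], axis=1).astype(float) - centroid
    perp = pts @ normal
    side_idx = np.where(perp >= 0, 0, 1)  # 0 upper, 1 lower

    t_implant = (np.argwhere(implant).astype(float) - centroid) @ axis
    t_lo, t_hi = t_implant.min(), t_implant.max()
    if t_hi <= t_lo:
        raise GeometryError("implant has zero extent along its principal axis")
    s = np.clip((pts @ axis - t_lo) / (t_hi - t_lo), 0.0, 1.0)
    sect_idx = np.minimum((s * 3).astype(int), 2)  # [0,1/3),[1/3,2/3),[2/3,1]

    labels = np.zeros(implant.shape, dtype=np.uint8)
    labels[rows, cols] = (
        side_idx * (len(LAYERS) * len(SECTIONS))
        + layer_idx[rows, cols] * len(SECTIONS)
        + sect_idx
        + 1
    )

    counts = np.bincount(labels[rows, cols], minlength=19)[1:]
    table = pd.DataFrame(
        REGION_TABLE, columns=["region_id", "side", "layer", "section"]
    )
    table["pixel_count"] = counts
    table["area_mm2"] = counts * pixel_area_um2 * 1e-6
    return ZonePartition(labels=labels, table=table,
                         pixel_area_um2=pixel_area_um2, thickness_um=thickness_um)
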