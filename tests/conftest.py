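"""Shared fixtures: small fast sections, the full-scale geometry, and
exhaustive brute-force oracles for band/BIC geometry."""

from __future__ import annotations

import numpy as np
import pytest

from periomorph import synthdata, zonegeom
from periomorph.synthdata import SectionSpec


#: Reduced-scale section used throughout the fast tests: same shapes and
#: layer structure as the full geometry (100-μm layers span ~6 px at the
#: 4× coarser calibration), two orders of magnitude fewer pixels.
SMALL_SPEC = SectionSpec(
    image_width_px=170, image_height_px=140,
    pixel_area_um2=17.43 * 16,            # 4× coarser pixel edge (~16.7 μm)
    implant_length_mm=1.8, implant_thickness_mm=0.25, defect_diameter_mm=1.3,
    growth_steps=30, conduction_bias=2.0, seed=3,
)


@pytest.fixture(scope="session")
def small_spec() -> SectionSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_section(small_spec):
    """(MaskSet, GroundTruth) of one grown reduced-scale section."""
    return synthdata.generate_section(small_spec)


@pytest.fixture(scope="session")
def standard_geometry():
    """Implant/defect masks at the full default geometry (7 × 1 mm disc,
    5 mm defect, 17.43 μm²/px)."""
    return synthdata.section_geometry(SectionSpec())


@pytest.fixture(scope="session")
def standard_partition(standard_geometry):
    m = standard_geometry
    return zonegeom.partition_zones(m.implant, m.defect, m.pixel_area_um2)


@pytest.fixture(scope="session")
def grown_full_section():
    """One partially healed section at full scale (13-week-like fill)."""
    spec = SectionSpec(growth_steps=70, conduction_bias=2.0, seed=1)
    return synthdata.generate_section(spec)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_surface_band(implant: np.ndarray, defect: np.ndarray) -> np.ndarray:
    """Exhaustive 'pixel 8-adjacent to the implant' enumeration."""
    H, W = implant.shape
    out = np.zeros_like(implant, dtype=bool)
    for r in range(H):
        for c in range(W):
            if implant[r, c] or not defect[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and implant[rr, cc]:
                        out[r, c] = True
    return out


def brute_bic(implant, bone, defect) -> float:
    band = brute_surface_band(implant, defect)
    n = band.sum()
    if n == 0:
        return float("nan")
    return 100.0 * (band & bone).sum() / n


def brute_band(implant, defect, pixel_area_um2, thickness_um) -> np.ndarray:
    """All-pairs pixel-centre distance band (≤ 100×100 grids)."""
    from scipy.spatial.distance import cdist

    edge = np.sqrt(pixel_area_um2)
    pts_i = np.argwhere(implant).astype(float)
    pts_all = np.argwhere(~implant).astype(float)
    d = cdist(pts_all, pts_i).min(axis=1) * edge
    out = np.zeros_like(implant, dtype=bool)
    sel = (d > 0) & (d < thickness_um)
    out[tuple(pts_all[sel].astype(int).T)] = True
    return out & defect


def random_mask_triple(rng: np.random.Generator, size: int = 50):
    """Random (implant, bone, defect) masks: rectangular implant, blobby
    bone and defect."""
    H = int(rng.integers(10, size + 1))
    W = int(rng.integers(10, size + 1))
    implant = np.zeros((H, W), dtype=bool)
    h = int(rng.integers(2, max(3, H // 2)))
    w = int(rng.integers(2, max(3, W // 2)))
    r0 = int(rng.integers(0, H - h))
    c0 = int(rng.integers(0, W - w))
    implant[r0:r0 + h, c0:c0 + w] = True
    bone = rng.random((H, W)) < rng.uniform(0.2, 0.7)
    bone &= ~implant
    defect = rng.random((H, W)) < rng.uniform(0.5, 1.0)
    return implant, bone, defect
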