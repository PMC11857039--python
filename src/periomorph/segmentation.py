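"""Stain-colour segmentation and fluorescence-area measurement.

Bone is detected by its Alizarin-red/magenta hue in HSV space (hue is robust
to illumination scaling; an RGB ratio rule is available as a fallback), the
implant cross-section as the largest dark connected component, and
CD31-positive area as the calibrated area of red-channel pixels above an
intensity threshold.  The study's "manually adjusted" thresholds are
realised as explicit per-image overrides so the manual step stays
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology

logger = logging.getLogger(__name__)


class ChannelError(ValueError):
    """Raised when an image lacks the channels an operation needs."""


class DetectionError(RuntimeError):
    """Raised when automatic detection fails and a manual mask is required."""


@dataclass(frozen=True)
class CalibratedImage:
    """Pixel grid (1 grayscale or 3 RGB planes, floats in [0, 1]) with a
    physical per-pixel area in μm²."""

    data: np.ndarray
    pixel_area_um2: float = 17.43

    def __post_init__(self):
        a = np.asarray(self.data)
        if a.ndim == 3 and a.shape[2] not in (1, 3):
            raise ValueError(f"expected 1 or 3 planes, got {a.shape[2]}")
        if a.ndim not in (2, 3):
            raise ValueError(f"expected a 2-D or 3-plane image, got ndim={a.ndim}")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        object.__setattr__(self, "data", a)

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(frozen=True)
class ColorConfig:
    """Bone / implant colour thresholds.

    ``bone_hue_range`` is on the HSV hue circle in [0, 1); a range with
    lo > hi wraps through 0 (the default window straddles red).  All bounds
    are half-open on the high side except the hue window, which is treated
    as lo ≤ h or h ≤ hi when wrapping.  ``manual_overrides`` maps an image
    identifier to per-image replacement thresholds (the reproducible form of
    manually adjusted parameters); applied overrides are logged.
    """

    color_space: str = "hsv"
    bone_hue_range: tuple[float, float] = (0.90, 0.06)
    bone_saturation_min: float = 0.30
    bone_value_range: tuple[float, float] = (0.18, 0.90)
    implant_value_max: float = 0.15
    min_object_px: int = 5
    manual_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.color_space not in ("hsv", "rgb"):
            raise ValueError(f"unknown color_space {self.color_space!r}")
        for lo, hi, name in [(self.bone_value_range[0], self.bone_value_range[1],
                              "bone_value_range")]:
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"{name} must be well-ordered within [0, 1]")
        if not 0 <= self.bone_saturation_min <= 1:
            raise ValueError("bone_saturation_min out of [0, 1]")
        if not 0 < self.implant_value_max <= 1:
            raise ValueError("implant_value_max out of (0, 1]")

    def for_image(self, image_id: str | None) -> "ColorConfig":
        """Config with any per-image manual override applied (and logged)."""
        if image_id is None or image_id not in self.manual_overrides:
            return self
        over = dict(self.manual_overrides[image_id])
        logger.info("applying manual threshold overrides for %s: %s", image_id, over)
        for key in ("bone_hue_range", "bone_value_range"):
            if key in over:
                over[key] = tuple(over[key])
        return replace(self, **over)

    @classmethod
    def from_yaml(cls, path) -> "ColorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bone_hue_range", "bone_value_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _require_rgb(image: CalibratedImage, op: str) -> np.ndarray:
    if image.n_channels != 3:
        raise ChannelError(f"{op} requires a 3-channel colour image, "
                           f"got {image.n_channels} channel(s)")
    return np.asarray(image.data, dtype=float)


def _hue_in_window(hue: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)  # wraps through 0


def segment_bone(image: CalibratedImage, cfg: ColorConfig | None = None, *,
                 implant_mask=None, image_id: str | None = None) -> np.ndarray:
    """Binary mask of Alizarin-stained bone pixels.

    A pixel is bone when its colour lies inside the configured hue window,
    at or above the saturation floor, and inside the value range; connected
    components smaller than ``min_object_px`` are removed (set it to 0 for
    the raw threshold contract).  Pixels inside a supplied implant mask are
    excluded.
    """
    cfg = (cfg or ColorConfig()).for_image(image_id)
    rgb = _require_rgb(image, "segment_bone")
    if cfg.color_space == "hsv":
        hsv = skcolor.rgb2hsv(rgb)
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        mask = (_hue_in_window(h, cfg.bone_hue_range)
                & (s >= cfg.bone_saturation_min)
                & (v >= cfg.bone_value_range[0])
                & (v <= cfg.bone_value_range[1]))
    else:
        # RGB ratio fallback: red clearly dominant over green, not too dark/bright
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        total = rgb.sum(axis=2) + 1e-12
        mask = ((r / total > 0.45) & (g / total < 0.28)
                & (total / 3 >= cfg.bone_value_range[0])
                & (total / 3 <= cfg.bone_value_range[1]))
    if cfg.min_object_px > 0:
        # keep components of at least min_object_px pixels
        mask = morphology.remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    if implant_mask is not None:
        mask = mask & ~np.asarray(implant_mask, dtype=bool)
    return mask


def segment_implant(image: CalibratedImage, cfg: ColorConfig | None = None, *,
                    image_id: str | None = None) -> np.ndarray:
    """Largest connected dark component, holes filled.

    The titanium cross-section is near-black in bright-field; darkness is
    judged on HSV value (max of the RGB planes).  When no dark component
    exists a :class:`DetectionError` prompts for a manual mask.
    """
    cfg = (cfg or ColorConfig()).for_image(image_id)
    rgb = _require_rgb(image, "segment_implant")
    value = rgb.max(axis=2)
    dark = value < cfg.implant_value_max
    labels, n = ndimage.label(dark)
    if n == 0:
        raise DetectionError("no dark component found; supply a manual implant mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(largest)


def measure_cd31(field: CalibratedImage, intensity_threshold: float = 0.5) -> float:
    """CD31-positive area in μm²: red pixels ≥ threshold × pixel area.

    Works on a 3-channel field (red plane = channel 0) or a single-plane red
    image.  Nonincreasing in the threshold by construction.
    """
    if not 0 <= intensity_threshold <= 1:
        raise ValueError("intensity_threshold must lie within the intensity range [0, 1]")
    data = np.asarray(field.data, dtype=float)
    red = data if data.ndim == 2 else data[..., 0]
    return float(np.count_nonzero(red >= intensity_threshold) * field.pixel_area_um2)
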