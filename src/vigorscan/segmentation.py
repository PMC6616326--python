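"""Binary plant-mask extraction from the rescaled color planes.

The chain is: channel thresholding (hue window AND (green-a* OR yellow-b*)),
binary median (majority) denoise, morphological opening, hole filling, and
removal of small connected components.  All thresholds are calibration knobs
exposed through :class:`SegmentationConfig`; the defaults bracket green-to-
yellow vegetation on the shared 0-255 channel axis and are chosen for the
synthetic scenes this package renders, not measured constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .color_spaces import ChannelStack, build_channel_stack, validate_rgb_image

__all__ = [
    "SegmentationConfig",
    "channel_threshold_mask",
    "median_denoise",
    "morphological_refine",
    "fill_holes",
    "remove_small_components",
    "segment_plant",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Free parameters of the segmentation chain.

    hue_window : (low, high) on the rescaled 0-255 hue axis; default (35, 120)
        is roughly 50-170 degrees, the yellow-through-green band.
    a_green_max : pixels with rescaled a* at or below this count as green.
    b_yellow_min : pixels with rescaled b* at or above this count as yellow.
    median_radius : binary median (majority) filter radius in px; 0 = off.
    morph_size : side of the square structuring element for opening.
    morph_iterations : number of opening passes; 0 = off.
    min_component_area : 8-connected foreground components smaller than this
        (in px) are dropped at the end of the chain.
    soil_line_row : optional fixed row treated as the plant base by the height
        measurement downstream (None = use the lowest foreground row).
    """

    hue_window: tuple[float, float] = (35.0, 120.0)
    a_green_max: float = 120.0
    b_yellow_min: float = 135.0
    median_radius: int = 1
    morph_size: int = 3
    morph_iterations: int = 1
    min_component_area: int = 25
    soil_line_row: int | None = None

    def __post_init__(self) -> None:
        low, high = self.hue_window
        if not low < high:
            raise ValueError(f"degenerate hue window: low={low} must be < high={high}")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.morph_size < 1:
            raise ValueError("morph_size must be >= 1")
        if self.morph_iterations < 0:
            raise ValueError("morph_iterations must be >= 0")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")


def channel_threshold_mask(stack: ChannelStack, cfg: SegmentationConfig) -> np.ndarray:
    """Boolean plant mask from the three rescaled planes.

    Rule: (hue inside window) AND ((y_a <= a_green_max) OR (y_b >= b_yellow_min)).
    The hue window confines pixels to the plant color family; the opponent
    channels recover strongly green or senescent-yellow tissue within it.
    """
    low, high = cfg.hue_window
    in_hue = (stack.y_hue >= low) & (stack.y_hue <= high)
    greenish = stack.y_a <= cfg.a_green_max
    yellowish = stack.y_b >= cfg.b_yellow_min
    return in_hue & (greenish | yellowish)


def median_denoise(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary median (majority) filter over a (2r+1)^2 window, replicate padding."""
    if radius < 0:
        raise ValueError("median radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    size = 2 * radius + 1
    out = ndimage.median_filter(mask.astype(np.uint8), size=size, mode="nearest")
    return out.astype(bool)


def _square_element(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def morphological_refine(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Morphological opening (erosion then dilation), repeated morph_iterations times."""
    mask = np.asarray(mask, dtype=bool)
    if cfg.morph_iterations == 0:
        return mask.copy()
    elem = _square_element(cfg.morph_size)
    out = mask
    for _ in range(cfg.morph_iterations):
        out = ndimage.binary_erosion(out, structure=elem)
        out = ndimage.binary_dilation(out, structure=elem)
    return out


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(mask)


def remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected foreground components smaller than min_area px."""
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def segment_plant(img: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Full segmentation chain from RGB image to clean binary plant mask."""
    if cfg is None:
        cfg = SegmentationConfig()
    validate_rgb_image(img)
    stack = build_channel_stack(img)
    mask = channel_threshold_mask(stack, cfg)
    mask = median_denoise(mask, cfg.median_radius)
    mask = morphological_refine(mask, cfg)
    mask = fill_holes(mask)
    mask = remove_small_components(mask, cfg.min_component_area)
    return mask
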