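"""Projected plant height and pixel area from binary masks; batch trait records.

Projected height is the inclusive vertical extent of the mask (top-most to
bottom-most foreground row), optionally measured against a fixed soil-line
row when pots are visible.  Pixel traits are primary; millimetre conversion
is an optional, explicitly labelled calibration step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationConfig, segment_plant

__all__ = [
    "TRAIT_VOCABULARY",
    "TraitRecord",
    "CalibrationScale",
    "BatchFailure",
    "projected_height",
    "pixel_area",
    "calibrate",
    "extract_traits_batch",
]

logger = logging.getLogger(__name__)

#: Closed trait vocabulary: image height (px / mm), pixel area, manual shoot
#: length (mm) and fresh weight (g).
TRAIT_VOCABULARY = frozenset({"PH_px", "PH_mm", "AREA_px", "SL_mm", "FW_g"})


@dataclass(frozen=True)
class TraitRecord:
    """One measurement: (line, replicate, trait, value >= 0)."""

    line_id: str
    replicate: int
    trait: str
    value: float

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_VOCABULARY:
            raise ValueError(f"unknown trait {self.trait!r}; allowed: {sorted(TRAIT_VOCABULARY)}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"trait value must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class CalibrationScale:
    """Linear pixel-to-millimetre scale (mm per pixel)."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mm_per_px) or self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be finite and > 0, got {self.mm_per_px}")


@dataclass(frozen=True)
class BatchFailure:
    """A per-image failure that did not abort the batch."""

    line_id: str
    replicate: int
    error: str


def projected_height(mask: np.ndarray, soil_line_row: int | None = None) -> int:
    """Inclusive vertical extent of the foreground in pixels; 0 for an empty mask.

    With ``soil_line_row`` set, the base is that fixed row rather than the
    lowest foreground row (rows count downward from the image top).
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        logger.warning("projected_height: empty mask, returning 0")
        return 0
    top, bottom = int(rows[0]), int(rows[-1])
    if soil_line_row is not None:
        bottom = int(soil_line_row)
        if bottom < top:
            logger.warning("projected_height: soil line above plant tip, returning 0")
            return 0
    return bottom - top + 1


def pixel_area(mask: np.ndarray) -> int:
    """Number of foreground pixels."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def calibrate(height_px: int, scale: CalibrationScale) -> float:
    """Convert a pixel measurement to millimetres."""
    return float(height_px) * scale.mm_per_px


def extract_traits_batch(
    images: list[tuple[str, int, np.ndarray]],
    cfg: SegmentationConfig | None = None,
    scale: CalibrationScale | None = None,
) -> tuple[list[TraitRecord], list[BatchFailure]]:
    """Segment each (line_id, replicate, image) and emit PH_px / AREA_px records.

    Adds PH_mm when a calibration scale is given.  Per-image failures are
    collected and reported, never fatal to the batch.  Duplicate
    (line_id, replicate) keys are an input error.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    keys = [(lid, rep) for lid, rep, _ in images]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (line_id, replicate) keys in batch: {dupes}")

    records: list[TraitRecord] = []
    failures: list[BatchFailure] = []
    for line_id, replicate, img in images:
        try:
            mask = segment_plant(img, cfg)
            h = projected_height(mask, soil_line_row=cfg.soil_line_row)
            a = pixel_area(mask)
            records.append(TraitRecord(line_id, replicate, "PH_px", float(h)))
            records.append(TraitRecord(line_id, replicate, "AREA_px", float(a)))
            if scale is not None:
                records.append(TraitRecord(line_id, replicate, "PH_mm", calibrate(h, scale)))
        except Exception as exc:  # noqa: BLE001 - batch isolation is the contract
            logger.warning("extract_traits_batch: %s rep %s failed: %s", line_id, replicate, exc)
            failures.append(BatchFailure(line_id, replicate, str(exc)))
    return records, failures
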