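"""RGB -> HSI / CIELAB conversion and channel rescaling to a common 0-255 axis.

The segmentation stage thresholds three color planes: the HSI hue angle
(yellow-to-green band), the CIELAB a* opponent (greenness) and b* opponent
(yellowness).  All three are rescaled onto a shared 0-255 axis so thresholds
live in one coordinate system:

    Y_a  = ((a* + 100) / 200) * 255
    Y_b  = ((b* + 100) / 200) * 255
    Y_H  = (H / 360) * 255

HSI follows the geometric (Gonzalez-Woods) definition: intensity is the
channel mean, saturation is 1 - min/mean, and hue is the arccos angle of the
RGB vector around the gray diagonal.  CIELAB assumes sRGB input under D65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HSIImage",
    "LabImage",
    "ChannelStack",
    "validate_rgb_image",
    "rgb_to_hsi",
    "rgb_to_lab",
    "scale_a_channel",
    "scale_b_channel",
    "scale_hue_channel",
    "build_channel_stack",
]

#: Saturation below this is treated as achromatic (hue undefined -> 0 + flag).
ACHROMATIC_EPS = 1e-6


@dataclass(frozen=True)
class HSIImage:
    """Hue/saturation/intensity planes; hue in degrees [0, 360).

    ``achromatic`` flags pixels whose saturation falls below
    :data:`ACHROMATIC_EPS`; their hue is stored as 0 but carries no color
    information.
    """

    hue_deg: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    achromatic: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class LabImage:
    """CIELAB planes: L in [0, 100], a*/b* signed opponents."""

    L: np.ndarray
    a_star: np.ndarray
    b_star: np.ndarray


@dataclass(frozen=True)
class ChannelStack:
    """The three rescaled planes thresholded by segmentation, each in [0, 255]."""

    y_hue: np.ndarray
    y_a: np.ndarray
    y_b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.y_hue.shape  # type: ignore[return-value]


def validate_rgb_image(img: np.ndarray) -> np.ndarray:
    """Validate an H x W x 3 integer RGB raster with channels in [0, 255].

    Returns the validated array (unchanged).  Raises ``ValueError`` on empty
    or malformed input.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert an RGB image to HSI under the geometric definition.

    Intensity = (R+G+B)/3 on the unit scale; saturation = 1 - min/I (0 at
    black); hue = arccos angle, reflected to (180, 360) when B > G.
    Achromatic pixels (R=G=B, including black) get hue 0 and are flagged.
    """
    arr = validate_rgb_image(img).astype(np.float64) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]

    total = r + g + b
    intensity = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = (saturation < ACHROMATIC_EPS) | (den < 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.clip(num / np.where(den > 0, den, 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(achromatic, 0.0, hue)
    hue = np.where(hue >= 360.0, 0.0, hue)
    return HSIImage(hue_deg=hue, saturation=saturation, intensity=intensity, achromatic=achromatic)


#: Standard sRGB -> XYZ matrix (IEC 61966-2-1, D65); rows sum to the D65
#: white tristimulus so reference white maps exactly to L*=100, a*=b*=0.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = _SRGB_TO_XYZ.sum(axis=1)  # (0.95047, 1.0000001, 1.08883)


def rgb_to_lab(img: np.ndarray) -> LabImage:
    """Convert sRGB to CIELAB (D65 white, 2-degree observer).

    Uses the standard chain: sRGB gamma expansion, the tabulated linear-RGB
    -> XYZ matrix, and the CIE L*a*b* cube-root compression with the white
    point implied by that matrix.
    """
    arr = validate_rgb_image(img).astype(np.float64) / 255.0
    lin = np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _D65_WHITE
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(L=L, a_star=a, b_star=b)


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def scale_a_channel(a_star):
    """Map a* onto [0, 255] via ((a* + 100) / 200) * 255, clipping to [-100, 100]."""
    a = _check_finite(a_star, "a*")
    return ((np.clip(a, -100.0, 100.0) + 100.0) / 200.0) * 255.0


def scale_b_channel(b_star):
    """Map b* onto [0, 255] via ((b* + 100) / 200) * 255, clipping to [-100, 100]."""
    b = _check_finite(b_star, "b*")
    return ((np.clip(b, -100.0, 100.0) + 100.0) / 200.0) * 255.0


def scale_hue_channel(hue_deg):
    """Map a hue angle in [0, 360] onto [0, 255] via (H / 360) * 255."""
    h = _check_finite(hue_deg, "hue")
    if np.any(h < 0.0) or np.any(h > 360.0):
        raise ValueError("hue must lie in [0, 360]")
    return (h / 360.0) * 255.0


def build_channel_stack(img: np.ndarray) -> ChannelStack:
    """Full per-pixel conversion of an RGB image to the rescaled threshold planes."""
    hsi = rgb_to_hsi(img)
    lab = rgb_to_lab(img)
    return ChannelStack(
        y_hue=scale_hue_channel(hsi.hue_deg),
        y_a=scale_a_channel(lab.a_star),
        y_b=scale_b_channel(lab.b_star),
    )
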