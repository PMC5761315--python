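"""Skin-image loading, morphological enhancement and directional gradient.

The texture pipeline starts from a grayscale forearm photograph. Wrinkle
lines — the structures that carry the disease signal — are fine, low-contrast
features, so the image is first contrast-enhanced with a morphological
top-hat scheme and then reduced to a directional-gradient field whose
magnitude makes the line structure explicit for co-occurrence analysis.

Coordinate convention: row index = y (downward), column index = x
(rightward), 0-based throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.morphology import disk, white_tophat, black_tophat

__all__ = [
    "SkinImage",
    "GradientField",
    "DEFAULT_PIXEL_AREA_UM2",
    "load_image",
    "save_image",
    "enhance",
    "directional_gradient",
    "gradient_texture_image",
]

#: physical area covered by one pixel at the study's acquisition geometry
#: (20.83 µm × 36 µm per pixel).
DEFAULT_PIXEL_AREA_UM2: float = 20.83 * 36.0

# ITU-R BT.601 luminance weights for RGB → grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_MIN_SIDE = 16


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclasses.dataclass(frozen=True)
class SkinImage:
    """A grayscale skin image with physical pixel-size metadata.

    Parameters
    ----------
    pixels
        2-D float array with intensities in [0, 1].
    pixel_area_um2
        Physical area covered by one pixel, in µm².
    """

    pixels: np.ndarray
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D intensity matrix, got ndim={px.ndim}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValidationError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        if self.pixel_area_um2 <= 0:
            raise ValidationError("pixel_area_um2 must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass(frozen=True)
class GradientField:
    """Directional gradient of an image: gx = ∂f/∂x, gy = ∂f/∂y,
    theta = atan2(gy, gx) in (−π, π], magnitude = √(gx² + gy²)."""

    gx: np.ndarray
    gy: np.ndarray
    theta: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.gx, self.gy, self.theta, self.magnitude)}
        if len(shapes) != 1:
            raise ValidationError("gradient components must share one shape")


def load_image(path: str | Path, pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2) -> SkinImage:
    """Load a PNG/TIFF image as a :class:`SkinImage`.

    RGB inputs are collapsed to luminance (0.299 R + 0.587 G + 0.114 B);
    integer intensities are rescaled to [0, 1] by the dtype's full scale.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path!s}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        scale = 255.0  # PIL decodes multi-channel images to 8-bit
    elif np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float)
    else:
        arr = arr.astype(float)
        scale = 1.0
    return SkinImage(np.clip(arr / scale, 0.0, 1.0), pixel_area_um2=pixel_area_um2)


def save_image(img: SkinImage, path: str | Path) -> None:
    """Write a :class:`SkinImage` as an 8-bit grayscale PNG."""
    data = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path))


def enhance(img: SkinImage, selem_radius: int = 3) -> SkinImage:
    """Morphological contrast enhancement: img + white-top-hat − black-top-hat.

    The white top-hat amplifies bright detail finer than the structuring
    element and the black top-hat dark detail (the wrinkle lines); adding the
    first and subtracting the second boosts both against the smooth skin
    background. Result is clipped to [0, 1].
    """
    if selem_radius < 1 or selem_radius >= min(img.height_px, img.width_px) / 2:
        raise ValidationError(
            f"selem_radius={selem_radius} out of range for a "
            f"{img.height_px}x{img.width_px} image"
        )
    footprint = disk(selem_radius)
    px = img.pixels
    out = px + white_tophat(px, footprint) - black_tophat(px, footprint)
    return SkinImage(np.clip(out, 0.0, 1.0), pixel_area_um2=img.pixel_area_um2)


def directional_gradient(img: SkinImage) -> GradientField:
    """Central-difference gradient field of an image.

    gx and gy are ∂f/∂x (columns) and ∂f/∂y (rows), central differences in
    the interior and one-sided at the borders. ``theta`` uses the
    two-argument arctangent so that gx = 0 is well-defined; it is set to 0
    wherever the magnitude vanishes.
    """
    if img.height_px < 3 or img.width_px < 3:
        raise ValidationError("image must be at least 3x3 for gradients")
    gy, gx = np.gradient(img.pixels)  # axis 0 = y (rows), axis 1 = x (cols)
    magnitude = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    theta[magnitude == 0.0] = 0.0
    # arctan2 range is [−π, π]; fold −π onto π for the (−π, π] convention
    theta[theta == -np.pi] = np.pi
    return GradientField(gx=gx, gy=gy, theta=theta, magnitude=magnitude)


def gradient_texture_image(img: SkinImage, source: str = "magnitude") -> SkinImage:
    """The scalar image handed to texture analysis.

    ``source`` selects what the co-occurrence statistics are computed on:
    ``"magnitude"`` (default) rescales the gradient magnitude to [0, 1],
    ``"theta"`` maps gradient direction from (−π, π] to [0, 1], and
    ``"enhanced"`` bypasses the gradient and returns the image unchanged.
    """
    if source == "enhanced":
        return img
    field = directional_gradient(img)
    if source == "magnitude":
        mag = field.magnitude
        top = mag.max()
        scaled = mag / top if top > 0 else mag
    elif source == "theta":
        scaled = (field.theta + np.pi) / (2.0 * np.pi)
    else:
        raise ValidationError(f"unknown texture source {source!r}")
    return SkinImage(np.clip(scaled, 0.0, 1.0), pixel_area_um2=img.pixel_area_um2)
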