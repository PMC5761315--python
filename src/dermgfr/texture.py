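"""Grey-level co-occurrence texture features.

The wrinkle signal in the gradient image is second-order: what matters is
how often pairs of grey levels co-occur at a fixed displacement, not the
first-order histogram. The co-occurrence matrix is accumulated over four
orientations at unit distance (hand pose makes any single orientation
unreliable) and summarised by four Haralick statistics — contrast, energy,
correlation, homogeneity — used downstream as the four random variables of
each skin-texture process, plus entropy for reporting.

All four RVs are kept on a common [0, 1]-bounded scale (contrast is divided
by (L−1)²) so they can act as the asymptotes/slope/inflection of the
four-parameter model.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix

from .imaging import SkinImage, ValidationError

__all__ = [
    "GLCMatrix",
    "TextureFeatures",
    "DEFAULT_ANGLES",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "image_features",
]

#: default co-occurrence orientations: 0°, 45°, 90°, 135°.
DEFAULT_ANGLES: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

DEFAULT_LEVELS = 8


@dataclasses.dataclass(frozen=True)
class GLCMatrix:
    """Normalized grey-level co-occurrence matrix.

    ``p[i, j]`` is the probability of observing levels (i, j) at the stored
    displacement(s); entries are non-negative and sum to one. ``offsets``
    records the (dr, dc) displacement of each accumulated angle.
    """

    p: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    distance: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.levels, self.levels):
            raise ValidationError(f"GLCM shape {p.shape} != levels {self.levels}")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("GLCM entries must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)


@dataclasses.dataclass(frozen=True)
class TextureFeatures:
    """The four texture random variables plus entropy for one image."""

    contrast: float      # Σ (i−j)² p(i,j) / (L−1)², in [0, 1]
    correlation: float   # Σ (i−μi)(j−μj) p(i,j) / (σi σj), in [−1, 1]
    energy: float        # Σ p(i,j)² (angular second moment), in (0, 1]
    homogeneity: float   # Σ p(i,j) / (1 + (i−j)²), in (0, 1]
    entropy: float       # −Σ p log₂ p, ≥ 0

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("non-finite texture feature")

    def as_array(self) -> np.ndarray:
        return np.array(dataclasses.astuple(self))


def quantize(img: SkinImage | np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniform quantization of [0, 1] intensities into ``levels`` bins.

    Bin k covers [k/levels, (k+1)/levels); intensity 1.0 maps to the top
    bin (levels − 1).
    """
    if not 2 <= levels <= 256:
        raise ValidationError(f"levels must be in [2, 256], got {levels}")
    px = img.pixels if isinstance(img, SkinImage) else np.asarray(img, dtype=float)
    return np.minimum((px * levels).astype(np.intp), levels - 1)


def _offset(distance: int, angle: float) -> tuple[int, int]:
    # same displacement convention as skimage.feature.graycomatrix
    return int(round(np.sin(angle) * distance)), int(round(np.cos(angle) * distance))


def compute_glcm(
    qimg: np.ndarray,
    distance: int = 1,
    angles: Sequence[float] = DEFAULT_ANGLES,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCMatrix:
    """Co-occurrence matrix of a level-indexed image.

    Counts from every requested angle are accumulated before normalization;
    with ``symmetric`` each pair is counted in both orders.
    """
    qimg = np.asarray(qimg)
    if levels is None:
        levels = int(qimg.max()) + 1
    offsets = tuple(_offset(distance, a) for a in angles)
    for dr, dc in offsets:
        rows = qimg.shape[0] - abs(dr)
        cols = qimg.shape[1] - abs(dc)
        if rows * cols < 2:
            raise ValidationError(
                f"image {qimg.shape} too small for offset ({dr}, {dc})"
            )
    counts = graycomatrix(
        qimg.astype(np.uint8),
        distances=[distance],
        angles=list(angles),
        levels=levels,
        symmetric=symmetric,
        normed=False,
    ).astype(float)
    acc = counts[:, :, 0, :].sum(axis=-1)
    p = acc / acc.sum()
    return GLCMatrix(p=p, levels=levels, offsets=offsets, symmetric=symmetric, distance=distance)


def haralick_features(glcm: GLCMatrix, degenerate_correlation: float = 0.0) -> TextureFeatures:
    """The four texture RVs (plus entropy) of a normalized GLCM.

    Correlation is undefined when either marginal is constant (σ = 0); such
    images are reported with ``degenerate_correlation`` and a warning, which
    keeps the downstream four-parameter model finite.
    """
    p = glcm.p
    L = glcm.levels
    idx = np.arange(L, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    diff2 = (i - j) ** 2

    contrast = float((diff2 * p).sum())
    if L > 1:
        contrast /= (L - 1) ** 2
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(idx @ pi)
    mu_j = float(idx @ pj)
    sd_i = float(np.sqrt(((idx - mu_i) ** 2) @ pi))
    sd_j = float(np.sqrt(((idx - mu_j) ** 2) @ pj))
    if sd_i == 0.0 or sd_j == 0.0:
        warnings.warn(
            "constant-level image: correlation undefined, reporting "
            f"{degenerate_correlation}",
            stacklevel=2,
        )
        correlation = degenerate_correlation
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum() / (sd_i * sd_j))

    return TextureFeatures(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        entropy=entropy,
    )


def image_features(
    img: SkinImage,
    levels: int = DEFAULT_LEVELS,
    distance: int = 1,
    angles: Sequence[float] = DEFAULT_ANGLES,
    symmetric: bool = True,
) -> TextureFeatures:
    """Quantize an image and extract its texture features in one call."""
    q = quantize(img, levels=levels)
    glcm = compute_glcm(q, distance=distance, angles=angles, symmetric=symmetric, levels=levels)
    return haralick_features(glcm)
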