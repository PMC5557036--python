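"""Gray-level co-occurrence matrices (GLCM) and Haralick-style texture features.

The GLCM counts pairs of quantized gray levels at a fixed pixel offset,
restricted to a binary region-of-interest mask: a pair contributes only when
both pixels lie inside the mask.  Intensities are quantized by equal-width
binning over the masked min-max range (so the features are invariant to
positive affine rescaling of the image).  In symmetric mode both orderings of
each pair are accumulated, making the matrix symmetric.

Five texture features summarize the normalized matrix ``p(i, j)``:

    entropy       = -sum p log2 p          (randomness of the matrix)
    energy        =  sum p^2               (orderliness)
    homogeneity   =  sum p / (1 + |i-j|)   (uniformity; inverse difference)
    dissimilarity =  sum p |i-j|
    contrast      =  sum p (i-j)^2         (variation)

A lesion profile averages each feature over the offset directions (by
default the four distance-1 2-D directions), the standard direction-averaging
convention for rotation-robust texture summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GLCMSpec",
    "GLCM",
    "TextureFeatures",
    "GLCMOffsetError",
    "quantize_levels",
    "quantize_and_glcm",
    "texture_features",
    "lesion_texture_profile",
]

#: Distance-1 2-D directions: horizontal, vertical, and both diagonals.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


class GLCMOffsetError(ValueError):
    """Raised when an offset yields fewer than two in-mask pixel pairs."""


@dataclass(frozen=True)
class GLCMSpec:
    """Quantization and co-occurrence settings."""

    n_levels: int = 32
    offsets: tuple[tuple[int, ...], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    homogeneity_form: str = "inverse_difference"  # or "inverse_difference_squared"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.offsets:
            raise ValueError("at least one offset is required")
        for off in self.offsets:
            if not any(off):
                raise ValueError("offsets must be non-zero")
        if self.homogeneity_form not in (
            "inverse_difference",
            "inverse_difference_squared",
        ):
            raise ValueError("unknown homogeneity_form")


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence matrix for one offset."""

    P: np.ndarray
    spec: GLCMSpec
    offset: tuple[int, ...]
    n_pairs: int

    def __post_init__(self) -> None:
        if np.any(self.P < 0):
            raise ValueError("GLCM probabilities must be non-negative")
        if abs(float(self.P.sum()) - 1.0) > 1e-12:
            raise ValueError("GLCM probabilities must sum to 1")


@dataclass(frozen=True)
class TextureFeatures:
    entropy: float
    energy: float
    homogeneity: float
    dissimilarity: float
    contrast: float

    def as_dict(self) -> dict[str, float]:
        return {
            "entropy": self.entropy,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
            "dissimilarity": self.dissimilarity,
            "contrast": self.contrast,
        }


def quantize_levels(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of masked intensities into [0, n_levels).

    Bin edges span the masked min-max range; the masked maximum maps to the
    top level.  A constant region maps entirely to level 0.  Values outside
    the mask are quantized with the same edges (they are never paired unless
    the mask says so).
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if not np.isfinite(img[mask]).all():
        raise ValueError("image contains non-finite values inside the mask")
    lo = img[mask].min()
    hi = img[mask].max()
    if hi == lo:
        return np.zeros_like(img, dtype=np.intp)
    levels = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(levels, 0, n_levels - 1)


def quantize_and_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    spec: GLCMSpec | None = None,
) -> list[GLCM]:
    """Compute one masked, normalized GLCM per offset in the spec."""
    spec = spec or GLCMSpec()
    levels = quantize_levels(image, mask, spec.n_levels)
    mask = np.asarray(mask, dtype=bool)
    out = []
    for off in spec.offsets:
        out.append(_glcm_for_offset(levels, mask, off, spec))
    return out


def _glcm_for_offset(
    levels: np.ndarray,
    mask: np.ndarray,
    offset: Sequence[int],
    spec: GLCMSpec,
) -> GLCM:
    ndim = levels.ndim
    off = tuple(offset)
    if len(off) != ndim:
        raise ValueError(f"offset {off} does not match image dimensionality {ndim}")
    src = [slice(None)] * ndim
    dst = [slice(None)] * ndim
    for ax, d in enumerate(off):
        n = levels.shape[ax]
        if abs(d) >= n:
            raise GLCMOffsetError(f"offset {off} exceeds image extent")
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    a = levels[tuple(src)].ravel()
    b = levels[tuple(dst)].ravel()
    valid = (mask[tuple(src)] & mask[tuple(dst)]).ravel()
    a, b = a[valid], b[valid]
    counts = np.zeros((spec.n_levels, spec.n_levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    if n_pairs < 2:
        raise GLCMOffsetError(
            f"offset {off}: fewer than 2 in-mask pixel pairs ({n_pairs})"
        )
    return GLCM(P=counts / counts.sum(), spec=spec, offset=off, n_pairs=n_pairs)


def texture_features(glcm: GLCM) -> TextureFeatures:
    """The five texture features of a normalized GLCM."""
    P = glcm.P
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = np.abs(i - j)
    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    energy = float((P**2).sum())
    if glcm.spec.homogeneity_form == "inverse_difference":
        homog = float((P / (1.0 + diff)).sum())
    else:
        homog = float((P / (1.0 + diff**2)).sum())
    dissim = float((P * diff).sum())
    contrast = float((P * diff.astype(float) ** 2).sum())
    return TextureFeatures(entropy, energy, homog, dissim, contrast)


def lesion_texture_profile(
    image: np.ndarray,
    mask: np.ndarray,
    spec: GLCMSpec | None = None,
) -> tuple[TextureFeatures, dict[tuple[int, ...], TextureFeatures]]:
    """Direction-averaged texture features for one masked lesion.

    Offsets whose in-mask pair count is too small are skipped; if every
    offset fails, the error is re-raised.  Returns the unweighted mean of
    each feature over the succeeding offsets plus the per-offset values.
    """
    spec = spec or GLCMSpec()
    levels = quantize_levels(image, mask, spec.n_levels)
    maskb = np.asarray(mask, dtype=bool)
    per_offset: dict[tuple[int, ...], TextureFeatures] = {}
    last_err: Exception | None = None
    for off in spec.offsets:
        try:
            glcm = _glcm_for_offset(levels, maskb, off, spec)
        except GLCMOffsetError as err:
            last_err = err
            continue
        per_offset[tuple(off)] = texture_features(glcm)
    if not per_offset:
        raise GLCMOffsetError(f"all offsets failed; last error: {last_err}")
    names = ("entropy", "energy", "homogeneity", "dissimilarity", "contrast")
    means = {
        name: float(np.mean([getattr(f, name) for f in per_offset.values()]))
        for name in names
    }
    return TextureFeatures(**means), per_offset
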