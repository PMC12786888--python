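"""Grey-level co-occurrence matrices over masked regions.

The co-occurrence tally is asymmetric: each in-mask horizontal pixel pair
``(r, c) -> (r, c + d)`` is counted once, left to right, at the single offset
``(d, 0 degrees)``.  Features are computed on the normalised probability grid.

Note on the homogeneity denominator: the standard definition uses
``1 + |i - j|`` (guaranteeing a value in (0, 1]); this module implements the
absolute-difference form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Number of grey levels (8-bit depth); the GLCM is always N_LEVELS x N_LEVELS.
N_LEVELS = 256

_PROB_SUM_TOL = 1e-9


class EmptyROIError(ValueError):
    """Raised when an ROI contributes zero valid pixel pairs."""

    def __init__(self, zone: str = "roi"):
        self.zone = zone
        super().__init__(f"empty ROI: zone {zone!r} has no valid horizontal pixel pair")


@dataclass(frozen=True)
class GLCMatrix:
    """Co-occurrence counts for one ROI at a single offset."""

    counts: np.ndarray  # (256, 256) non-negative integers
    offset_distance: int
    offset_angle: float
    total_pairs: int

    def __post_init__(self):
        if self.counts.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"counts must be {N_LEVELS}x{N_LEVELS}, got {self.counts.shape}")
        if int(self.counts.sum()) != self.total_pairs:
            raise ValueError("sum of counts must equal total_pairs")


@dataclass(frozen=True)
class TextureFeatures:
    """The two texture scores of one ROI."""

    contrast: float
    homogeneity: float


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    if not np.issubdtype(image.dtype, np.integer):
        if not np.all(image == np.floor(image)):
            raise ValueError("image must contain integer grey levels")
        image = image.astype(np.int64)
    if image.size and (image.min() < 0 or image.max() > N_LEVELS - 1):
        raise ValueError(f"grey levels must lie in [0, {N_LEVELS - 1}]")
    return image.astype(np.int64, copy=False)


def compute_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    d: int = 1,
    angle: float = 0.0,
    *,
    symmetric: bool = False,
    zone: str = "roi",
) -> GLCMatrix:
    """Tally co-occurrences of grey levels at horizontal offset ``d``.

    A pair contributes only when BOTH pixels lie inside ``mask``; pairs
    straddling the mask boundary are dropped.

    Parameters
    ----------
    image : 2-D integer array, values in [0, 255]
    mask : boolean array, same shape as ``image``
    d : offset distance in pixels (>= 1)
    angle : offset direction in degrees; only 0 is supported
    symmetric : also count each pair in the transposed cell (off by default)
    zone : label used in the empty-ROI error message

    Raises
    ------
    EmptyROIError
        If no valid pair exists (degenerate ROI is a hard error, never a
        silent zero matrix).
    """
    image = _validate_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if d < 1:
        raise ValueError(f"offset distance must be >= 1, got {d}")
    if angle != 0.0:
        raise NotImplementedError("only the horizontal direction (0 degrees) is supported")

    if image.shape[1] <= d:
        raise EmptyROIError(zone)
    valid = mask[:, :-d] & mask[:, d:]
    i = image[:, :-d][valid]
    j = image[:, d:][valid]
    if i.size == 0:
        raise EmptyROIError(zone)

    flat = np.bincount(i * N_LEVELS + j, minlength=N_LEVELS * N_LEVELS)
    counts = flat.reshape(N_LEVELS, N_LEVELS).astype(np.int64)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(
        counts=counts,
        offset_distance=int(d),
        offset_angle=float(angle),
        total_pairs=int(counts.sum()),
    )


def normalize(glcm: GLCMatrix) -> np.ndarray:
    """Return the probability grid ``counts / total_pairs`` (sums to 1)."""
    if glcm.total_pairs < 1:
        raise EmptyROIError()
    return glcm.counts / glcm.total_pairs


def _check_prob(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (N_LEVELS, N_LEVELS):
        raise ValueError(f"probability grid must be {N_LEVELS}x{N_LEVELS}")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError(f"probability grid sums to {P.sum()!r}, expected 1")
    return P


# Precomputed |i - j| over the 256x256 grid, shared by both features.
_LEVELS = np.arange(N_LEVELS)
_ABSDIFF = np.abs(_LEVELS[:, None] - _LEVELS[None, :]).astype(float)


def contrast(P: np.ndarray) -> float:
    """Sum of P(i,j) * (i - j)^2 — weight on dissimilar neighbour levels."""
    P = _check_prob(P)
    return float((P * _ABSDIFF**2).sum())


def homogeneity(P: np.ndarray) -> float:
    """Sum of P(i,j) / (1 + |i - j|) — probability mass near the diagonal."""
    P = _check_prob(P)
    return float((P / (1.0 + _ABSDIFF)).sum())


def texture_features(glcm: GLCMatrix) -> TextureFeatures:
    """Both features from one matrix."""
    P = normalize(glcm)
    return TextureFeatures(contrast=contrast(P), homogeneity=homogeneity(P))


def glcm_brute_force_oracle(
    image: np.ndarray, mask: np.ndarray, d: int = 1, *, zone: str = "roi"
) -> GLCMatrix:
    """Reference implementation: naive double loop over all pixel pairs.

    Same contract as :func:`compute_glcm`; kept deliberately independent of
    the vectorised path and used only in tests.
    """
    image = _validate_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if d < 1:
        raise ValueError(f"offset distance must be >= 1, got {d}")

    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=np.int64)
    n_rows, n_cols = image.shape
    total = 0
    for r in range(n_rows):
        for c in range(n_cols - d):
            if mask[r, c] and mask[r, c + d]:
                counts[image[r, c], image[r, c + d]] += 1
                total += 1
    if total == 0:
        raise EmptyROIError(zone)
    return GLCMatrix(counts=counts, offset_distance=int(d), offset_angle=0.0, total_pairs=total)
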