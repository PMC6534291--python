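"""Image preprocessing: border cropping, grayscale conversion, normal scores.

A fundus photograph is surrounded by a black mask that carries no retinal
signal; :func:`crop_border` removes it.  The retained RGB content is reduced
to luminance and then marginally transformed to a standard normal
distribution, so that every image presents the same marginal field
distribution to the sub-level-set filtration and summary statistics are
comparable across cameras and exposures.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

#: ITU-R BT.601 luma coefficients for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default intensity (out of 255) below which a pixel counts as border.
DEFAULT_CROP_THRESHOLD = 10.0


class EmptyContentError(ValueError):
    """No pixel exceeds the background threshold; nothing to crop to."""


class DegenerateFieldError(ValueError):
    """The field is constant, so rank-based normal scores are undefined."""


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {image.shape}")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2 x 2 pixels")
    if np.nanmin(image) < 0 or np.nanmax(image) > 255:
        raise ValueError("channel intensities must lie in [0, 255]")
    return image


def crop_border(image: np.ndarray, background_threshold: float = DEFAULT_CROP_THRESHOLD) -> np.ndarray:
    """Crop ``image`` to the tight bounding box of non-background pixels.

    A pixel is content if its maximum channel intensity strictly exceeds
    ``background_threshold`` (0-255 scale).

    Raises
    ------
    EmptyContentError
        If every pixel is at or below the threshold.
    """
    image = _validate_rgb(image)
    if not 0 <= background_threshold <= 255:
        raise ValueError("background_threshold must lie in [0, 255]")
    content = image.max(axis=2) > background_threshold
    if not content.any():
        raise EmptyContentError("no pixel exceeds the background threshold")
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    return image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert RGB to luminance with weights 0.299 R + 0.587 G + 0.114 B."""
    image = _validate_rgb(image).astype(np.float64)
    r, g, b = LUMA_WEIGHTS
    return r * image[:, :, 0] + g * image[:, :, 1] + b * image[:, :, 2]


def normal_score_transform(field: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Rank-based normal-scores transform, centred and scaled to unit sd.

    Values are replaced by standard-normal quantiles at Blom plotting
    positions, ``Phi^{-1}((r - 3/8) / (n + 1/4))`` for rank ``r`` out of
    ``n``, then standardised to sample mean 0 and standard deviation 1.
    Ties receive average ranks, so equal inputs map to equal outputs and the
    result is invariant under any strictly increasing transform of the
    input.

    Parameters
    ----------
    field
        2D array of finite values with at least two distinct entries.
    ddof
        Delta degrees of freedom for the final scaling (1 = sample sd).

    Raises
    ------
    DegenerateFieldError
        If the field is constant.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2:
        raise ValueError(f"expected a 2D field, got shape {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    flat = field.ravel()
    if np.ptp(flat) == 0:
        raise DegenerateFieldError("constant field has no normal-scores transform")
    n = flat.size
    ranks = rankdata(flat, method="average")
    scores = norm.ppf((ranks - 0.375) / (n + 0.25))
    scores -= scores.mean()
    sd = scores.std(ddof=ddof)
    scores /= sd
    return scores.reshape(field.shape)


def standardize_image(
    image: np.ndarray,
    background_threshold: float = DEFAULT_CROP_THRESHOLD,
    crop: bool = True,
) -> np.ndarray:
    """Full preprocessing chain: crop border, grayscale, normal scores."""
    if crop:
        image = crop_border(image, background_threshold)
    return normal_score_transform(to_grayscale(image))
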