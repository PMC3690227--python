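"""Shared small helpers: validation, rounding, image IO."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rgb_array", "as_gray_array", "round_half_up"]


def as_rgb_array(image) -> np.ndarray:
    """Validate and return an 8-bit RGB image as an (H, W, 3) uint8 array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) and arr.max(initial=0.0) <= 1.0:
            raise ValueError(
                "float image in [0, 1] given; scale to [0, 255] and cast to uint8"
            )
        out_of_range = (arr < 0) | (arr > 255)
        if out_of_range.any():
            raise ValueError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_gray_array(image) -> np.ndarray:
    """Validate a single-channel image as an (H, W) array."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) single-channel image, got {arr.shape}")
    if arr.size == 0:
        raise ValueError("image must contain at least one pixel")
    return arr


def round_half_up(x, decimals: int = 0):
    """Round half away from zero at the given decimal, like hand-rounded tables.

    A 1e-9 nudge absorbs binary representation error so that quantities that
    are exact decimal halves (e.g. a mean of 0.1225) round up as they would in
    decimal arithmetic, instead of falling just below the .5 boundary in
    binary floating point.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5 + 1e-9) / factor
    return out.item() if out.ndim == 0 else out
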