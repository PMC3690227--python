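"""Three-class tissue segmentation from the hue channel.

After color normalization, normal collagenous tissue is pink (low hue),
fibrocartilaginous metaplasia is blue/purple (high hue), and the empty slide
background is near-white (little chroma, hue undefined or noisy). The
segmentation proceeds in three Otsu-thresholding steps:

1. Otsu on the hue histogram splits a rough low-hue foreground (pink plus
   part of the purple) from a rough background.
2. Within the rough background only, Otsu on the green channel recovers the
   residual purple pixels (purple is dark in G, the empty slide bright); the
   recovered pixels are merged into the foreground.
3. Otsu on the hue of foreground pixels separates NORMAL (low hue) from
   ABNORMAL (high hue).

The final label map is smoothed with a 9×9 majority (rank) filter.

Because hue is an angle, plain Otsu on the linear [0, 360) axis cannot follow
pinks that wrap past 360°; color normalization is what keeps hue ranges
stable enough for this to work, and the wrap-around remains the documented
failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_rgb_array

__all__ = [
    "TissueLabel",
    "OtsuResult",
    "rgb_to_hue",
    "hue_to_byte",
    "otsu_threshold",
    "segment_foreground",
    "segment_abnormal",
    "rank_filter",
    "extract_boundaries",
    "segment_tissue",
    "TissueSegmenter",
]


class TissueLabel(IntEnum):
    """Per-pixel tissue class. Order doubles as rank-filter tie priority."""

    BACKGROUND = 0
    NORMAL = 1
    ABNORMAL = 2


@dataclass(frozen=True)
class OtsuResult:
    """Optimal threshold and the interclass-variance decomposition at it."""

    k_star: int
    sigma_b_sq: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float


def rgb_to_hue(image):
    """Hue angle H ∈ [0, 360) per pixel, HSI convention.

    θ = arccos{ ½[(R−G)+(R−B)] / √[(R−G)² + (R−B)(G−B)] }; H = θ if B ≤ G,
    else 360 − θ. Gray pixels (R=G=B) have no defined hue and are flagged.

    Returns
    -------
    hue : (H, W) float array, degrees; 0 where undefined
    valid : (H, W) bool array, False where hue is undefined
    """
    arr = as_rgb_array(image).astype(float)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    num = 0.5 * ((r - g) + (r - b))
    den_sq = (r - g) ** 2 + (r - b) * (g - b)
    valid = den_sq > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(valid, num / np.sqrt(np.where(valid, den_sq, 1.0)), 0.0)
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(valid, hue, 0.0)
    # arccos can return 0 for B>G edge cases giving exactly 360; wrap to 0
    hue = np.where(hue >= 360.0, 0.0, hue)
    return hue, valid


def hue_to_byte(hue) -> np.ndarray:
    """Scale hue degrees [0, 360) linearly to integers [0, 255]."""
    return np.floor(np.asarray(hue, dtype=float) * (255.0 / 360.0) + 0.5).astype(np.uint8)


def otsu_threshold(values) -> OtsuResult:
    """Exhaustive Otsu threshold over integer values in [0, 255].

    Scans every k in 0..255 and maximizes the interclass variance
    σ_B²(k) = ω0·ω1·(μ0 − μ1)², where class 0 holds values ≤ k. Ties are
    broken by the smallest k.

    Raises
    ------
    ValueError
        If fewer than two distinct values are present (no separating
        threshold exists).
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("no values to threshold")
    if (values < 0).any() or (values > 255).any():
        raise ValueError("values must lie in [0, 255]")
    hist = np.bincount(values.astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("all values identical; no separating threshold exists")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    omega0 = np.cumsum(p)
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(omega0 > 0, mu_cum / omega0, 0.0)
        mu1 = np.where(omega1 > 0, (mu_total - mu_cum) / omega1, 0.0)
    sigma_b = np.where((omega0 > 0) & (omega1 > 0), omega0 * omega1 * (mu0 - mu1) ** 2, 0.0)
    k = int(np.argmax(sigma_b))  # argmax takes the first max: smallest k
    return OtsuResult(
        k_star=k,
        sigma_b_sq=float(sigma_b[k]),
        omega0=float(omega0[k]),
        omega1=float(omega1[k]),
        mu0=float(mu0[k]),
        mu1=float(mu1[k]),
    )


# Fraction above which the "low" Otsu class is assumed to be the wrong
# orientation (inverted staining) and the classes are swapped.
_INVERT_GUARD = 0.95


def _low_class_mask(values_byte, population, k_star):
    """Mask of the low class within `population`, orientation-guarded."""
    low = population & (values_byte <= k_star)
    if population.sum() > 0 and low.sum() / population.sum() > _INVERT_GUARD:
        low = population & (values_byte > k_star)
    return low


def segment_foreground(
    norm_image,
    hue=None,
    valid=None,
    *,
    min_separation: float = 30.0,
    details: dict | None = None,
) -> np.ndarray:
    """Tissue-foreground mask via the two-step hue + G-channel thresholding.

    Step 1 applies Otsu to the hue histogram (scaled to bytes; undefined-hue
    pixels are assigned to the background population): the low-hue class is
    the rough foreground. Step 2 applies Otsu to the G channel of the rough
    background only and merges the dark (low-G, purple) class back into the
    foreground.

    Step 2 only fires when the two G classes are separated by at least
    ``min_separation`` gray levels — on a background with no residual purple
    the G histogram is unimodal and an unconditional Otsu would split sensor
    noise in half.
    """
    arr = as_rgb_array(norm_image)
    if hue is None or valid is None:
        hue, valid = rgb_to_hue(arr)
    hb = hue_to_byte(hue)

    res1 = otsu_threshold(hb[valid] if valid.any() else hb)
    fg = _low_class_mask(hb, valid, res1.k_star)  # undefined hue → background
    if details is not None:
        details["hue_k_star"] = res1.k_star

    bg = ~fg
    recovered = np.zeros_like(fg)
    if bg.any():
        g = arr[..., 1].astype(np.int64)
        try:
            res2 = otsu_threshold(g[bg])
        except ValueError:
            res2 = None  # constant background: nothing to recover
        if res2 is not None and abs(res2.mu1 - res2.mu0) >= min_separation:
            recovered = _low_class_mask(g, bg, res2.k_star)
            if details is not None:
                details["g_k_star"] = res2.k_star
    return fg | recovered


def segment_abnormal(
    hue,
    foreground,
    *,
    min_separation: float = 30.0,
    details: dict | None = None,
) -> np.ndarray:
    """Split the foreground into NORMAL (low hue) and ABNORMAL (high hue).

    Otsu runs over the hue values of foreground pixels only; background
    pixels are never relabeled. If the two hue classes are closer than
    ``min_separation`` byte levels the foreground is considered uniformly
    normal (all-normal specimen), since thresholding a unimodal histogram
    would split noise.
    """
    foreground = np.asarray(foreground, dtype=bool)
    labels = np.full(foreground.shape, TissueLabel.BACKGROUND, dtype=np.uint8)
    if not foreground.any():
        return labels
    hb = hue_to_byte(hue)
    labels[foreground] = TissueLabel.NORMAL
    try:
        res = otsu_threshold(hb[foreground])
    except ValueError:
        return labels  # single hue value: all normal
    if details is not None:
        details["abnormal_k_star"] = res.k_star
    if abs(res.mu1 - res.mu0) >= min_separation:
        labels[foreground & (hb > res.k_star)] = TissueLabel.ABNORMAL
    return labels


def rank_filter(labels, window: int = 9) -> np.ndarray:
    """Majority (modal) filter over a square window, cropped at borders.

    Each pixel takes the most frequent label in its window; ties are broken
    by the fixed priority BACKGROUND > NORMAL > ABNORMAL.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and ≥ 3")
    labels = np.asarray(labels)
    kernel = np.ones((window, window))
    counts = [
        ndimage.correlate((labels == lab).astype(float), kernel, mode="constant", cval=0.0)
        for lab in TissueLabel
    ]
    # stacking in enum order + first-max argmax implements the tie priority
    return np.argmax(np.stack(counts), axis=0).astype(np.uint8)


def extract_boundaries(labels) -> np.ndarray:
    """Pixels labeled ABNORMAL with at least one 4-neighbor not ABNORMAL.

    Pixels on the image border count the outside as not-ABNORMAL, so a fully
    abnormal image yields its frame.
    """
    ab = np.asarray(labels) == TissueLabel.ABNORMAL
    pad = np.pad(ab, 1, constant_values=False)
    interior = (
        pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    )
    return ab & ~interior


def segment_tissue(
    norm_image,
    *,
    window: int = 9,
    min_separation: float = 30.0,
    details: dict | None = None,
) -> np.ndarray:
    """Full tissue segmentation: hue → foreground → abnormal split → rank filter."""
    hue, valid = rgb_to_hue(norm_image)
    fg = segment_foreground(
        norm_image, hue, valid, min_separation=min_separation, details=details
    )
    labels = segment_abnormal(hue, fg, min_separation=min_separation, details=details)
    return rank_filter(labels, window=window)


# grayscale codes used when a label map is written as an 8-bit PNG
LABEL_TO_GRAY = {TissueLabel.BACKGROUND: 0, TissueLabel.NORMAL: 128, TissueLabel.ABNORMAL: 255}
GRAY_TO_LABEL = {v: k for k, v in LABEL_TO_GRAY.items()}


def labels_to_gray(labels) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for lab, gray in LABEL_TO_GRAY.items():
        lut[int(lab)] = gray
    return lut[np.asarray(labels)]


def gray_to_labels(gray) -> np.ndarray:
    out = np.zeros(np.asarray(gray).shape, dtype=np.uint8)
    for g, lab in GRAY_TO_LABEL.items():
        out[np.asarray(gray) == g] = int(lab)
    return out


class TissueSegmenter(TransformerMixin, BaseEstimator):
    """Stateless tissue segmenter with sklearn transformer semantics.

    Parameters
    ----------
    window : int, default=9
        Side of the square majority-filter window (odd, ≥ 3).
    min_separation : float, default=30.0
        Minimum Otsu class-mean separation (gray / hue-byte levels) for the
        G-channel recovery and the normal/abnormal split to fire.

    Attributes
    ----------
    thresholds_ : dict
        Otsu thresholds chosen for the most recent image (audit log).
    """

    def __init__(self, window: int = 9, min_separation: float = 30.0):
        self.window = window
        self.min_separation = min_separation

    def fit(self, X=None, y=None):
        """No-op; segmentation has no trained state."""
        return self

    def __sklearn_is_fitted__(self):
        return True  # stateless transformer

    def transform(self, X):
        """Segment one RGB image (or a list) into a TissueLabel map."""
        if isinstance(X, (list, tuple)):
            return [self.transform(x) for x in X]
        self.thresholds_ = {}
        return segment_tissue(
            X,
            window=self.window,
            min_separation=self.min_separation,
            details=self.thresholds_,
        )
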