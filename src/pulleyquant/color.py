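"""Reinhard statistics-transfer color normalization in lαβ space.

Microscopic H&E slides from different staining batches and acquisition
sessions differ in overall color and illumination. The Reinhard method maps
an input image onto the color distribution of a small set of operator-chosen
target images: pixels are moved to the decorrelated logarithmic lαβ space
(Ruderman), where each channel of the input is shifted and scaled so that its
mean and standard deviation match the averaged target statistics, and the
result is mapped back to RGB.

The lαβ space is reached via RGB → LMS (a fixed 3×3 matrix), a logarithm, and
a fixed orthogonal decorrelating transform. Because the printed RGB↔LMS
matrices are a rounded inverse pair, a round trip reproduces 8-bit pixels
only to within a few gray levels; all statistics matching happens before the
inverse transform and is exact in floating point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_rgb_array

__all__ = [
    "RGB_TO_LMS",
    "LMS_TO_RGB",
    "LMS_TO_LAB",
    "LAB_TO_LMS",
    "ChannelStats",
    "TargetProfile",
    "rgb_to_lab",
    "lab_to_rgb",
    "compute_channel_stats",
    "build_target_profile",
    "normalize",
    "ReinhardNormalizer",
]

#: Fixed conversion from linear RGB to cone-response LMS space.
RGB_TO_LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)

#: Rounded inverse of :data:`RGB_TO_LMS` (agrees with the true inverse to ~5e-3).
LMS_TO_RGB = np.array(
    [
        [4.4679, -3.5873, 0.1193],
        [-1.2186, 2.3809, -0.1624],
        [0.0497, -0.2439, 1.2045],
    ]
)

# Decorrelating transform from log-LMS to lαβ: a diagonal scaling times an
# orthogonal mixing matrix (achromatic, yellow-blue, red-green axes).
_DIAG = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)])
_MIX = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
LMS_TO_LAB = _DIAG @ _MIX
LAB_TO_LMS = np.linalg.inv(LMS_TO_LAB)

#: Clamp applied to LMS values before the logarithm; keeps black pixels finite.
EPSILON = 1.0 / 255.0

# standard deviations below this are zero up to float error (constant channel)
_ZERO_SD_TOL = 1e-9


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation of an image in lαβ space."""

    mean: np.ndarray  # (3,) means of (l, α, β)
    sd: np.ndarray  # (3,) standard deviations, ≥ 0

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != (3,) or self.sd.shape != (3,):
            raise ValueError("mean and sd must each hold three channel values")
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class TargetProfile:
    """Averaged lαβ statistics of the target-image set.

    The six numbers (three means, three SDs) fully define the normalization;
    a profile is computed once and reused for every input image. A profile
    with any zero spread is rejected as degenerate.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_targets: int = 1

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != (3,) or self.sd.shape != (3,):
            raise ValueError("mean and sd must each hold three channel values")
        if (self.sd <= 0).any():
            raise ValueError("a target profile must have strictly positive spread")
        if self.n_targets < 1:
            raise ValueError("n_targets must be ≥ 1")

    def to_dict(self) -> dict:
        return {
            "mean_l": float(self.mean[0]),
            "mean_alpha": float(self.mean[1]),
            "mean_beta": float(self.mean[2]),
            "sd_l": float(self.sd[0]),
            "sd_alpha": float(self.sd[1]),
            "sd_beta": float(self.sd[2]),
            "n_targets": int(self.n_targets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetProfile":
        return cls(
            mean=[d["mean_l"], d["mean_alpha"], d["mean_beta"]],
            sd=[d["sd_l"], d["sd_alpha"], d["sd_beta"]],
            n_targets=int(d.get("n_targets", 1)),
        )

    def save(self, path) -> None:
        """Serialize to YAML or JSON, chosen by file extension."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "TargetProfile":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def rgb_to_lab(image) -> np.ndarray:
    """Convert an 8-bit RGB image to lαβ.

    LMS values are clamped to EPSILON before the (natural) logarithm so that
    black pixels map to finite coordinates.
    """
    arr = as_rgb_array(image).astype(float)
    lms = arr @ RGB_TO_LMS.T
    lms = np.maximum(lms, EPSILON)
    return np.log(lms) @ LMS_TO_LAB.T


def lab_to_rgb(lab) -> np.ndarray:
    """Invert :func:`rgb_to_lab` back to a clipped, quantized 8-bit RGB image."""
    lab = np.asarray(lab, dtype=float)
    lms = np.exp(lab @ LAB_TO_LMS.T)
    rgb = lms @ LMS_TO_RGB.T
    rgb = np.clip(rgb, 0.0, 255.0)
    return np.floor(rgb + 0.5).astype(np.uint8)  # round half-up


def compute_channel_stats(lab) -> ChannelStats:
    """Per-channel mean and (population) standard deviation over all pixels."""
    lab = np.asarray(lab, dtype=float)
    flat = lab.reshape(-1, 3)
    if flat.shape[0] < 1:
        raise ValueError("image must contain at least one pixel")
    return ChannelStats(mean=flat.mean(axis=0), sd=flat.std(axis=0))


def build_target_profile(targets) -> TargetProfile:
    """Average the per-image lαβ statistics of the target-image set.

    Each of the six statistics is the arithmetic mean across target images of
    that image's own value.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("at least one target image is required")
    stats = [compute_channel_stats(rgb_to_lab(t)) for t in targets]
    mean = np.mean([s.mean for s in stats], axis=0)
    sd = np.mean([s.sd for s in stats], axis=0)
    if (sd <= _ZERO_SD_TOL).any():
        raise ValueError(
            "target images have zero spread on some lαβ channel; "
            "choose targets with non-constant color"
        )
    return TargetProfile(mean=mean, sd=sd, n_targets=len(targets))


def _match_stats(lab: np.ndarray, profile: TargetProfile, on_zero_sd: str) -> np.ndarray:
    src = compute_channel_stats(lab)
    sd = src.sd.copy()
    zero = sd <= _ZERO_SD_TOL
    if zero.any():
        if on_zero_sd == "identity":
            sd[zero] = profile.sd[zero]  # makes σ_t/σ_s = 1 on the flat channel
        else:
            raise ValueError(
                "source image has zero spread on an lαβ channel; "
                "pass on_zero_sd='identity' to skip scaling there"
            )
    return (lab - src.mean) * (profile.sd / sd) + profile.mean


def normalize(image, profile: TargetProfile, *, on_zero_sd: str = "raise") -> np.ndarray:
    """Map an RGB image onto the target color distribution.

    In lαβ space each channel is recentered and rescaled so its statistics
    equal the profile exactly; the result is transformed back to 8-bit RGB
    (clipped to [0, 255], rounded half-up).

    Parameters
    ----------
    on_zero_sd : {"raise", "identity"}
        What to do when the source image has zero spread on a channel:
        raise (default), or keep that channel unscaled.
    """
    if on_zero_sd not in ("raise", "identity"):
        raise ValueError("on_zero_sd must be 'raise' or 'identity'")
    lab = rgb_to_lab(image)
    return lab_to_rgb(_match_stats(lab, profile, on_zero_sd))


class ReinhardNormalizer(TransformerMixin, BaseEstimator):
    """Stain/color normalizer: fit on target images, transform inputs.

    Parameters
    ----------
    on_zero_sd : {"raise", "identity"}, default="raise"
        Handling of source images that are constant on an lαβ channel.

    Attributes
    ----------
    profile_ : TargetProfile
        Averaged target statistics computed by :meth:`fit`.

    Examples
    --------
    >>> norm = ReinhardNormalizer().fit([target_img])       # doctest: +SKIP
    >>> out = norm.transform(source_img)                    # doctest: +SKIP
    """

    def __init__(self, on_zero_sd: str = "raise"):
        self.on_zero_sd = on_zero_sd

    def fit(self, X, y=None):
        """Build the target profile from one image or a list of images."""
        images = X if isinstance(X, (list, tuple)) else [X]
        self.profile_ = build_target_profile(images)
        return self

    def transform(self, X):
        """Normalize one image or a list of images."""
        if not hasattr(self, "profile_"):
            raise AttributeError("ReinhardNormalizer is not fitted yet; call fit first")
        if isinstance(X, (list, tuple)):
            return [normalize(x, self.profile_, on_zero_sd=self.on_zero_sd) for x in X]
        return normalize(X, self.profile_, on_zero_sd=self.on_zero_sd)
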