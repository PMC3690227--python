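"""Nuclei segmentation (active double thresholding) and shape classification.

Nuclei are the darkest structures in the R channel of a color-normalized H&E
image. Because absolute intensity varies between slides, the two hysteresis
thresholds are set adaptively: the mean of the ten lowest pixel intensities
anchors the image's dark end, and fixed offsets (+30 for seeds, +45 for
growth) define the double threshold. Seed pixels start 8-connected region
growing that may expand into any pixel below the growth threshold.

Each segmented component is then classified from three shape features:

* area (pixel count),
* circularity 4πA/P² (≈1 for a disc, small for elongated shapes),
* the ratio of maximum to minimum centroid-to-boundary distance.

A component is a NORMAL_ROD (elongated fibroblast nucleus) iff circularity
< 0.95, distance ratio > 3 and area < 2000 px; otherwise it is abnormal —
a single round (chondrocyte-like) nucleus if its area is < 2000 px, else a
multinucleus cluster whose nucleus count is estimated by dividing its area
by the image's mean single-round-nucleus area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_gray_array, as_rgb_array

__all__ = [
    "DoubleThresholdParams",
    "ClassifierRules",
    "NucleusClass",
    "NucleusRegion",
    "NucleiSummary",
    "active_double_threshold",
    "compute_shape_features",
    "classify_nucleus",
    "count_cluster_nuclei",
    "summarize_nuclei",
    "analyze_nuclei",
    "regions_to_dataframe",
    "NucleiAnalyzer",
]

logger = logging.getLogger(__name__)

MIN_REGION_AREA = 5  # components smaller than this are discarded as noise


@dataclass(frozen=True)
class DoubleThresholdParams:
    """Adaptive hysteresis thresholds anchored at the image's dark end."""

    n_lowest: int = 10
    offset_seed: float = 30.0
    offset_grow: float = 45.0

    def __post_init__(self):
        if self.n_lowest < 1:
            raise ValueError("n_lowest must be ≥ 1")
        if not 0 < self.offset_seed < self.offset_grow:
            raise ValueError("offsets must satisfy 0 < offset_seed < offset_grow")


@dataclass(frozen=True)
class ClassifierRules:
    """Rod-vs-round decision rules on the three shape features."""

    circularity_max: float = 0.95
    elongation_min: float = 3.0
    area_max: float = 2000.0

    def __post_init__(self):
        if min(self.circularity_max, self.elongation_min, self.area_max) <= 0:
            raise ValueError("all rule values must be strictly positive")


class NucleusClass(str, Enum):
    NORMAL_ROD = "normal_rod"
    ABNORMAL_ROUND = "abnormal_round"
    ABNORMAL_CLUSTER = "abnormal_cluster"


@dataclass
class NucleusRegion:
    """One connected nucleus component with its shape features."""

    id: int
    coords: np.ndarray  # (n, 2) row/col pixel coordinates
    area: int
    perimeter: float
    circularity: float
    centroid: tuple  # (row, col)
    d_max: float
    d_min: float
    centroid_outside: bool = False
    n_nuclei: int = 1
    label: NucleusClass | None = None

    @property
    def elongation(self) -> float:
        return self.d_max / self.d_min


@dataclass(frozen=True)
class NucleiSummary:
    """Per-image nucleus counts feeding the abnormal-nucleus number ratio."""

    n_normal: int
    n_abnormal: int
    mean_single_round_area: float = float("nan")


def active_double_threshold(r_channel, params: DoubleThresholdParams | None = None,
                            *, base_out: list | None = None) -> np.ndarray:
    """Hysteresis nucleus mask from a single-channel intensity image.

    base = mean of the ``n_lowest`` darkest pixels; seeds are pixels at most
    ``base + offset_seed``; the mask is the union of the 8-connected
    components of {intensity ≤ base + offset_grow} that contain a seed.
    """
    img = as_gray_array(r_channel).astype(float)
    params = params or DoubleThresholdParams()
    if img.size < params.n_lowest:
        raise ValueError("image smaller than n_lowest pixels")
    flat = img.ravel()
    base = float(np.partition(flat, params.n_lowest - 1)[: params.n_lowest].mean())
    if base_out is not None:
        base_out.append(base)
    seeds = img <= base + params.offset_seed
    if not seeds.any():
        return np.zeros_like(img, dtype=bool)
    grow = img <= base + params.offset_grow
    comp = measure.label(grow, connectivity=2)
    seeded_ids = np.unique(comp[seeds])
    seeded_ids = seeded_ids[seeded_ids != 0]
    return np.isin(comp, seeded_ids)


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Pixels of the component with at least one 4-neighbor outside it."""
    pad = np.pad(mask, 1, constant_values=False)
    interior = pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    return mask & ~interior


def compute_shape_features(coords, region_id: int = 0) -> NucleusRegion:
    """Shape features of one connected component given its pixel coordinates.

    Perimeter is the weighted outer-contour length (diagonal steps count √2,
    via scikit-image); circularity is 4πA/P². Centroid-to-boundary distances
    use boundary pixel centers, with d_min floored at half a pixel so that
    degenerate one-pixel-wide components stay finite. A centroid falling
    outside the pixel set (strongly concave region) is flagged but the
    distances are computed as stated regardless.
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of row/col pixels")
    area = coords.shape[0]
    if area < MIN_REGION_AREA:
        raise ValueError(f"component area {area} below minimum {MIN_REGION_AREA}")

    rmin, cmin = coords.min(axis=0)
    local = coords - [rmin, cmin]
    mask = np.zeros(local.max(axis=0) + 1, dtype=bool)
    mask[local[:, 0], local[:, 1]] = True

    perimeter = float(measure.perimeter(mask, neighborhood=4))
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.inf
    centroid = local.mean(axis=0)
    boundary = np.argwhere(_boundary_mask(mask))
    d = np.hypot(boundary[:, 0] - centroid[0], boundary[:, 1] - centroid[1])
    d_max = float(d.max())
    d_min = float(max(d.min(), 0.5))
    cr, cc = np.floor(centroid + 0.5).astype(int)
    centroid_outside = not mask[cr, cc]
    return NucleusRegion(
        id=region_id,
        coords=coords,
        area=int(area),
        perimeter=perimeter,
        circularity=float(circularity),
        centroid=(float(centroid[0] + rmin), float(centroid[1] + cmin)),
        d_max=d_max,
        d_min=d_min,
        centroid_outside=centroid_outside,
    )


def classify_nucleus(region: NucleusRegion, rules: ClassifierRules | None = None) -> NucleusRegion:
    """Assign the rod / round / cluster label from the shape features."""
    rules = rules or ClassifierRules()
    is_rod = (
        region.circularity < rules.circularity_max
        and region.elongation > rules.elongation_min
        and region.area < rules.area_max
    )
    if is_rod:
        region.label = NucleusClass.NORMAL_ROD
    elif region.area < rules.area_max:
        region.label = NucleusClass.ABNORMAL_ROUND
    else:
        region.label = NucleusClass.ABNORMAL_CLUSTER
    return region


def count_cluster_nuclei(cluster: NucleusRegion, mean_single_round_area: float) -> int:
    """Estimate nuclei in a multinucleus cluster as area / mean single area.

    Rounded half-up, floored at 1.
    """
    if mean_single_round_area <= 0:
        raise ValueError("mean_single_round_area must be positive")
    return max(1, int(np.floor(cluster.area / mean_single_round_area + 0.5)))


def summarize_nuclei(regions) -> NucleiSummary:
    """Count normal and abnormal nuclei over classified regions.

    Abnormal counts include one per single round nucleus plus the estimated
    per-cluster nucleus counts.
    """
    n_normal = sum(1 for r in regions if r.label is NucleusClass.NORMAL_ROD)
    singles = [r for r in regions if r.label is NucleusClass.ABNORMAL_ROUND]
    clusters = [r for r in regions if r.label is NucleusClass.ABNORMAL_CLUSTER]
    n_abnormal = len(singles) + sum(r.n_nuclei for r in clusters)
    mean_area = float(np.mean([r.area for r in singles])) if singles else float("nan")
    return NucleiSummary(n_normal=n_normal, n_abnormal=n_abnormal,
                         mean_single_round_area=mean_area)


def analyze_nuclei(
    r_channel,
    params: DoubleThresholdParams | None = None,
    rules: ClassifierRules | None = None,
    *,
    details: dict | None = None,
) -> list[NucleusRegion]:
    """Full per-image nucleus workflow: segment, measure, classify, count.

    Cluster nucleus counts use the mean area of this image's single round
    nuclei; with no single round nucleus present each cluster counts as one
    (logged as a warning).
    """
    base_out: list = []
    mask = active_double_threshold(r_channel, params, base_out=base_out)
    if details is not None and base_out:
        details["double_threshold_base"] = base_out[0]
    labeled = measure.label(mask, connectivity=2)
    regions = []
    for i, props in enumerate(measure.regionprops(labeled), start=1):
        if props.area < MIN_REGION_AREA:
            continue
        region = compute_shape_features(props.coords, region_id=i)
        regions.append(classify_nucleus(region, rules))
    singles = [r.area for r in regions if r.label is NucleusClass.ABNORMAL_ROUND]
    clusters = [r for r in regions if r.label is NucleusClass.ABNORMAL_CLUSTER]
    if clusters:
        if singles:
            mean_area = float(np.mean(singles))
            for r in clusters:
                r.n_nuclei = count_cluster_nuclei(r, mean_area)
        else:
            logger.warning(
                "no single round nuclei in image; counting each of %d clusters as 1",
                len(clusters),
            )
            for r in clusters:
                r.n_nuclei = 1
    return regions


def regions_to_dataframe(regions) -> pd.DataFrame:
    """Per-nucleus table (one row per component) for CSV export."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "area": r.area,
                "perimeter": r.perimeter,
                "circularity": r.circularity,
                "d_max": r.d_max,
                "d_min": r.d_min,
                "label": r.label.value if r.label else "",
                "n_nuclei": r.n_nuclei,
            }
            for r in regions
        ],
        columns=["id", "area", "perimeter", "circularity", "d_max", "d_min", "label", "n_nuclei"],
    )


def render_nuclei_overlay(image, regions) -> np.ndarray:
    """Overlay nucleus boundaries on the image: red = normal, green = abnormal."""
    out = as_rgb_array(image).copy()
    for r in regions:
        rows, cols = r.coords[:, 0], r.coords[:, 1]
        mask = np.zeros(out.shape[:2], dtype=bool)
        mask[rows, cols] = True
        edge = _boundary_mask(mask)
        color = (255, 0, 0) if r.label is NucleusClass.NORMAL_ROD else (0, 255, 0)
        out[edge] = color
    return out


class NucleiAnalyzer(TransformerMixin, BaseEstimator):
    """Nucleus segmentation + classification with transformer semantics.

    Accepts an RGB image (the R channel is extracted, per the normalized-image
    workflow) or a single-channel grayscale image.

    Parameters mirror :class:`DoubleThresholdParams` and
    :class:`ClassifierRules`.

    Attributes
    ----------
    regions_ : list of NucleusRegion
        Classified components of the most recent image.
    """

    def __init__(
        self,
        n_lowest: int = 10,
        offset_seed: float = 30.0,
        offset_grow: float = 45.0,
        circularity_max: float = 0.95,
        elongation_min: float = 3.0,
        area_max: float = 2000.0,
    ):
        self.n_lowest = n_lowest
        self.offset_seed = offset_seed
        self.offset_grow = offset_grow
        self.circularity_max = circularity_max
        self.elongation_min = elongation_min
        self.area_max = area_max

    def _params(self):
        return DoubleThresholdParams(self.n_lowest, self.offset_seed, self.offset_grow)

    def _rules(self):
        return ClassifierRules(self.circularity_max, self.elongation_min, self.area_max)

    def fit(self, X=None, y=None):
        """No-op; nucleus analysis has no trained state."""
        return self

    def __sklearn_is_fitted__(self):
        return True  # stateless transformer

    def transform(self, X) -> NucleiSummary:
        """Analyze one image and return its :class:`NucleiSummary`."""
        arr = np.asarray(X)
        gray = arr[..., 0] if arr.ndim == 3 else arr  # R channel of RGB input
        self.regions_ = analyze_nuclei(gray, self._params(), self._rules())
        return summarize_nuclei(self.regions_)
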