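"""Seeded synthetic H&E-like pulley images with exact ground truth.

Real annotated pulley slides are not publicly available, so every pipeline
stage is validated against rendered images whose tissue label map, nucleus
masks and class labels are known by construction. An image consists of:

* a near-white slide background with a faint bluish tint (a perfectly
  neutral gray background would have noise-dominated, uniformly random hue,
  which no hue-threshold method — nor real microscopy — exhibits);
* parallel pink collagen-fiber bands with small per-band color jitter,
  rendered so the pink stays on the low-hue side (B < G);
* purple elliptical metaplastic patches covering approximately the requested
  fraction of the tissue;
* planted non-overlapping dark-blue nuclei: elongated ellipses (rods,
  normal fibroblasts) in pink tissue and discs (round, chondrocyte-like)
  inside the purple patches;
* a multiplicative illumination gradient, an additive color cast, and
  Gaussian noise.

Identical seeds give bitwise-identical images; all randomness flows through
one local generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw
from scipy import ndimage

from .segmentation import TissueLabel, labels_to_gray

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SpecimenImages",
    "generate_image",
    "generate_specimen_set",
    "write_dataset",
    "STAGE_FRACTIONS",
    "STAGE_ROUND_SHARE",
]

# per-stage ranges for the abnormal tissue-area fraction
STAGE_FRACTIONS = {"H": (0.24, 0.28), "M": (0.18, 0.22), "L": (0.06, 0.16)}
# per-stage ranges for the share of round nuclei among all planted nuclei
STAGE_ROUND_SHARE = {"H": (0.66, 0.80), "M": (0.58, 0.66), "L": (0.42, 0.58)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Rendering parameters; the defaults define the standard test conditions."""

    width: int = 512
    height: int = 512
    abnormal_area_fraction: float = 0.25
    n_rod_nuclei: int = 40
    n_round_nuclei: int = 20
    rod_major_range: tuple = (10.0, 16.0)  # semi-axes, px
    rod_minor_range: tuple = (1.6, 2.4)
    round_radius_range: tuple = (5.0, 8.0)
    pink: tuple = (235, 150, 125)
    purple: tuple = (140, 90, 160)
    nucleus_color: tuple = (60, 50, 110)
    background: tuple = (240, 242, 253)
    margin: int = 24
    illumination_amplitude: float = 0.05
    color_cast: tuple = (0, 0, 0)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("image must be at least 64×64")
        if not 0.0 <= self.abnormal_area_fraction <= 1.0:
            raise ValueError("abnormal_area_fraction must lie in [0, 1]")
        if self.n_rod_nuclei < 0 or self.n_round_nuclei < 0:
            raise ValueError("nucleus counts must be non-negative")


@dataclass
class GroundTruth:
    """Exact per-pixel truth for a rendered image."""

    tissue_labels: np.ndarray  # uint8 TissueLabel map
    nucleus_labels: np.ndarray  # int32, 0 = no nucleus, i = i-th planted nucleus
    nucleus_classes: list  # "rod" or "round" per planted nucleus, 1-indexed
    abnormal_fraction: float  # realized abnormal / (normal + abnormal) tissue area
    n_rod: int
    n_round: int


@dataclass
class SpecimenImages:
    """A simulated specimen: several fields of view with shared stage."""

    specimen_id: str
    stage: str
    images: list  # of (rgb uint8 array, GroundTruth)
    fractions: list  # requested abnormal fraction per image


def _paint_fiber_bands(img, tissue, cfg, rng):
    """Horizontal pink bands with per-band jitter keeping B < G (low hue)."""
    h = img.shape[0]
    row = 0
    while row < h:
        band = int(rng.integers(8, 17))
        jitter = rng.integers(-6, 7, size=3)
        color = np.array(cfg.pink, dtype=int) + jitter
        color[2] = min(color[2], color[1] - 4)  # hue stays on the pink side
        color = np.clip(color, 0, 255)
        sel = tissue[row : row + band, :]
        img[row : row + band, :][sel] = color
        row += band


def _add_purple_patches(img, tissue, cfg, rng):
    """Union of random ellipses covering ≈ the requested tissue fraction."""
    abnormal = np.zeros(tissue.shape, dtype=bool)
    tissue_area = int(tissue.sum())
    target = cfg.abnormal_area_fraction * tissue_area
    if target <= 0:
        return abnormal
    coords = np.argwhere(tissue)
    max_patch = max(np.pi * 12**2, 0.08 * tissue_area)
    for _ in range(1000):
        deficit = target - abnormal.sum()
        if deficit / tissue_area <= 0.005:
            break
        area_draw = min(deficit * float(rng.uniform(0.5, 1.05)), max_patch)
        r_eq = max(np.sqrt(area_draw / np.pi), 4.0)
        u = float(rng.uniform(0.8, 1.4))
        cy, cx = coords[rng.integers(len(coords))]
        rr, cc = draw.ellipse(
            cy, cx, r_eq * u, r_eq / u,
            rotation=float(rng.uniform(0, np.pi)), shape=tissue.shape,
        )
        keep = tissue[rr, cc]
        abnormal[rr[keep], cc[keep]] = True
    jitter_base = np.array(cfg.purple, dtype=int)
    # per-patch-free gentle mottling: vary purple slightly per connected blob
    lab, n = ndimage.label(abnormal)
    for i in range(1, n + 1):
        color = np.clip(jitter_base + rng.integers(-5, 6, size=3), 0, 255)
        img[lab == i] = color
    return abnormal


def _place_nuclei(img, gt_labels, allowed, occupied, n, shape_sampler, color, rng,
                  nucleus_labels, classes, class_name, max_retries=400):
    """Plant n non-overlapping nuclei fully inside `allowed`; error if impossible."""
    coords = np.argwhere(allowed)
    if len(coords) == 0 and n > 0:
        raise ValueError(f"no room to place {class_name} nuclei")
    for _ in range(n):
        for attempt in range(max_retries):
            cy, cx = coords[rng.integers(len(coords))]
            rr, cc = shape_sampler(cy, cx, rng)
            if rr.size == 0:
                continue
            inside = (
                (rr >= 0) & (rr < allowed.shape[0]) & (cc >= 0) & (cc < allowed.shape[1])
            )
            if not inside.all():
                continue
            if not allowed[rr, cc].all():
                continue
            if occupied[rr, cc].any():
                continue
            idx = len(classes) + 1
            jittered = np.clip(np.array(color, dtype=int) + rng.integers(-5, 6, 3), 0, 255)
            img[rr, cc] = jittered
            nucleus_labels[rr, cc] = idx
            # reserve a 2-px moat so planted nuclei never touch
            moat = np.zeros(allowed.shape, dtype=bool)
            moat[rr, cc] = True
            occupied |= ndimage.binary_dilation(moat, iterations=3)
            classes.append(class_name)
            break
        else:
            raise ValueError(
                f"could not place {class_name} nucleus after {max_retries} retries"
            )


def generate_image(config: SyntheticConfig | None = None, **overrides):
    """Render one synthetic pulley field of view.

    Returns
    -------
    (image, truth) : (uint8 (H, W, 3) array, GroundTruth)
    """
    cfg = replace(config or SyntheticConfig(), **overrides)
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width

    img = np.empty((h, w, 3), dtype=int)
    img[...] = cfg.background
    tissue = np.zeros((h, w), dtype=bool)
    m = cfg.margin
    tissue[m : h - m, m : w - m] = True

    _paint_fiber_bands(img, tissue, cfg, rng)
    abnormal = _add_purple_patches(img, tissue, cfg, rng)

    labels = np.full((h, w), int(TissueLabel.BACKGROUND), dtype=np.uint8)
    labels[tissue] = int(TissueLabel.NORMAL)
    labels[abnormal] = int(TissueLabel.ABNORMAL)

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    classes: list = []
    occupied = np.zeros((h, w), dtype=bool)

    # rods live in pink tissue, clear of the purple patches
    rod_zone = tissue & ~ndimage.binary_dilation(abnormal, iterations=3)
    rod_zone = ndimage.binary_erosion(rod_zone, iterations=2)

    def rod_sampler(cy, cx, rng):
        a = float(rng.uniform(*cfg.rod_major_range))
        b = float(rng.uniform(*cfg.rod_minor_range))
        rot = float(rng.uniform(0, np.pi))
        return draw.ellipse(cy, cx, a, b, rotation=rot)

    def disc_sampler(cy, cx, rng):
        r = float(rng.uniform(*cfg.round_radius_range))
        return draw.disk((cy, cx), r)

    # discs live inside the purple patches when there is room, else in tissue
    disc_zone = ndimage.binary_erosion(abnormal, iterations=2)
    need = cfg.n_round_nuclei * np.pi * max(cfg.round_radius_range) ** 2 * 4
    if disc_zone.sum() < need:
        disc_zone = ndimage.binary_erosion(tissue, iterations=2)

    _place_nuclei(img, labels, rod_zone, occupied, cfg.n_rod_nuclei, rod_sampler,
                  cfg.nucleus_color, rng, nucleus_labels, classes, "rod")
    _place_nuclei(img, labels, disc_zone, occupied, cfg.n_round_nuclei, disc_sampler,
                  cfg.nucleus_color, rng, nucleus_labels, classes, "round")

    out = img.astype(float)
    if cfg.illumination_amplitude:
        ramp = 1.0 + cfg.illumination_amplitude * np.linspace(-1.0, 1.0, w)
        out *= ramp[None, :, None]
    out += np.asarray(cfg.color_cast, dtype=float)
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    out = np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)

    tissue_area = int(tissue.sum())
    truth = GroundTruth(
        tissue_labels=labels,
        nucleus_labels=nucleus_labels,
        nucleus_classes=classes,
        abnormal_fraction=float(abnormal.sum()) / tissue_area,
        n_rod=classes.count("rod"),
        n_round=classes.count("round"),
    )
    return out, truth


def generate_specimen_set(
    n_specimens: int = 3,
    images_per_specimen: int = 2,
    stage_fractions: dict | None = None,
    stage_round_share: dict | None = None,
    total_nuclei: int = 40,
    seed: int = 0,
    **config_overrides,
):
    """Simulate specimens with stage-dependent severity.

    Stages cycle H, M, L across specimens. Each image's abnormal area
    fraction is drawn uniformly from its stage's range, and the rod/round
    nucleus mix from the stage's round-share range. Ranges must be ordered
    H above M above L without overlap.
    """
    fr = dict(stage_fractions or STAGE_FRACTIONS)
    sh = dict(stage_round_share or STAGE_ROUND_SHARE)
    for ranges in (fr, sh):
        for a, b in (("H", "M"), ("M", "L")):
            if not (ranges[a][0] >= ranges[b][1] and ranges[a][0] <= ranges[a][1]
                    and ranges[b][0] <= ranges[b][1]):
                raise ValueError("stage ranges must be ordered H > M > L and non-empty")
    rng = np.random.default_rng(seed)
    stages = ["H", "M", "L"]
    specimens = []
    for s in range(n_specimens):
        stage = stages[s % 3]
        images, fractions = [], []
        for _ in range(images_per_specimen):
            frac = float(rng.uniform(*fr[stage]))
            share = float(rng.uniform(*sh[stage]))
            n_round = int(round(total_nuclei * share))
            cfg = SyntheticConfig(
                abnormal_area_fraction=frac,
                n_rod_nuclei=total_nuclei - n_round,
                n_round_nuclei=n_round,
                seed=int(rng.integers(2**31)),
                **config_overrides,
            )
            images.append(generate_image(cfg))
            fractions.append(frac)
        specimens.append(
            SpecimenImages(
                specimen_id=f"{stage}-{s // 3 + 1}", stage=stage,
                images=images, fractions=fractions,
            )
        )
    return specimens


def write_dataset(specimens, out_dir) -> pd.DataFrame:
    """Write images, ground-truth label PNGs and a manifest CSV."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for specimen in specimens:
        for i, ((image, truth), frac) in enumerate(zip(specimen.images, specimen.fractions), 1):
            stem = f"{specimen.specimen_id}_img{i:02d}"
            img_path = out_dir / f"{stem}.png"
            gt_path = out_dir / f"{stem}_labels.png"
            iio.imwrite(img_path, image)
            iio.imwrite(gt_path, labels_to_gray(truth.tissue_labels))
            rows.append(
                {
                    "image": img_path.name,
                    "labels": gt_path.name,
                    "specimen": specimen.specimen_id,
                    "stage": specimen.stage,
                    "requested_fraction": frac,
                    "true_fraction": truth.abnormal_fraction,
                    "n_rod": truth.n_rod,
                    "n_round": truth.n_round,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
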