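"""End-to-end pipeline: images in, per-image / per-specimen reports out.

Stage order per image: color normalization → tissue segmentation →
nuclei segmentation/classification → one ImageMeasurement row. Rows are
aggregated per specimen (sum-then-ratio), and when pathologist stage labels
covering H, M and L are provided the group summaries, midpoint cuts,
predicted stages and pairwise Welch tests are produced as well.

Every run logs the thresholds chosen per image (Otsu k*, double-threshold
base) and ends with an integrity check asserting that each per-specimen
number is recomputable from the per-image table.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .color import ReinhardNormalizer, TargetProfile
from .nuclei import (
    NucleiAnalyzer,
    regions_to_dataframe,
    render_nuclei_overlay,
    summarize_nuclei,
)
from .quantify import ImageMeasurement, aggregate_specimen, severity_report
from .segmentation import (
    TissueLabel,
    TissueSegmenter,
    extract_boundaries,
    labels_to_gray,
)

__all__ = ["PipelineConfig", "run_pipeline", "measure_image", "quantify_measurements"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    manifest: str = ""  # CSV: image path, specimen id, optional stage
    output_dir: str = "pulleyquant_out"
    target_images: list = field(default_factory=list)
    profile_path: str = ""  # serialized TargetProfile; overrides target_images
    window: int = 9
    min_separation: float = 30.0
    n_lowest: int = 10
    offset_seed: float = 30.0
    offset_grow: float = 45.0
    circularity_max: float = 0.95
    elongation_min: float = 3.0
    area_max: float = 2000.0
    decimals: int = 3
    write_overlays: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("rank-filter window must be odd and ≥ 3")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def measure_image(norm_image, segmenter: TissueSegmenter, analyzer: NucleiAnalyzer):
    """Segment tissue and nuclei in one normalized image.

    Returns
    -------
    (measurement, labels, regions, details)
    """
    labels = segmenter.transform(norm_image)
    details = dict(segmenter.thresholds_)
    summary = analyzer.transform(norm_image)
    regions = analyzer.regions_
    measurement = ImageMeasurement(
        area_normal=int((labels == TissueLabel.NORMAL).sum()),
        area_abnormal=int((labels == TissueLabel.ABNORMAL).sum()),
        n_normal=summary.n_normal,
        n_abnormal=summary.n_abnormal,
    )
    return measurement, labels, regions, details


def _load_profile(config: PipelineConfig) -> TargetProfile:
    if config.profile_path:
        return TargetProfile.load(config.profile_path)
    if not config.target_images:
        raise ValueError("either profile_path or target_images must be given")
    targets = [iio.imread(p)[..., :3] for p in config.target_images]
    return ReinhardNormalizer().fit(targets).profile_


def _boundary_overlay(norm_image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = norm_image.copy()
    out[extract_boundaries(labels)] = (255, 255, 0)
    return out


def quantify_measurements(per_image: pd.DataFrame, *, decimals: int = 3) -> dict:
    """Aggregate a per-image measurement table and run the downstream analysis.

    ``per_image`` needs columns specimen, area_normal, area_abnormal,
    n_normal, n_abnormal, and optionally stage. Tables that are already per
    specimen (one row each) pass through the same sums unchanged.
    """
    grouped = per_image.groupby("specimen", sort=False)
    rows = []
    for specimen, g in grouped:
        stage = g["stage"].iloc[0] if "stage" in g else None
        rows.append(
            {
                "specimen": specimen,
                "stage": stage,
                "area_normal": g["area_normal"].sum(),
                "area_abnormal": g["area_abnormal"].sum(),
                "n_normal": g["n_normal"].sum(),
                "n_abnormal": g["n_abnormal"].sum(),
            }
        )
    specimens = pd.DataFrame(rows)
    stages = set(specimens["stage"].dropna()) if "stage" in specimens else set()
    if {"H", "M", "L"} <= stages:
        return severity_report(specimens, decimals=decimals)
    # without all three diseased stages only the ratios are computable
    from .quantify import parameter1, parameter2

    specimens["parameter1"] = [
        parameter1(an, aa)
        for an, aa in zip(specimens["area_normal"], specimens["area_abnormal"])
    ]
    specimens["parameter2"] = [
        parameter2(nn, na)
        for nn, na in zip(specimens["n_normal"], specimens["n_abnormal"])
    ]
    return {"specimens": specimens, "groups": None, "thresholds": None,
            "misclassified": None, "comparisons": None}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report dict."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest)
    if "image" not in manifest or "specimen" not in manifest:
        raise ValueError("manifest must have 'image' and 'specimen' columns")
    base = Path(config.manifest).parent

    profile = _load_profile(config)
    normalizer = ReinhardNormalizer()
    normalizer.profile_ = profile
    segmenter = TissueSegmenter(window=config.window, min_separation=config.min_separation)
    analyzer = NucleiAnalyzer(
        n_lowest=config.n_lowest,
        offset_seed=config.offset_seed,
        offset_grow=config.offset_grow,
        circularity_max=config.circularity_max,
        elongation_min=config.elongation_min,
        area_max=config.area_max,
    )

    per_image_rows = []
    for _, row in manifest.iterrows():
        path = Path(row["image"])
        if not path.is_absolute():
            path = base / path
        try:
            image = iio.imread(path)[..., :3]
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"cannot read image {path}") from exc
        norm = normalizer.transform(image)
        m, labels, regions, details = measure_image(norm, segmenter, analyzer)
        logger.info("image %s thresholds: %s", path.name, details)
        per_image_rows.append(
            {
                "image": row["image"],
                "specimen": row["specimen"],
                "stage": row.get("stage", None),
                "area_normal": m.area_normal,
                "area_abnormal": m.area_abnormal,
                "n_normal": m.n_normal,
                "n_abnormal": m.n_abnormal,
                **details,
            }
        )
        if config.write_overlays:
            stem = path.stem
            iio.imwrite(out_dir / f"{stem}_normalized.png", norm)
            iio.imwrite(out_dir / f"{stem}_labels.png", labels_to_gray(labels))
            iio.imwrite(out_dir / f"{stem}_tissue_overlay.png",
                        _boundary_overlay(norm, labels))
            iio.imwrite(out_dir / f"{stem}_nuclei_overlay.png",
                        render_nuclei_overlay(norm, regions))
            regions_to_dataframe(regions).to_csv(out_dir / f"{stem}_nuclei.csv", index=False)

    per_image = pd.DataFrame(per_image_rows)
    report = quantify_measurements(per_image, decimals=config.decimals)
    _check_integrity(per_image, report["specimens"])

    per_image.to_csv(out_dir / "per_image.csv", index=False)
    report["specimens"].to_csv(out_dir / "per_specimen.csv", index=False)
    if report["groups"] is not None:
        report["groups"].to_csv(out_dir / "group_summary.csv", index=False)
        report["comparisons"].to_csv(out_dir / "comparisons.csv", index=False)
    report["per_image"] = per_image
    return report


def _check_integrity(per_image: pd.DataFrame, specimens: pd.DataFrame) -> None:
    """Every per-specimen number must be recomputable from the per-image rows."""
    for _, row in specimens.iterrows():
        g = per_image[per_image["specimen"] == row["specimen"]]
        sums = [g[c].sum() for c in ("area_normal", "area_abnormal", "n_normal", "n_abnormal")]
        report = aggregate_specimen(
            [
                ImageMeasurement(r.area_normal, r.area_abnormal, r.n_normal, r.n_abnormal)
                for r in g.itertuples()
            ],
            specimen_id=str(row["specimen"]),
        )
        ok = (
            sums == [row["area_normal"], row["area_abnormal"], row["n_normal"], row["n_abnormal"]]
            and np.isclose(report.parameter1, row["parameter1"])
            and np.isclose(report.parameter2, row["parameter2"])
        )
        if not ok:
            raise AssertionError(
                f"integrity check failed for specimen {row['specimen']}: "
                "per-specimen values do not match per-image sums"
            )
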