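"""Severity parameters, stage discrimination and group statistics.

Two per-specimen indices summarize pathological progression:

* parameter 1 — the abnormal-tissue area ratio,
  area_abnormal / (area_abnormal + area_normal);
* parameter 2 — the abnormal-nucleus number ratio,
  n_abnormal / (n_abnormal + n_normal).

Per-specimen values aggregate the raw areas/counts of that specimen's images
by summation first, then take the ratio (sum-then-ratio, not mean-of-ratios).
Severity stages High/Middle/Low are discriminated by two cuts placed at the
midpoints of adjacent stage means; a ratio exactly at a cut goes to the more
severe stage. Group differences are tested with Welch's unequal-variance
two-sample t-test (the pooled-variance variant is available but does not
reproduce the reference analyses).

By default the discrimination emulates reported-precision arithmetic: ratios
and stage means are rounded half-up to three decimals before the cuts are
formed, which is how results tabulated at 3 dp are compared by a reader (and
is required for a specimen lying exactly on a cut to be reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from ._utils import round_half_up

__all__ = [
    "ImageMeasurement",
    "SpecimenReport",
    "StageThresholds",
    "GroupComparison",
    "parameter1",
    "parameter2",
    "aggregate_specimen",
    "group_summary",
    "stage_thresholds",
    "classify_stage",
    "compare_groups",
    "StageClassifier",
    "severity_report",
]

STAGE_ORDER = ("H", "M", "L", "N")


@dataclass(frozen=True)
class ImageMeasurement:
    """Raw per-image measurements entering the two parameters."""

    area_normal: float
    area_abnormal: float
    n_normal: int
    n_abnormal: int

    def __post_init__(self):
        if min(self.area_normal, self.area_abnormal, self.n_normal, self.n_abnormal) < 0:
            raise ValueError("measurements must be non-negative")


@dataclass(frozen=True)
class SpecimenReport:
    """Summed measurements and both severity parameters for one specimen."""

    specimen_id: str
    area_normal: float
    area_abnormal: float
    n_normal: int
    n_abnormal: int
    parameter1: float
    parameter2: float
    stage_label: str | None = None
    predicted_stage: str | None = None


@dataclass(frozen=True)
class StageThresholds:
    """Midpoint cuts between adjacent stage means (H/M and M/L)."""

    cut_hm: float
    cut_ml: float

    def __post_init__(self):
        if not self.cut_hm > self.cut_ml:
            raise ValueError("cut_hm must exceed cut_ml")


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def parameter1(area_normal: float, area_abnormal: float) -> float:
    """Abnormal-tissue area ratio: abnormal / (abnormal + normal)."""
    total = area_normal + area_abnormal
    if total <= 0:
        raise ValueError("total tissue area must be positive")
    return area_abnormal / total


def parameter2(n_normal: float, n_abnormal: float) -> float:
    """Abnormal-nucleus number ratio: abnormal / (abnormal + normal)."""
    total = n_normal + n_abnormal
    if total <= 0:
        raise ValueError("total nucleus count must be positive")
    return n_abnormal / total


def aggregate_specimen(
    measurements, specimen_id: str = "", stage_label: str | None = None
) -> SpecimenReport:
    """Sum per-image measurements, then compute both ratios on the sums."""
    measurements = list(measurements)
    if not measurements:
        raise ValueError("at least one image measurement is required")
    a_n = float(sum(m.area_normal for m in measurements))
    a_a = float(sum(m.area_abnormal for m in measurements))
    n_n = int(sum(m.n_normal for m in measurements))
    n_a = int(sum(m.n_abnormal for m in measurements))
    return SpecimenReport(
        specimen_id=specimen_id,
        area_normal=a_n,
        area_abnormal=a_a,
        n_normal=n_n,
        n_abnormal=n_a,
        parameter1=parameter1(a_n, a_a),
        parameter2=parameter2(n_n, n_a),
        stage_label=stage_label,
    )


def group_summary(ratios) -> tuple:
    """Mean and sample standard deviation (n−1 denominator) of a group."""
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("empty group")
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if ratios.size >= 2 else float("nan")
    return mean, sd


def stage_thresholds(mean_h: float, mean_m: float, mean_l: float) -> StageThresholds:
    """Cuts at the midpoints of adjacent stage means."""
    if not mean_h > mean_m > mean_l:
        raise ValueError("stage means must satisfy H > M > L")
    return StageThresholds(cut_hm=(mean_h + mean_m) / 2.0, cut_ml=(mean_m + mean_l) / 2.0)


def classify_stage(ratio: float, cuts: StageThresholds) -> str:
    """H if ratio ≥ cut_hm; M if cut_ml ≤ ratio < cut_hm; else L.

    A value exactly at a cut goes to the more severe stage; the comparison
    carries a 1e-12 tolerance so that a boundary case is not decided by
    floating-point representation error in the midpoint.
    """
    if ratio >= cuts.cut_hm - 1e-12:
        return "H"
    if ratio >= cuts.cut_ml - 1e-12:
        return "M"
    return "L"


def _welch(a: np.ndarray, b: np.ndarray):
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se_sq = va / na + vb / nb
    if se_sq == 0:
        return 0.0, float(na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(se_sq)
    df = se_sq**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def _pooled(a: np.ndarray, b: np.ndarray):
    na, nb = a.size, b.size
    df = na + nb - 2
    sp_sq = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se_sq = sp_sq * (1.0 / na + 1.0 / nb)
    if se_sq == 0:
        return 0.0, float(df)
    return float((a.mean() - b.mean()) / np.sqrt(se_sq)), float(df)


def compare_groups(group_a, group_b, *, equal_var: bool = False,
                   label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sample two-tailed t-test between groups.

    Welch's unequal-variance test with Satterthwaite degrees of freedom by
    default; ``equal_var=True`` selects the pooled-variance Student test.
    Two zero-variance groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t, df = _pooled(a, b) if equal_var else _welch(a, b)
    p = float(2.0 * sps.t.sf(abs(t), df)) if t != 0 else 1.0
    if t == 0 and a.mean() != b.mean():
        # zero spread but different means: infinitely significant in the limit
        p = 0.0
        t = float("inf") if a.mean() > b.mean() else float("-inf")
    return GroupComparison(label_a, label_b, t, df, p)


class StageClassifier(ClassifierMixin, BaseEstimator):
    """Midpoint-threshold severity-stage discriminator.

    Fit on per-specimen severity ratios with H/M/L stage labels: the two cuts
    are the midpoints of adjacent stage means. Predict assigns H/M/L with a
    ≥ convention at each cut. Normal (N) specimens are ignored during
    fitting — the cuts are defined on the diseased stages only.

    Parameters
    ----------
    decimals : int or None, default=3
        Round ratios and stage means half-up to this many decimals before
        forming the cuts, emulating arithmetic on values reported at fixed
        precision. ``None`` uses full precision.

    Attributes
    ----------
    stage_means_ : dict  — per-stage mean ratio (rounded if decimals set)
    thresholds_ : StageThresholds
    classes_ : ndarray of the fitted stage labels
    """

    def __init__(self, decimals: int | None = 3):
        self.decimals = decimals

    def _round(self, x):
        return round_half_up(x, self.decimals) if self.decimals is not None else x

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=object).ravel()
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        ratios = self._round(X)
        means = {}
        for stage in ("H", "M", "L"):
            sel = y == stage
            if not sel.any():
                raise ValueError(f"no specimens with stage {stage!r}")
            means[stage] = float(self._round(np.mean(ratios[sel])))
        self.stage_means_ = means
        self.thresholds_ = stage_thresholds(means["H"], means["M"], means["L"])
        self.classes_ = np.array(["H", "L", "M"], dtype=object)
        return self

    def predict(self, X):
        if not hasattr(self, "thresholds_"):
            raise AttributeError("StageClassifier is not fitted yet; call fit first")
        ratios = self._round(np.asarray(X, dtype=float).ravel())
        return np.array([classify_stage(r, self.thresholds_) for r in ratios], dtype=object)


def severity_report(specimens: pd.DataFrame, *, decimals: int | None = 3,
                    equal_var: bool = False) -> dict:
    """Full downstream analysis of a per-specimen measurement table.

    Parameters
    ----------
    specimens : DataFrame with columns specimen, stage, area_normal,
        area_abnormal, n_normal, n_abnormal (stage in {H, M, L, N}).

    Returns
    -------
    dict with:

    * ``specimens`` — input plus parameter1/parameter2 and, for H/M/L rows,
      predicted stages by each parameter;
    * ``groups`` — per stage and parameter: n, mean, sample SD;
    * ``thresholds`` — fitted StageThresholds per parameter;
    * ``misclassified`` — per parameter: count of stage-label disagreements;
    * ``comparisons`` — pairwise Welch tests (H vs M, M vs L) per parameter.
    """
    df = specimens.copy()
    df["parameter1"] = [
        parameter1(an, aa) for an, aa in zip(df["area_normal"], df["area_abnormal"])
    ]
    df["parameter2"] = [
        parameter2(nn, na) for nn, na in zip(df["n_normal"], df["n_abnormal"])
    ]

    groups_rows, comp_rows = [], []
    thresholds, misclassified = {}, {}
    hml = df[df["stage"].isin(["H", "M", "L"])]
    for param in ("parameter1", "parameter2"):
        try:
            clf = StageClassifier(decimals=decimals).fit(hml[param], hml["stage"])
        except ValueError:
            # non-monotone stage means: midpoint discrimination is undefined
            thresholds[param] = None
            misclassified[param] = None
        else:
            pred = clf.predict(hml[param])
            df.loc[hml.index, f"predicted_{param}"] = pred
            thresholds[param] = clf.thresholds_
            misclassified[param] = int((pred != hml["stage"].to_numpy()).sum())
        for stage in STAGE_ORDER:
            vals = df.loc[df["stage"] == stage, param]
            if len(vals) == 0:
                continue
            mean, sd = group_summary(vals)
            groups_rows.append(
                {"parameter": param, "stage": stage, "n": len(vals), "mean": mean, "sd": sd}
            )
        for a, b in (("H", "M"), ("M", "L")):
            ga = df.loc[df["stage"] == a, param]
            gb = df.loc[df["stage"] == b, param]
            if len(ga) < 2 or len(gb) < 2:
                continue  # a t-test needs at least two observations per group
            comp = compare_groups(ga, gb, equal_var=equal_var, label_a=a, label_b=b)
            comp_rows.append(
                {
                    "parameter": param,
                    "group_a": a,
                    "group_b": b,
                    "t": comp.t_statistic,
                    "df": comp.degrees_of_freedom,
                    "p_value": comp.p_value,
                }
            )
    return {
        "specimens": df,
        "groups": pd.DataFrame(groups_rows),
        "thresholds": thresholds,
        "misclassified": misclassified,
        "comparisons": pd.DataFrame(comp_rows),
    }
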