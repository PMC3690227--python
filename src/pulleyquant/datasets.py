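"""Bundled reference measurements for 29 graded A1-pulley specimens.

Each specimen was graded by a pathologist into severity stage H (high),
M (middle), L (low) or N (normal) and measured over ten 2560×1920 fields of
view; the table holds the summed normal/abnormal tissue areas (pixels²) and
the summed normal/abnormal nucleus counts per specimen. These numbers are
the canonical worked example for the downstream analysis: severity ratios,
stage discrimination by midpoint cuts, and group statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_measurements"]

# specimen, stage, area_normal, area_abnormal, n_normal, n_abnormal
_REFERENCE = [
    ("H-1", "H", 31791895, 12495997, 271, 660),
    ("H-2", "H", 30894213, 10986876, 481, 1088),
    ("H-3", "H", 31869804, 11038359, 244, 529),
    ("H-4", "H", 32511973, 11026116, 117, 385),
    ("H-5", "H", 33797170, 10267132, 289, 1098),
    ("H-6", "H", 31635397, 11474053, 721, 1653),
    ("H-7", "H", 31451368, 11224479, 292, 655),
    ("H-8", "H", 32950410, 11695269, 165, 817),
    ("H-9", "H", 34067450, 10887277, 446, 1013),
    ("H-10", "H", 27747278, 10290969, 59, 151),
    ("M-1", "M", 35698059, 7946874, 382, 687),
    ("M-2", "M", 34326147, 8515580, 318, 591),
    ("M-3", "M", 35324719, 8461582, 192, 360),
    ("M-4", "M", 33284256, 7671304, 131, 187),
    ("M-5", "M", 34422738, 9418395, 308, 652),
    ("M-6", "M", 34315916, 9170559, 173, 343),
    ("M-7", "M", 33027627, 9072248, 335, 456),
    ("M-8", "M", 34051300, 7529957, 726, 1311),
    ("M-9", "M", 35167293, 8706583, 382, 647),
    ("M-10", "M", 32745438, 8083811, 379, 795),
    ("L-1", "L", 40491940, 5972857, 824, 771),
    ("L-2", "L", 43877544, 2773360, 1080, 1210),
    ("L-3", "L", 36923582, 6077911, 520, 636),
    ("L-4", "L", 37539086, 4417329, 404, 477),
    ("L-5", "L", 34975123, 7460192, 862, 1165),
    ("L-6", "L", 36623101, 5244448, 123, 259),
    ("N-1", "N", 40904631, 5482052, 473, 247),
    ("N-2", "N", 32792539, 3323970, 310, 205),
    ("N-3", "N", 32724101, 4340358, 292, 308),
]


def load_reference_measurements() -> pd.DataFrame:
    """Per-specimen reference table.

    Returns
    -------
    DataFrame with columns ``specimen``, ``stage``, ``area_normal``,
    ``area_abnormal`` (pixels²), ``n_normal``, ``n_abnormal`` (counts).
    """
    return pd.DataFrame(
        _REFERENCE,
        columns=["specimen", "stage", "area_normal", "area_abnormal", "n_normal", "n_abnormal"],
    )
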