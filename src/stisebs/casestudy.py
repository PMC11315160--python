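"""Published per-class confusion counts from a Sahel land-cover study.

These are the one-vs-rest confusion counts (and the per-class metrics
printed alongside them, rounded to 3 decimals) reported for a 20-year,
8-day NDVI case study over 695,532 high-resolution pixels in the Sahel
region of Burkina Faso, where hypothetical HR pixels carrying each
segment's modal land-cover class were scored against an ESA/Sentinel-2
land-cover map.  Three segmentation methods were compared: the
time-series superpixels produced by this package's pipeline, the e-SLIC
benchmark, and naive 1000-m low-resolution blocks.

The counts are *inputs* (published observations); the metric columns
are the values printed next to them and serve as a cross-check for
:func:`stisebs.assess.binary_metrics`.  Every row sums to the study's
695,532 pixels.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CASE_STUDY_PIXELS", "confusion_rows"]

CASE_STUDY_PIXELS = 695_532

# method, land-cover class, TP, FP, FN, TN, precision, sensitivity, F1, MCC
_ROWS = [
    ("stisebs", "water", 268, 91, 343, 694_830, 0.747, 0.439, 0.553, 0.572),
    ("stisebs", "trees", 2456, 1085, 5515, 686_476, 0.694, 0.308, 0.427, 0.458),
    ("stisebs", "flooded_vegetation", 155, 41, 78, 695_258, 0.791, 0.665, 0.723, 0.725),
    ("stisebs", "crops", 572, 256, 669, 694_035, 0.691, 0.461, 0.553, 0.564),
    ("stisebs", "built_area", 679, 184, 342, 694_327, 0.787, 0.665, 0.721, 0.723),
    ("stisebs", "bare_ground", 3361, 1318, 5570, 685_283, 0.718, 0.376, 0.494, 0.516),
    ("stisebs", "rangeland", 672_738, 12_328, 2786, 7680, 0.982, 0.996, 0.989, 0.521),
    ("eslic", "water", 236, 114, 375, 694_807, 0.674, 0.386, 0.491, 0.510),
    ("eslic", "trees", 2589, 1174, 5389, 686_380, 0.688, 0.325, 0.441, 0.469),
    ("eslic", "flooded_vegetation", 147, 101, 86, 695_198, 0.593, 0.631, 0.611, 0.611),
    ("eslic", "crops", 581, 266, 663, 694_022, 0.686, 0.467, 0.556, 0.565),
    ("eslic", "built_area", 643, 207, 378, 694_304, 0.756, 0.630, 0.687, 0.690),
    ("eslic", "bare_ground", 2956, 1016, 5979, 685_581, 0.744, 0.331, 0.458, 0.492),
    ("eslic", "rangeland", 672_828, 12_674, 2682, 7348, 0.982, 0.996, 0.989, 0.509),
    ("coarse", "water", 175, 113, 436, 694_808, 0.608, 0.286, 0.389, 0.417),
    ("coarse", "trees", 2050, 1085, 5921, 686_476, 0.654, 0.257, 0.369, 0.406),
    ("coarse", "flooded_vegetation", 105, 55, 128, 695_244, 0.656, 0.451, 0.534, 0.544),
    ("coarse", "crops", 616, 259, 625, 694_032, 0.704, 0.496, 0.582, 0.591),
    ("coarse", "built_area", 613, 155, 408, 694_356, 0.798, 0.600, 0.685, 0.692),
    ("coarse", "bare_ground", 3408, 1234, 5523, 685_367, 0.734, 0.382, 0.502, 0.525),
    ("coarse", "rangeland", 672_784, 12_880, 2740, 7128, 0.981, 0.996, 0.989, 0.498),
]


def confusion_rows() -> pd.DataFrame:
    """The published rows as a DataFrame (counts + printed metrics)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "method",
            "land_cover",
            "tp",
            "fp",
            "fn",
            "tn",
            "precision",
            "sensitivity",
            "f1",
            "mcc",
        ],
    )
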