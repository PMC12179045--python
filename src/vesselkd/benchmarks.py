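"""Published benchmark rows used for report generation and cross-checks.

Values are the printed test-set percentages for the four vessel-segmentation
benchmarks (metrics: ACC, SEN, SPE, F1, IOU).  `unet` is the baseline U-Net,
`mtkd` the multi-teacher distilled student, and `mtkd_lp` its
loss-penalized variant.  Entries that were not reported are None.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_RESULTS", "improvement_over_baseline", "max_improvement"]

PUBLISHED_RESULTS: dict[str, dict[str, dict[str, float | None]]] = {
    "DRIVE": {
        "unet": {"ACC": 96.78, "SEN": 80.57, "SPE": 98.33, "F1": 81.41, "IOU": 68.64},
        "mtkd": {"ACC": 96.72, "SEN": 80.22, "SPE": 98.32, "F1": 80.74, "IOU": 67.82},
        "mtkd_lp": {"ACC": 96.93, "SEN": 79.54, "SPE": 98.60, "F1": 81.66, "IOU": 69.08},
    },
    "CHASEDB1": {
        "unet": {"ACC": 97.43, "SEN": 76.50, "SPE": 98.84, "F1": 78.98, "IOU": 65.26},
        "mtkd": {"ACC": 97.26, "SEN": 74.90, "SPE": 98.76, "F1": 77.48, "IOU": 63.28},
        "mtkd_lp": {"ACC": 97.54, "SEN": 78.09, "SPE": 98.83, "F1": 79.95, "IOU": 66.62},
    },
    "CHUAC": {
        "unet": {"ACC": 97.84, "SEN": 58.81, "SPE": 99.40, "F1": 67.68, "IOU": 51.15},
        "mtkd": {"ACC": 98.23, "SEN": 73.33, "SPE": 99.40, "F1": 76.02, "IOU": 61.41},
        "mtkd_lp": {"ACC": 98.19, "SEN": 75.34, "SPE": 99.10, "F1": 76.12, "IOU": 61.57},
    },
    "DCA1": {
        "unet": {"ACC": 97.58, "SEN": 78.16, "SPE": 98.66, "F1": 77.35, "IOU": 63.07},
        "mtkd": {"ACC": 97.84, "SEN": 80.19, "SPE": 98.84, "F1": 79.38, "IOU": 66.00},
        "mtkd_lp": {"ACC": 97.79, "SEN": 84.48, "SPE": 98.54, "F1": 79.87, "IOU": 66.63},
    },
}


def improvement_over_baseline(metric: str, method: str = "mtkd_lp") -> dict[str, float]:
    """Per-dataset improvement (in points) of `method` over the baseline U-Net."""
    out = {}
    for dataset, rows in PUBLISHED_RESULTS.items():
        base, prop = rows["unet"].get(metric), rows[method].get(metric)
        if base is None or prop is None:
            continue
        out[dataset] = round(prop - base, 2)
    return out


def max_improvement(metric: str, method: str = "mtkd_lp") -> float:
    """Largest per-dataset improvement of `method` over the baseline U-Net."""
    return max(improvement_over_baseline(metric, method).values())
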