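"""Published reference values shipped with the package.

These constants reproduce the numbers printed with the original
single-panicle litchi study and serve as fixed inputs for verification
and as shipped calibration defaults.  Nothing here is computed; the
computations that consume them live in :mod:`flowernet.calibration` and
:mod:`flowernet.train_eval`.
"""

from __future__ import annotations

from .calibration import CalibrationModel

#: Verification set: 10 panicles, (FH manual count, FM calibrated model
#: prediction).  Feeding these to ``verification_report`` reproduces the
#: published per-sample differences and accuracy rates, MAE 49.9,
#: RMSE 59.57 and average accuracy 85.59%.
VERIFICATION_PAIRS: list[tuple[float, float]] = [
    (221, 284),
    (348, 350),
    (240, 299),
    (204, 259),
    (144, 154),
    (301, 328),
    (464, 573),
    (571, 544),
    (778, 685),
    (728, 782),
]

#: Calibration line fitted on network-predicted counts (FF → FH),
#: y = 51.27003 + 1.50501·x, reported with R² = 0.81.
FF_CALIBRATION = CalibrationModel(slope=1.50501, intercept=51.27003)

#: Calibration line fitted on image-annotated counts (FL → FH),
#: y = 35.53595 + 1.503735·x, reported with R² = 0.88.
FL_CALIBRATION = CalibrationModel(slope=1.503735, intercept=35.53595)

#: Default shipped calibration (the network-count line).
DEFAULT_CALIBRATION = FF_CALIBRATION

#: Single-panicle counting dataset summary: per collection type,
#: (number of images, total flowers across the dataset).
SINGLE_PANICLE_DATASET = {
    "observation": {"images": 110, "total_flowers": 52_235,
                    "max": 1_022, "min": 144},
    "annotation": {"images": 110, "total_flowers": 32_106,
                   "max": 687, "min": 71},
}

#: Whole-image counting dataset bookkeeping: 337 images split 268/69,
#: 173,949 flowers in total.
COUNTING_DATASET = {"images": 337, "train": 268, "test": 69,
                    "total_flowers": 173_949, "max": 1_504, "min": 40}


def dataset_average(images: int, total_flowers: int) -> float:
    """Average flowers per image, to 2 decimals (as the tables print it)."""
    return round(total_flowers / images, 2)
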