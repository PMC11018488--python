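"""Linear calibration of image-derived flower counts to manual counts.

A panicle photographed from one side never shows every flower, so the
count read off an image (whether annotated by hand, FL, or predicted by
the network, FF) underestimates the true per-panicle count obtained by
manual counting in the field (FH).  A univariate linear model

    y = a·x + b

maps the image-derived count x to the manual count y.  Fit quality is
assessed with the Pearson correlation coefficient and the coefficient of
determination R² = 1 − Σ(Ŷᵢ−Yᵢ)²/Σ(Ȳ−Yᵢ)², and per-sample agreement
with the accuracy rate

    P = (1 − |FH − FM| / FH) × 100 ,

where FM is the calibrated prediction.  ``verification_report`` renders
the Table-style per-sample summary (difference, P) together with MAE,
RMSE and the average accuracy rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CalibrationModel:
    """Slope/intercept of y = a·x + b."""

    slope: float
    intercept: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=np.float64) + self.intercept


@dataclass
class PairedCounts:
    """(x, y) count pairs; x is the image-derived count, y the manual one."""

    records: list[tuple[float, float]]
    x_source: str = "FF"  # FF: model-predicted; FL: image-annotated

    @property
    def x(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=np.float64)


def _round2(v: float) -> float:
    """Half-up rounding to 2 decimals, as in the printed report tables."""
    return float(Decimal(repr(float(v))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def fit_linear(pairs: PairedCounts) -> CalibrationModel:
    """Ordinary least squares fit of y on x."""
    x, y = pairs.x, pairs.y
    if x.size < 2:
        raise ValueError("need at least 2 records to fit")
    if np.ptp(x) == 0:
        raise ValueError("singular fit: all x values identical")
    slope, intercept = np.polyfit(x, y, 1)
    return CalibrationModel(float(slope), float(intercept))


def apply_calibration(x: float, model: CalibrationModel) -> float:
    """Evaluate a·x + b."""
    return float(model.slope * x + model.intercept)


def pearson_r(pairs: PairedCounts) -> float:
    """Sample Pearson correlation between x and y."""
    x, y = pairs.x, pairs.y
    if x.size < 2:
        raise ValueError("need at least 2 records")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one coordinate")
    return float(stats.pearsonr(x, y).statistic)


def pearson_test(pairs: PairedCounts) -> tuple[float, float]:
    """Pearson r with its two-sided t-approximation p-value (informational)."""
    res = stats.pearsonr(pairs.x, pairs.y)
    return float(res.statistic), float(res.pvalue)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    May be negative for predictions worse than the mean; it is only
    bounded to [0, 1] when the predictions come from an OLS fit
    evaluated on its own fitting data.
    """
    y = np.asarray(observed, dtype=np.float64)
    yh = np.asarray(predicted, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.square(y - y.mean()).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in observations")
    return 1.0 - float(np.square(yh - y).sum()) / ss_tot


def accuracy_P(FH: float, FM: float) -> float:
    """Accuracy rate P = (1 − |FH − FM|/FH) × 100, to 2 decimals."""
    if FH <= 0:
        raise ValueError("FH must be positive")
    return _round2((1.0 - abs(FH - FM) / FH) * 100.0)


def verification_report(pairs: list[tuple[float, float]],
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-sample verification table plus summary metrics.

    ``pairs`` holds (FH, FM) = (manual count, calibrated prediction).
    Returns a DataFrame with columns index/FH/FM/difference/P and a dict
    with MAE, RMSE and the average accuracy rate (mean of per-sample P).
    """
    if not pairs:
        raise ValueError("empty verification set")
    rows = []
    for i, (fh, fm) in enumerate(pairs, start=1):
        if fh <= 0:
            raise ValueError(f"sample {i}: FH must be positive")
        rows.append({"index": i, "FH": fh, "FM": fm,
                     "difference": abs(fh - fm), "P": accuracy_P(fh, fm)})
    table = pd.DataFrame(rows)
    diff = table["FH"].to_numpy() - table["FM"].to_numpy()
    summary = {
        "MAE": float(np.abs(diff).mean()),
        "RMSE": float(np.sqrt(np.square(diff).mean())),
        "average_P": _round2(table["P"].mean()),
    }
    return table, summary
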