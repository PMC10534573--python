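"""Method-validation statistics: linearity, accuracy, precision.

Implements the numerical side of pharmacopoeial method validation —
calibration regression (slope, intercept, Pearson r), recovery and relative
standard deviation — together with the acceptance rules applied to an
active pharmaceutical ingredient versus a related compound (impurity):

* correlation coefficient r: > 0.99 (active), > 0.98 (impurity)
* recovery: 98.0-102.0 % (active), 70.0-130.0 % (impurity), inclusive
* RSD: <= 2 % (active), <= 15 % (impurity)

Limit of detection / quantification by signal-to-noise (3:1 and 10:1)
requires raw chromatogram traces and is out of computational scope here;
printed LOD values are carried as reference metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "RecoveryResult",
    "calibration_fit",
    "recovery",
    "rsd",
    "rsd_acceptable",
    "ACCEPTANCE",
]

#: Acceptance rules per analyte class.
ACCEPTANCE = {
    "active": {"r_min": 0.99, "recovery": (98.0, 102.0), "rsd_max": 2.0},
    "impurity": {"r_min": 0.98, "recovery": (70.0, 130.0), "rsd_max": 15.0},
}


def _check_class(analyte_class: str) -> None:
    if analyte_class not in ACCEPTANCE:
        raise ValueError(f"analyte_class must be one of {sorted(ACCEPTANCE)}")


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares calibration line y = a*x + b with Pearson correlation."""

    slope: float
    intercept: float
    r: float
    n: int
    analyte_class: str
    stderr_slope: float

    @property
    def acceptable(self) -> bool:
        """Strict r > bound, per the analyte class."""
        return self.r > ACCEPTANCE[self.analyte_class]["r_min"]


def calibration_fit(concentrations, signals, analyte_class: str = "active") -> CalibrationFit:
    """Fit the calibration line by OLS; r is the Pearson correlation."""
    _check_class(analyte_class)
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and signals must be 1-D of equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if np.ptp(x) == 0:
        raise ValueError("zero concentration variance")
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(x),
        analyte_class=analyte_class,
        stderr_slope=float(res.stderr),
    )


@dataclass(frozen=True)
class RecoveryResult:
    percent: float
    analyte_class: str

    @property
    def acceptable(self) -> bool:
        lo, hi = ACCEPTANCE[self.analyte_class]["recovery"]
        return lo <= self.percent <= hi


def recovery(found: float, nominal: float, analyte_class: str = "active") -> RecoveryResult:
    """Accuracy as found/nominal x 100 %, checked against the class band."""
    _check_class(analyte_class)
    if not nominal > 0:
        raise ValueError(f"nominal amount must be positive, got {nominal}")
    return RecoveryResult(100.0 * found / nominal, analyte_class)


def rsd(values) -> float:
    """Relative standard deviation in percent (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def rsd_acceptable(value: float, analyte_class: str = "active") -> bool:
    _check_class(analyte_class)
    return value <= ACCEPTANCE[analyte_class]["rsd_max"]
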