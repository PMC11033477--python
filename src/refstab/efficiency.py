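"""Standard-curve fitting for qPCR amplification efficiency.

A dilution series is fitted by ordinary least squares,
``Ct = intercept + slope * log10(dilution)``, and the slope converted to an
amplification efficiency in percent via ``E = (10**(-1/slope) - 1) * 100``.
A slope of -1/log10(2) = -3.3219 corresponds to perfect doubling (100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "fit_standard_curve",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of a dilution series.

    slope is in cycles per log10(dilution) and must be negative for a valid
    amplification curve; efficiency_percent is derived from the slope.
    """

    slope: float
    intercept: float
    r2: float
    efficiency_percent: float
    n_points: int


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    Returns ``(10**(-1/slope) - 1) * 100`` unrounded; callers that mirror
    reporting conventions round to two decimals.
    """
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    if slope >= 0:
        raise ValueError(f"non-amplifying curve: slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_percent: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    if efficiency_percent <= -100.0:
        raise ValueError("efficiency must exceed -100%")
    return -1.0 / np.log10(1.0 + efficiency_percent / 100.0)


def fit_standard_curve(log10_dilution: Sequence[float], ct: Sequence[float]) -> StandardCurve:
    """Fit Ct against log10 relative template amount.

    Requires at least three points over at least two distinct dilution
    values.  r2 is the squared Pearson correlation of the simple regression,
    identical to the OLS coefficient of determination.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log10_dilution and ct must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need >=3 points to fit a standard curve, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all dilution values identical")

    fit = stats.linregress(x, y)
    if np.isclose(np.std(y), 0.0):
        r2 = 1.0  # flat response fits itself exactly; linregress returns r=0
    else:
        r2 = float(fit.rvalue) ** 2
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        efficiency_percent=efficiency_from_slope(float(fit.slope)),
        n_points=int(x.size),
    )
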