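"""Model-quality metrics: R^2, RMSE, RPD and its qualitative banding.

RPD (ratio of prediction to deviation) is the test-set standard deviation of
the reference values divided by the test RMSE; values above 2.0 are
conventionally called excellent and 1.4-2.0 good.
"""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "rmse", "rpd", "band_rpd", "RPD_GOOD", "RPD_EXCELLENT"]

RPD_GOOD = 1.4
RPD_EXCELLENT = 2.0


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative).

    The total sum of squares uses the mean of the reference values in the
    evaluated set.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares: constant reference values")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error with divisor n, in the units of y."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def rpd(sd_test: float, rmse_test: float) -> float:
    """Ratio of prediction to deviation: SD of the test references / RMSE.

    ``sd_test`` must be the sample standard deviation (n-1 denominator).
    """
    if rmse_test == 0:
        raise ValueError("degenerate perfect prediction: RMSE is zero")
    if rmse_test < 0 or sd_test < 0:
        raise ValueError("sd and rmse must be non-negative")
    return float(sd_test) / float(rmse_test)


def band_rpd(value: float) -> str:
    """Qualitative RPD band: excellent (>2.0), good ([1.4, 2.0]), below_good."""
    if value <= 0:
        raise ValueError("RPD must be positive")
    if value > RPD_EXCELLENT:
        return "excellent"
    if value >= RPD_GOOD:
        return "good"
    return "below_good"
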