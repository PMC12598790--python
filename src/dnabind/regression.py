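"""Ordinary least squares with the full parameter covariance.

Every linearized binding analysis in this package (Benesi-Hildebrand,
Stern-Volmer, double-log, van't Hoff, the electrochemical log-log fit and the
calibration line) reduces to a straight-line fit whose derived quantities need
slope/intercept standard errors and, for ratios such as Kb = slope/intercept,
their covariance.  scipy's linregress does not expose the covariance, so the
normal-equation solution is written out here once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError

__all__ = ["OlsFit", "ols"]


@dataclass(frozen=True)
class OlsFit:
    """Straight-line OLS fit y = slope*x + intercept."""

    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    cov_slope_intercept: float
    r_squared: float
    residual_sd: float  # sqrt(SSE / (n - 2))
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def ols(x, y) -> OlsFit:
    """Fit y = a*x + b by ordinary least squares.

    Parameters
    ----------
    x, y : array-like, same length, >= 2 points, x not all equal.

    Returns
    -------
    OlsFit with parameter standard errors computed from the residual variance
    (n-2 denominator; zero when n == 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise FitError(f"need at least 2 points, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in regression input")
    xbar = x.mean()
    ybar = y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0.0:
        raise FitError("x values are all identical")
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    syy = float(np.sum((y - ybar) ** 2))
    r_squared = 1.0 if syy == 0.0 else max(0.0, 1.0 - sse / syy)

    if n > 2:
        sigma2 = sse / (n - 2)
    else:
        sigma2 = 0.0
    residual_sd = float(np.sqrt(sigma2))
    var_slope = sigma2 / sxx
    var_intercept = sigma2 * (1.0 / n + xbar**2 / sxx)
    cov_si = -sigma2 * xbar / sxx

    return OlsFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_stderr=float(np.sqrt(var_slope)),
        intercept_stderr=float(np.sqrt(var_intercept)),
        cov_slope_intercept=float(cov_si),
        r_squared=float(r_squared),
        residual_sd=residual_sd,
        n=int(n),
    )
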