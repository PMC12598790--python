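"""Calibration, detection limits and method-validation statistics.

The voltammetric determination rests on a linear calibration of the dGuo
peak current against drug concentration (A vs uM).  Figures of merit follow
the standard regression-based definitions: LOD = 3*SD/|slope| and
LOQ = 10*SD/|slope| with SD the residual standard deviation of the
calibration line (a blank-replicate SD may be supplied instead).  Replicate
statistics use the sample (n-1) standard deviation throughout;
%RSD = 100*SD/mean and recovery bias = mean recovery - 100.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import FitError, ParameterError
from .regression import ols
from .types import CalibrationResult, ValidationStats

__all__ = [
    "calibration_fit",
    "lod_loq",
    "repeatability_rsd",
    "assay_tablet",
    "recovery_analysis",
]

log = logging.getLogger(__name__)


def calibration_fit(points: Sequence[tuple[float, float]]) -> CalibrationResult:
    """OLS calibration line from (concentration uM, current A) pairs.

    Requires >= 5 points with at least two distinct concentrations.  The
    residual SD uses the n-2 denominator.  Points whose externally
    studentized residual exceeds 3 are flagged as outliers (flag only; they
    stay in the fit).
    """
    conc = np.array([float(c) for c, _ in points])
    cur = np.array([float(i) for _, i in points])
    if conc.size < 5:
        raise FitError(f"calibration needs >= 5 points, got {conc.size}")
    if np.unique(conc).size < 2:
        raise FitError("calibration needs at least two distinct concentrations")
    fit = ols(conc, cur)
    lod, loq = lod_loq(fit.residual_sd, fit.slope)

    outliers: list[int] = []
    n = conc.size
    # skip the outlier scan when residuals are pure floating-point noise
    current_scale = float(np.max(np.abs(cur))) or 1.0
    if n > 3 and fit.residual_sd > 1e-12 * current_scale:
        resid = cur - fit.predict(conc)
        xbar = conc.mean()
        sxx = np.sum((conc - xbar) ** 2)
        lev = 1.0 / n + (conc - xbar) ** 2 / sxx
        sse = np.sum(resid**2)
        for j in range(n):
            # leave-one-out residual variance
            s2_j = (sse - resid[j] ** 2 / (1.0 - lev[j])) / (n - 3)
            if s2_j <= 0:
                continue
            t_j = resid[j] / np.sqrt(s2_j * (1.0 - lev[j]))
            if abs(t_j) > 3.0:
                outliers.append(j)
        if outliers:
            log.warning("calibration: studentized residual > 3 at indices %s", outliers)

    log.info(
        "calibration: slope=%.3g A/uM, intercept=%.3g A, R^2=%.4f, LOD=%.3g uM (n=%d)",
        fit.slope, fit.intercept, fit.r_squared, lod, n,
    )
    return CalibrationResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        residual_sd=fit.residual_sd,
        lod=lod,
        loq=loq,
        linear_range=(float(conc.min()), float(conc.max())),
        n_points=int(n),
        outlier_indices=outliers,
    )


def lod_loq(residual_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits: (3*SD/|slope|, 10*SD/|slope|).

    Their ratio is exactly 10/3 because both derive from the same SD and
    slope; values are returned unrounded.
    """
    if slope == 0:
        raise ParameterError("slope must be nonzero")
    if residual_sd < 0:
        raise ParameterError("residual SD must be non-negative")
    lod = 3.0 * residual_sd / abs(slope)
    return lod, lod * (10.0 / 3.0)


def _replicate_stats(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray([float(v) for v in values], dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0:
        raise ParameterError("%RSD undefined for zero mean")
    return mean, sd, 100.0 * sd / abs(mean)


def repeatability_rsd(replicates: Sequence[float]) -> ValidationStats:
    """Mean, sample SD and %RSD of repeated measurements (>= 3 replicates)."""
    if len(replicates) < 3:
        raise ParameterError(f"need >= 3 replicates, got {len(replicates)}")
    mean, sd, rsd = _replicate_stats(replicates)
    return ValidationStats(mean=mean, sd=sd, rsd_percent=rsd, per_sample=[float(v) for v in replicates])


def assay_tablet(measured_mg: Sequence[float], label_mg: float) -> tuple[ValidationStats, float]:
    """Tablet-content statistics plus the mean percent of label claim.

    All tablets enter the statistics as measured - a zero-content tablet is
    not silently excluded.
    """
    if label_mg <= 0:
        raise ParameterError("label amount must be positive")
    if len(measured_mg) < 3:
        raise ParameterError(f"need >= 3 tablets, got {len(measured_mg)}")
    mean, sd, rsd = _replicate_stats(measured_mg)
    percent_of_label = 100.0 * mean / label_mg
    stats = ValidationStats(
        mean=mean, sd=sd, rsd_percent=rsd, per_sample=[float(v) for v in measured_mg]
    )
    log.info("assay: mean %.1f mg of %g mg label (%.1f%%), %%RSD %.2f",
             mean, label_mg, percent_of_label, rsd)
    return stats, percent_of_label


def recovery_analysis(added: Sequence[float], found: Sequence[float]) -> ValidationStats:
    """Spike-recovery statistics with %bias.

    Per-sample recovery = 100*found/added; the returned stats are of the
    recoveries, with bias_percent = mean recovery - 100.
    """
    if len(added) != len(found):
        raise ParameterError("added and found must have equal lengths")
    added_arr = np.asarray([float(v) for v in added])
    if np.any(added_arr <= 0):
        raise ParameterError("added amounts must be positive")
    recoveries = [100.0 * float(f) / float(a) for a, f in zip(added, found)]
    mean, sd, rsd = _replicate_stats(recoveries)
    log.info("recovery: mean %.1f%%, %%RSD %.2f, bias %+.1f%%", mean, rsd, mean - 100.0)
    return ValidationStats(
        mean=mean, sd=sd, rsd_percent=rsd, per_sample=recoveries, bias_percent=mean - 100.0
    )
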