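"""Viscometry and rheology analysis.

Intercalation lengthens the DNA helix and raises solution viscosity;
groove binding leaves it essentially unchanged.  Two routes are covered:

* flow-time titrations: specific viscosity eta = (t - t0)/t0 per point,
  presented as the conventional cube-root relative viscosity
  (eta/eta0)^(1/3) against the mixing ratio r = [ligand]/[DNA], plus a
  trend test on that series;
* rheometer flow curves: Herschel-Bulkley fits tau = tau0 + K*gamma^n with
  the apparent viscosity tau/gamma at a user-chosen shear rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .regression import ols
from .types import FlowTimeSeries, Rheogram

__all__ = [
    "RelativeViscosityPoint",
    "relative_viscosity_series",
    "TrendResult",
    "viscosity_trend_test",
    "HerschelBulkleyFit",
    "herschel_bulkley_fit",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelativeViscosityPoint:
    r: float  # [ligand]/[DNA]
    value: float  # (eta/eta0)^(1/3)
    flagged: bool = False  # flow time below buffer reference


def relative_viscosity_series(flow: FlowTimeSeries) -> list[RelativeViscosityPoint]:
    """Cube-root relative viscosities from a flow-time titration.

    The zero-ligand point defines the free-DNA specific viscosity
    eta0 = (t_dna - t0)/t0 and is included in the output (its value is 1 by
    construction).  Points with t < t0 are physically impossible for a
    polymer solution and are flagged, not dropped.
    """
    if flow.ligand_conc[0] != 0.0:
        raise ValidationError("flow-time series must start at zero ligand (free DNA)")
    eta = (flow.t - flow.t0) / flow.t0
    eta0 = eta[0]
    if eta0 <= 0:
        raise ValidationError("DNA flow time not above buffer: eta0 <= 0")
    r = flow.ligand_conc / flow.dna_conc
    out = []
    for ri, etai, ti in zip(r, eta, flow.t):
        flagged = ti < flow.t0
        ratio = etai / eta0
        value = float(np.cbrt(ratio)) if ratio >= 0 else float("nan")
        out.append(RelativeViscosityPoint(r=float(ri), value=value, flagged=bool(flagged)))
        if flagged:
            log.warning("flow time %.3f s below buffer reference %.3f s at r=%.2f", ti, flow.t0, ri)
    return out


@dataclass
class TrendResult:
    slope: float
    slope_ci: tuple[float, float]  # 95%
    classification: str  # "flat" | "increasing" | "decreasing"
    predicted_change: float  # slope * r-range
    n: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "slope": self.slope,
            "slope_ci95": list(self.slope_ci),
            "classification": self.classification,
            "predicted_change": self.predicted_change,
            "n": self.n,
        }


def viscosity_trend_test(
    series: Sequence[tuple[float, float]] | Sequence[RelativeViscosityPoint],
    flat_change_threshold: float = 0.05,
) -> TrendResult:
    """OLS trend of (eta/eta0)^(1/3) against r with a 95% CI on the slope.

    The series is "flat" when the CI contains zero or when the predicted
    change over the observed r range is below the threshold (in cube-root
    units); otherwise the slope sign labels it increasing/decreasing.
    """
    pts = [
        (p.r, p.value) if isinstance(p, RelativeViscosityPoint) else (float(p[0]), float(p[1]))
        for p in series
    ]
    if len(pts) < 4:
        raise ValidationError(f"trend test needs >= 4 points, got {len(pts)}")
    r = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    fit = ols(r, v)
    tcrit = stats.t.ppf(0.975, fit.n - 2) if fit.n > 2 else float("inf")
    ci = (fit.slope - tcrit * fit.slope_stderr, fit.slope + tcrit * fit.slope_stderr)
    change = fit.slope * float(np.ptp(r))
    if ci[0] <= 0.0 <= ci[1] or abs(change) < flat_change_threshold:
        cls = "flat"
    elif fit.slope > 0:
        cls = "increasing"
    else:
        cls = "decreasing"
    return TrendResult(
        slope=fit.slope,
        slope_ci=(float(ci[0]), float(ci[1])),
        classification=cls,
        predicted_change=float(change),
        n=fit.n,
    )


@dataclass
class HerschelBulkleyFit:
    """tau = tau0 + K*gamma^n with parameter SEs and fit diagnostics."""

    tau0: float
    k: float
    n: float
    tau0_stderr: float
    k_stderr: float
    n_stderr: float
    rmse: float
    extras: dict[str, Any] = field(default_factory=dict)

    def apparent_viscosity(self, shear_rate: float) -> float:
        """eta_app = tau(gamma)/gamma (Pa s) at the given shear rate (1/s)."""
        if shear_rate <= 0:
            raise ValidationError("shear rate must be positive")
        return (self.tau0 + self.k * shear_rate**self.n) / shear_rate

    def to_dict(self) -> dict[str, Any]:
        return {
            "tau0_Pa": self.tau0,
            "K_Pa_sn": self.k,
            "n": self.n,
            "tau0_stderr": self.tau0_stderr,
            "K_stderr": self.k_stderr,
            "n_stderr": self.n_stderr,
            "rmse": self.rmse,
        }


def _hb(gamma, tau0, k, n):
    return tau0 + k * np.power(gamma, n)


def herschel_bulkley_fit(rheogram: Rheogram) -> HerschelBulkleyFit:
    """Nonlinear least-squares Herschel-Bulkley fit with multi-start.

    Constraints tau0 >= 0, K > 0, n > 0 are enforced through bounds.  Three
    starts at n in {0.5, 1, 1.5} (K matched to the data scale) are tried and
    the lowest-SSE converged solution wins.  All-starts failure raises
    FitError with the residual scale in the message.
    """
    gamma = rheogram.shear_rate
    tau = rheogram.shear_stress
    if gamma.size < 5:
        raise ValidationError(f"need >= 5 points for a 3-parameter fit, got {gamma.size}")
    if np.all(tau == 0):
        raise FitError("all stresses are zero: no flow curve to fit")
    tau0_guess = max(float(tau.min()), 0.0)
    best = None
    bounds = ([0.0, 1e-30, 1e-6], [np.inf, np.inf, 10.0])
    for n0 in (0.5, 1.0, 1.5):
        span = float(tau.max() - tau0_guess)
        k0 = max(span, 1e-12) / float(gamma.max() ** n0)
        try:
            popt, pcov = curve_fit(
                _hb, gamma, tau, p0=[tau0_guess, k0, n0], bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((tau - _hb(gamma, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitError(
            f"Herschel-Bulkley fit failed from all starts (stress range {np.ptp(tau):.3g} Pa)"
        )
    sse, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    rmse = float(np.sqrt(sse / gamma.size))
    log.info(
        "herschel_bulkley: tau0=%.3g Pa, K=%.3g, n=%.3f (rmse %.2g)",
        popt[0], popt[1], popt[2], rmse,
    )
    return HerschelBulkleyFit(
        tau0=float(popt[0]), k=float(popt[1]), n=float(popt[2]),
        tau0_stderr=float(perr[0]), k_stderr=float(perr[1]), n_stderr=float(perr[2]),
        rmse=rmse,
    )
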