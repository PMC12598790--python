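"""van't Hoff analysis of the temperature dependence of a binding constant.

ln Kb = -dH/(R*T) + dS/R, so an OLS fit of ln Kb against 1/T yields
dH = -R*slope and dS = R*intercept (R = 8.314 J/(mol K); Kb is treated as
dimensionless against the implicit 1 M standard state).  Gibbs energies
follow from dG = dH - T*dS, and the signs of (dH, dS) classify the dominant
interaction force by the conventional rule: (+,+) hydrophobic, (-,-) van der
Waals / hydrogen bonding, (-,+) electrostatic.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .errors import FitError
from .regression import ols
from .types import ForceClass, ThermoResult

__all__ = ["R_GAS", "vant_hoff_fit", "gibbs", "classify_forces"]

R_GAS = 8.314  # J/(mol K)

log = logging.getLogger(__name__)


def classify_forces(delta_h: float, delta_s: float, *,
                    delta_h_stderr: float = 0.0, delta_s_stderr: float = 0.0,
                    significance_aware: bool = False) -> ForceClass:
    """Sign-rule classification of the dominant binding force.

    Point-estimate signs are used by default.  With significance_aware=True
    a sign is only trusted when the estimate clears a +/- 2 SE band around
    zero; otherwise the class is indeterminate.
    """
    if significance_aware:
        if abs(delta_h) < 2 * delta_h_stderr or abs(delta_s) < 2 * delta_s_stderr:
            return ForceClass.INDETERMINATE
    if delta_h > 0 and delta_s > 0:
        return ForceClass.HYDROPHOBIC
    if delta_h < 0 and delta_s < 0:
        return ForceClass.VDW_OR_HBOND
    if delta_h < 0 and delta_s > 0:
        return ForceClass.ELECTROSTATIC
    return ForceClass.INDETERMINATE


def gibbs(delta_h: float, delta_s: float, temps: Iterable[float]) -> dict[float, float]:
    """dG = dH - T*dS per temperature; dH in kJ/mol, dS in J/(mol K), T in K.

    Returns a {T: dG} mapping in kJ/mol.
    """
    return {float(t): delta_h - float(t) * delta_s / 1000.0 for t in temps}


def vant_hoff_fit(points: Sequence[tuple[float, float]]) -> ThermoResult:
    """Estimate dH and dS from (temperature K, Kb 1/M) pairs.

    Requires >= 3 distinct temperatures with positive Kb.  A curvature
    warning is set when adding a quadratic term in 1/T is significant at the
    2 SE level (only assessable with >= 4 points), signalling a
    temperature-dependent enthalpy.
    """
    pts = [(float(t), float(kb)) for t, kb in points]
    if len(pts) < 3:
        raise FitError(f"need at least 3 temperature points, got {len(pts)}")
    temps = np.array([t for t, _ in pts])
    kbs = np.array([kb for _, kb in pts])
    if len(set(temps.tolist())) != temps.size:
        raise FitError("duplicate temperatures in van't Hoff input")
    if np.any(kbs <= 0):
        raise FitError("all binding constants must be positive")
    x = 1.0 / temps
    y = np.log(kbs)
    fit = ols(x, y)
    delta_h = -R_GAS * fit.slope / 1000.0  # kJ/mol
    delta_s = R_GAS * fit.intercept  # J/(mol K)
    delta_h_stderr = R_GAS * fit.slope_stderr / 1000.0
    delta_s_stderr = R_GAS * fit.intercept_stderr

    curvature = False
    notes: list[str] = []
    if temps.size >= 4:
        coeffs, cov = np.polyfit(x, y, 2, cov=True)
        if abs(coeffs[0]) > 2.0 * np.sqrt(cov[0, 0]):
            curvature = True
            notes.append("quadratic term in 1/T significant: enthalpy may vary with T")
            log.warning(notes[-1])

    force = classify_forces(delta_h, delta_s)
    result = ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_per_temperature=gibbs(delta_h, delta_s, temps),
        force_class=force,
        delta_h_stderr=delta_h_stderr,
        delta_s_stderr=delta_s_stderr,
        curvature_warning=curvature,
        notes=notes,
    )
    log.info(
        "vant_hoff: dH=%.3f +/- %.3f kJ/mol, dS=%.2f +/- %.2f J/(mol K), %s (n=%d)",
        delta_h, delta_h_stderr, delta_s, delta_s_stderr, force.value, temps.size,
    )
    return result
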