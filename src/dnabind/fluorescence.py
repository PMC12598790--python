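"""Fluorescence quenching analysis.

Three classical treatments of a probe-displacement titration:

* Stern-Volmer: I0/I = 1 + Ksv*[Q]; Ksv is the slope of I0/I against the
  quencher concentration.  The intercept is fitted freely and a deviation
  from unity beyond 0.1 is flagged rather than forced.
* Double-log: log10((I0 - I)/I) = log10 Kb + n*log10 [Q]; the intercept
  gives the binding constant, the slope the apparent stoichiometry n.
  Base-10 logs are used consistently on both sides, so Kb is unaffected by
  the base choice.
* Displacement comparison: whichever site-selective probe (EtBr,
  intercalation; Hoechst 33258, minor groove) is quenched much more strongly
  marks the site class the test ligand occupies.

No inner-filter correction is applied by default; pass a correction callable
to :func:`stern_volmer_fit` if absorbance at the excitation/emission
wavelengths is significant.
"""

from __future__ import annotations

import enum
import logging
from typing import Callable

import numpy as np

from .errors import FitError, ParameterError, ValidationError
from .regression import ols
from .types import BindingFit, FitMethod, TitrationSeries

__all__ = ["stern_volmer_fit", "double_log_fit", "displacement_compare", "DisplacementCall"]

log = logging.getLogger(__name__)


class DisplacementCall(str, enum.Enum):
    GROOVE_PROBE_DISPLACED = "groove_probe_displaced"
    INTERCALATOR_PROBE_DISPLACED = "intercalator_probe_displaced"
    INDETERMINATE = "indeterminate"


def _prepare(series: TitrationSeries, correction: Callable | None):
    conc = series.ligand_conc
    intensity = series.response.astype(float)
    if correction is not None:
        intensity = np.asarray(correction(conc, intensity), dtype=float)
    if np.any(intensity <= 0):
        raise ValidationError("fluorescence intensities must be positive")
    if conc[0] != 0.0:
        raise FitError("series must include a zero-quencher point to define I0")
    return conc, intensity


def stern_volmer_fit(
    series: TitrationSeries, *, inner_filter_correction: Callable | None = None
) -> BindingFit:
    """Fit I0/I = 1 + Ksv*[Q] by OLS with a free intercept.

    Returns a BindingFit whose ``kb`` field carries Ksv (1/M).  A warning is
    recorded when the free intercept strays more than 0.1 from the
    theoretical value of 1.
    """
    conc, intensity = _prepare(series, inner_filter_correction)
    i0 = intensity[0]
    y = i0 / intensity
    fit = ols(conc, y)
    warnings: list[str] = []
    if abs(fit.intercept - 1.0) > 0.1:
        warnings.append(f"Stern-Volmer intercept {fit.intercept:.3f} deviates from 1 by > 0.1")
        log.warning(warnings[-1])
    if fit.slope <= 0:
        raise FitError("non-positive Stern-Volmer slope: no quenching detected")
    log.info("stern_volmer: Ksv=%.4g +/- %.2g 1/M (n=%d)", fit.slope, fit.slope_stderr, fit.n)
    return BindingFit(
        kb=fit.slope,
        kb_stderr=fit.slope_stderr,
        method=FitMethod.STERN_VOLMER,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        n_points=fit.n,
        warnings=warnings,
    )


def double_log_fit(
    series: TitrationSeries, *, inner_filter_correction: Callable | None = None
) -> BindingFit:
    """Fit log10((I0-I)/I) vs log10 [Q]; Kb = 10**intercept, n = slope.

    The zero-quencher point defines I0 and is excluded from the regression;
    interior points with I >= I0 (no net quenching) are excluded with a
    warning.
    """
    conc, intensity = _prepare(series, inner_filter_correction)
    i0 = intensity[0]
    q = conc[1:]
    i = intensity[1:]
    usable = (i < i0) & (q > 0)
    warnings: list[str] = []
    if not np.all(usable):
        warnings.append(f"excluded {int(np.sum(~usable))} point(s) with I >= I0")
        log.warning(warnings[-1])
    q, i = q[usable], i[usable]
    if q.size < 3:
        raise FitError(f"need >=3 usable quenched points, got {q.size}")
    fit = ols(np.log10(q), np.log10((i0 - i) / i))
    kb = 10.0**fit.intercept
    # d(10^b)/db = 10^b * ln 10
    kb_stderr = kb * np.log(10.0) * fit.intercept_stderr
    log.info(
        "double_log: Kb=%.4g +/- %.2g 1/M, n=%.3f +/- %.3f",
        kb, kb_stderr, fit.slope, fit.slope_stderr,
    )
    return BindingFit(
        kb=kb,
        kb_stderr=float(kb_stderr),
        method=FitMethod.DOUBLE_LOG,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        n_points=fit.n,
        n_stoichiometry=fit.slope,
        warnings=warnings,
    )


def displacement_compare(
    fit_etbr: BindingFit, fit_hoechst: BindingFit, ratio_threshold: float = 5.0
) -> DisplacementCall:
    """Compare probe quenching constants to identify the displaced probe.

    A Hoechst/EtBr Ksv ratio at or above the threshold means the
    minor-groove probe is displaced (the ligand competes for the groove);
    the reciprocal case implicates the intercalation site; anything in
    between is indeterminate.
    """
    if ratio_threshold <= 1:
        raise ParameterError("ratio_threshold must exceed 1")
    if fit_etbr.kb <= 0 or fit_hoechst.kb <= 0:
        raise ParameterError("quenching constants must be positive")
    ratio = fit_hoechst.kb / fit_etbr.kb
    if ratio >= ratio_threshold:
        return DisplacementCall.GROOVE_PROBE_DISPLACED
    if 1.0 / ratio >= ratio_threshold:
        return DisplacementCall.INTERCALATOR_PROBE_DISPLACED
    return DisplacementCall.INDETERMINATE
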