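"""UV-vis binding analysis: double-reciprocal binding constant and
classification of the spectral change direction.

The Benesi-Hildebrand treatment linearizes the 1:1 complexation isotherm.
With the apparent per-point extinction coefficient eps_a = A/(l*[DNA]) and
the free-form coefficient eps_f taken from the zero-ligand point,

    x / (eps_a - eps_f) = x / (eps_b - eps_f) + 1 / (Kb * (eps_b - eps_f))

is linear in the titrant concentration x, and Kb = slope/intercept.  The
classic presentation writes x as [DNA]; in this study the DNA is fixed and
the drug is varied, so the default mode regresses against the ligand axis,
with ``vary_dna`` available for the literal double-reciprocal reading.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError
from .regression import ols
from .types import BindingFit, FitMethod, SeriesKind, SpectralChange, TitrationSeries

__all__ = ["benesi_hildebrand_fit", "classify_spectral_change"]

log = logging.getLogger(__name__)


def benesi_hildebrand_fit(series: TitrationSeries, mode: str = "vary_ligand") -> BindingFit:
    """Estimate the binding constant from a UV titration.

    Parameters
    ----------
    series : TitrationSeries with a zero-ligand point (defines eps_f).
    mode : "vary_ligand" (default; x = titrant concentration) or "vary_dna"
        (x = macromolecule concentration axis, the literal textbook form).

    Returns
    -------
    BindingFit with method "benesi_hildebrand".  Kb = slope/intercept; its
    standard error comes from first-order propagation of the slope and
    intercept errors including their covariance.  The fit is flagged
    unreliable when the intercept is statistically indistinguishable from
    zero (|intercept| < 2 SE), where the ratio degenerates.
    """
    if mode not in ("vary_ligand", "vary_dna"):
        raise ValidationError("mode must be 'vary_ligand' or 'vary_dna'")
    conc = series.ligand_conc
    if conc[0] != 0.0:
        raise FitError("series must include a zero-ligand point to define eps_f")
    path = float(series.metadata.get("path_cm", 1.0))
    eps = series.response / (path * series.macromolecule_conc)
    eps_f = eps[0]
    delta = eps[1:] - eps_f
    x_all = conc[1:]
    # overall spectral direction decides which sign of (eps_a - eps_f) is
    # physical; the ratio slope/intercept is the same for either direction
    direction = np.sign(np.median(delta[delta != 0])) if np.any(delta != 0) else 0.0
    if direction == 0.0:
        raise FitError("eps_a identical to eps_f at every point: no complexation signal")
    usable = np.sign(delta) == direction
    warnings: list[str] = []
    if not np.all(usable):
        n_dropped = int(np.sum(~usable))
        trend = "hyperchromic" if direction > 0 else "hypochromic"
        warnings.append(
            f"excluded {n_dropped} point(s) with eps_a on the wrong side of eps_f "
            f"for a {trend} series"
        )
        log.warning(warnings[-1])
    x = x_all[usable]
    delta = delta[usable]
    if x.size < 3:
        raise FitError(f"need >=3 usable points with eps_a != eps_f, got {x.size}")
    y = x / delta
    fit = ols(x, y)
    if fit.intercept == 0:
        raise FitError("zero intercept: binding constant undefined")
    kb = fit.slope / fit.intercept
    if kb <= 0:
        if abs(fit.intercept) < 2.0 * fit.intercept_stderr:
            raise FitError(
                "intercept indistinguishable from zero (|i| < 2 SE): "
                "binding constant undefined for a saturated titration"
            )
        raise FitError("non-positive binding constant from slope/intercept ratio")
    # var(s/i) ~ (ds/i)^2 + (s*di/i^2)^2 - 2*(s/i^3)*cov(s,i)
    s, i = fit.slope, fit.intercept
    var = (
        (fit.slope_stderr / i) ** 2
        + (s * fit.intercept_stderr / i**2) ** 2
        - 2.0 * s / i**3 * fit.cov_slope_intercept
    )
    kb_stderr = float(np.sqrt(max(var, 0.0)))
    reliable = abs(i) >= 2.0 * fit.intercept_stderr
    if not reliable:
        warnings.append("intercept indistinguishable from zero (|i| < 2 SE); Kb unreliable")
        log.warning(warnings[-1])
    log.info(
        "benesi_hildebrand: Kb=%.4g +/- %.2g 1/M (n=%d, R^2=%.4f)",
        kb, kb_stderr, fit.n, fit.r_squared,
    )
    return BindingFit(
        kb=kb,
        kb_stderr=kb_stderr,
        method=FitMethod.BENESI_HILDEBRAND,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        n_points=fit.n,
        reliable=reliable,
        warnings=warnings,
    )


def classify_spectral_change(
    series: TitrationSeries,
) -> tuple[SpectralChange, float | None]:
    """Classify the monotone trend of the optical response with ligand.

    Uses the Theil-Sen slope of response vs ligand concentration with its
    95% confidence interval; the trend is "none" when the interval spans
    zero.  Returns (classification, peak_shift_nm); the shift is None here
    because single-wavelength series carry no peak-position information.
    """
    if len(series) < 3:
        raise ValidationError("need at least 3 points to classify a spectral trend")
    if series.kind is not SeriesKind.UV_ABSORBANCE:
        log.info("classifying spectral trend of a non-UV series (%s)", series.kind.value)
    slope, _, lo, hi = stats.theilslopes(series.response, series.ligand_conc)
    if lo <= 0.0 <= hi:
        # a strictly monotone noiseless ramp has a degenerate all-equal slope
        # distribution (lo == hi == slope); only a genuine sign ambiguity is "none"
        if lo == hi and slope != 0.0:
            change = SpectralChange.HYPERCHROMIC if slope > 0 else SpectralChange.HYPOCHROMIC
        else:
            change = SpectralChange.NONE
    elif slope > 0:
        change = SpectralChange.HYPERCHROMIC
    else:
        change = SpectralChange.HYPOCHROMIC
    return change, None
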