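"""van't Hoff regression, Gibbs energies and force-sign classification."""

import math

import numpy as np
import pytest

from dnabind import R_GAS, ForceClass, classify_forces, gibbs, vant_hoff_fit
from dnabind.errors import FitError

# the study's binding constants vs temperature (K, 1/M)
KB_TABLE = [(288.15, 3.71e4), (298.15, 3.22e4), (308.15, 3.12e4)]


def _oracle_ols(x, y):
    """Independent closed-form least squares (normal equations via numpy)."""
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return slope, intercept


def test_printed_kb_triple_reproduces_reported_enthalpy_and_entropy():
    """OLS of ln Kb on 1/T over the three printed binding constants lands
    within a few percent of the reported dH = -6.70 kJ/mol and
    dS = +64.11 J/(mol K) (which were derived from unrounded Kb)."""
    result = vant_hoff_fit(KB_TABLE)
    assert result.delta_h == pytest.approx(-6.70, rel=0.05)
    assert result.delta_s == pytest.approx(64.11, rel=0.03)
    assert result.force_class is ForceClass.ELECTROSTATIC
    # cross-check against an independent least-squares computation
    x = np.array([1.0 / t for t, _ in KB_TABLE])
    y = np.array([math.log(kb) for _, kb in KB_TABLE])
    slope, intercept = _oracle_ols(x, y)
    assert result.delta_h == pytest.approx(-R_GAS * slope / 1000.0, rel=1e-12)
    assert result.delta_s == pytest.approx(R_GAS * intercept, rel=1e-12)


def test_exact_generation_recovered_to_machine_precision():
    dh, ds = -6.70, 64.11  # kJ/mol, J/(mol K)
    temps = [288.15, 298.15, 308.15]
    points = [(t, math.exp(-dh * 1000.0 / (R_GAS * t) + ds / R_GAS)) for t in temps]
    result = vant_hoff_fit(points)
    assert result.delta_h == pytest.approx(dh, rel=1e-12)
    assert result.delta_s == pytest.approx(ds, rel=1e-12)
    assert not result.curvature_warning


def test_constant_kb_means_zero_enthalpy():
    kb = 5.0e4
    result = vant_hoff_fit([(288.15, kb), (298.15, kb), (308.15, kb)])
    assert result.delta_h == pytest.approx(0.0, abs=1e-9)
    assert result.delta_s == pytest.approx(R_GAS * math.log(kb), rel=1e-12)


def test_gibbs_self_consistency_with_vant_hoff():
    """gibbs() applied to a fit of exactly log-linear data reproduces
    -RT ln Kb at each generating temperature."""
    dh, ds = -12.5, 40.0
    temps = [280.0, 295.0, 310.0, 325.0]
    points = [(t, math.exp(-dh * 1000.0 / (R_GAS * t) + ds / R_GAS)) for t in temps]
    result = vant_hoff_fit(points)
    for t, kb in points:
        expected = -R_GAS * t * math.log(kb) / 1000.0
        assert result.delta_g_per_temperature[t] == pytest.approx(expected, rel=1e-9)


def test_curvature_warning_on_nonlinear_arrhenius_data():
    temps = np.linspace(280, 330, 8)
    # ln Kb deliberately quadratic in 1/T
    x = 1.0 / temps
    lnkb = 5.0 + 800.0 * x + 5.0e8 * (x - x.mean()) ** 2
    points = list(zip(temps, np.exp(lnkb)))
    assert vant_hoff_fit(points).curvature_warning


@pytest.mark.parametrize(
    "dh, ds, expected",
    [
        (5.0, 10.0, ForceClass.HYDROPHOBIC),
        (-5.0, -10.0, ForceClass.VDW_OR_HBOND),
        (-6.70, 64.11, ForceClass.ELECTROSTATIC),
        (5.0, -10.0, ForceClass.INDETERMINATE),
        (0.0, 10.0, ForceClass.INDETERMINATE),
    ],
)
def test_force_sign_rules_partition_the_plane(dh, ds, expected):
    assert classify_forces(dh, ds) is expected


def test_significance_aware_classification_needs_clear_signs():
    assert (
        classify_forces(-1.0, 5.0, delta_h_stderr=2.0, delta_s_stderr=0.1, significance_aware=True)
        is ForceClass.INDETERMINATE
    )


@pytest.mark.parametrize(
    "points, message",
    [
        ([(298.15, 1e4), (308.15, 1e4)], "at least 3"),
        ([(298.15, 1e4), (298.15, 2e4), (308.15, 1e4)], "duplicate"),
        ([(288.15, -1.0), (298.15, 1e4), (308.15, 1e4)], "positive"),
    ],
)
def test_invalid_vant_hoff_inputs(points, message):
    with pytest.raises(FitError, match=message):
        vant_hoff_fit(points)


def test_gibbs_trivial_zero():
    assert gibbs(0.0, 0.0, [250.0, 300.0]) == {250.0: 0.0, 300.0: 0.0}
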