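"""Calibration figures of merit and method-validation statistics."""

import numpy as np
import pytest

from dnabind import (
    assay_tablet,
    calibration_fit,
    gen_calibration,
    lod_loq,
    recovery_analysis,
    repeatability_rsd,
)
from dnabind.errors import FitError, ParameterError
from dnabind.synthetic import PAPER_TRUTH

SLOPE, INTERCEPT = -5e-9, 3e-7  # A/uM, A
TABLET_MG = [246.0, 247.0, 247.0, 251.0, 253.0]


def test_exact_line_recovered():
    concs = np.linspace(2.5, 20.0, 8)
    points = [(c, SLOPE * c + INTERCEPT) for c in concs]
    result = calibration_fit(points)
    assert result.slope == pytest.approx(SLOPE, rel=1e-12)
    assert result.intercept == pytest.approx(INTERCEPT, rel=1e-12)
    assert result.r_squared == pytest.approx(1.0, abs=1e-12)
    assert result.linear_range == (2.5, 20.0)
    # residuals are floating-point noise, so the limits are numerically zero
    assert result.lod == pytest.approx(0.0, abs=1e-10)
    assert result.loq == pytest.approx(0.0, abs=1e-10)


def test_concentration_inversion_round_trips():
    concs = np.linspace(2.5, 20.0, 8)
    result = calibration_fit([(c, SLOPE * c + INTERCEPT) for c in concs])
    for c in (3.0, 10.0, 19.0):
        assert result.concentration(SLOPE * c + INTERCEPT) == pytest.approx(c, rel=1e-9)


def test_lod_loq_ratio_is_exactly_ten_thirds():
    for sd, slope in [(1.155e-9, -5e-9), (3.3e-8, 2e-7), (1.0, 4.0)]:
        lod, loq = lod_loq(sd, slope)
        assert loq / lod == pytest.approx(10.0 / 3.0, rel=1e-14)


def test_lod_loq_worked_example():
    # SD backed out of LOQ = 2.31 uM at |slope| = 5e-9 A/uM
    sd = 2.31 * 5e-9 / 10.0
    lod, loq = lod_loq(sd, -5e-9)
    assert loq == pytest.approx(2.31, rel=1e-12)
    assert lod == pytest.approx(0.693, rel=1e-12)


def test_zero_sd_gives_zero_limits_and_zero_slope_errors():
    assert lod_loq(0.0, -5e-9) == (0.0, 0.0)
    with pytest.raises(ParameterError):
        lod_loq(1e-9, 0.0)


def test_limits_invariant_to_current_unit_rescaling():
    concs = np.linspace(2.5, 20.0, 10)
    rng = np.random.default_rng(3)
    currents = SLOPE * concs + INTERCEPT + rng.normal(0, 1e-9, concs.size)
    a = calibration_fit(list(zip(concs, currents)))
    c = 1e6
    b = calibration_fit(list(zip(concs, currents * c)))
    assert b.slope == pytest.approx(a.slope * c, rel=1e-12)
    assert b.residual_sd == pytest.approx(a.residual_sd * c, rel=1e-9)
    assert b.lod == pytest.approx(a.lod, rel=1e-9)
    assert b.loq == pytest.approx(a.loq, rel=1e-9)


def test_calibration_scatter_envelope_matches_target_r_squared():
    """Residual SD chosen for R^2 ~ 0.97 over 2.5-20 uM keeps the fitted R^2
    inside [0.94, 0.99] in the typical case (median over 200 seeds)."""
    concs = np.linspace(2.5, 20.0, 8)
    sd_c = float(np.std(concs))
    target_r2 = 0.97
    residual_sd = abs(SLOPE) * sd_c * np.sqrt((1 - target_r2) / target_r2)
    truth = PAPER_TRUTH.with_(calib_residual_sd=residual_sd)
    r2 = []
    for seed in range(200):
        df = gen_calibration(truth, concs, seed=seed)
        r2.append(calibration_fit(list(zip(df["conc_uM"], df["current_A"]))).r_squared)
    assert 0.94 <= float(np.median(r2)) <= 0.99


def test_lod_recovery_across_seeds():
    """With the ground-truth residual SD the mean fitted LOD over 200 seeds
    lands within 5% of the implied 0.693 uM."""
    lods = []
    for seed in range(200):
        df = gen_calibration(PAPER_TRUTH, seed=seed)
        lods.append(calibration_fit(list(zip(df["conc_uM"], df["current_A"]))).lod)
    expected = 3.0 * PAPER_TRUTH.calib_residual_sd / abs(PAPER_TRUTH.calib_slope)
    assert float(np.mean(lods)) == pytest.approx(expected, rel=0.05)


def test_gross_outlier_flagged_by_studentized_residual():
    concs = np.linspace(2.5, 20.0, 8)
    rng = np.random.default_rng(11)
    sd = 1.155e-9
    currents = SLOPE * concs + INTERCEPT + rng.normal(0, sd, concs.size)
    currents[4] += 10 * sd
    result = calibration_fit(list(zip(concs, currents)))
    assert 4 in result.outlier_indices


def test_tablet_statistics_worked_example():
    stats, pct = assay_tablet(TABLET_MG, 250.0)
    assert stats.mean == pytest.approx(248.8)
    assert round(stats.mean) == 249
    assert stats.sd == pytest.approx(3.03, abs=0.005)
    assert stats.rsd_percent == pytest.approx(1.22, abs=0.005)
    assert pct == pytest.approx(100 * 248.8 / 250.0)


def test_repeatability_and_assay_agree_on_the_same_list():
    stats = repeatability_rsd(TABLET_MG)
    assay_stats, _ = assay_tablet(TABLET_MG, 250.0)
    assert stats.mean == assay_stats.mean
    assert stats.sd == assay_stats.sd
    assert stats.rsd_percent == assay_stats.rsd_percent


def test_repeatability_simulation_tracks_population_rsd():
    rng = np.random.default_rng(2)
    rsds = [
        repeatability_rsd(rng.normal(100.0, 2.0, 5)).rsd_percent for _ in range(500)
    ]
    assert float(np.mean(rsds)) == pytest.approx(2.0, rel=0.1)


def test_identical_replicates_have_zero_spread():
    stats = repeatability_rsd([5.0, 5.0, 5.0, 5.0])
    assert stats.sd == 0.0 and stats.rsd_percent == 0.0


def test_zero_content_tablet_is_not_silently_excluded():
    stats, _ = assay_tablet([0.0, 250.0, 250.0], 250.0)
    assert len(stats.per_sample) == 3
    assert stats.sd > 100.0


def test_recovery_worked_example():
    stats = recovery_analysis([0.10] * 5, [0.09, 0.08, 0.08, 0.11, 0.12])
    assert stats.per_sample == pytest.approx([90, 80, 80, 110, 120])
    assert stats.mean == pytest.approx(96.0)
    assert stats.sd == pytest.approx(18.16, abs=0.01)
    assert stats.rsd_percent == pytest.approx(18.92, abs=0.01)
    assert stats.bias_percent == pytest.approx(-4.0)


@pytest.mark.parametrize(
    "added, found, mean, bias",
    [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], 100.0, 0.0), ([2.0, 2.0, 2.0], [2.2, 2.2, 2.2], 110.0, 10.0)],
)
def test_recovery_closed_forms(added, found, mean, bias):
    stats = recovery_analysis(added, found)
    assert stats.mean == pytest.approx(mean)
    assert stats.bias_percent == pytest.approx(bias)
    assert stats.sd == pytest.approx(0.0, abs=1e-12)


def test_validation_errors():
    with pytest.raises(FitError):
        calibration_fit([(1.0, 1.0)] * 5)  # duplicate-only concentrations
    with pytest.raises(FitError):
        calibration_fit([(1.0, 1.0), (2.0, 2.0)])
    with pytest.raises(ParameterError):
        recovery_analysis([1.0, 2.0], [1.0])
    with pytest.raises(ParameterError):
        assay_tablet(TABLET_MG, 0.0)
    with pytest.raises(ParameterError):
        repeatability_rsd([1.0, 2.0])
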