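"""Baseline correction, peak location and the peak-suppression binding fit."""

import numpy as np
import pytest

from dnabind import (
    DADO_WINDOW,
    DGUO_WINDOW,
    Voltammogram,
    baseline_correct,
    electro_binding_fit,
    find_peak_current,
    gen_voltammogram,
)
from dnabind.errors import FitError, NoPeakError, ParameterError

GRID = np.arange(0.8, 1.6 + 1e-9, 0.005)


def _vgram(current):
    return Voltammogram(potential=GRID, current=np.asarray(current, float))


def test_zero_input_stays_zero():
    out = baseline_correct(_vgram(np.zeros(GRID.size)))
    assert np.allclose(out.current, 0.0)


def test_linear_ramp_is_removed():
    ramp = 2e-6 * (GRID - GRID[0])
    out = baseline_correct(_vgram(ramp), window_points=21)
    assert np.max(np.abs(out.current)) < 0.01 * np.ptp(ramp)


def test_peak_height_preserved_on_ramp(truth):
    v = gen_voltammogram(truth.with_(peak_heights=(1.2e-6,), peak_centers=(1.09,),
                                     peak_widths=(0.03,), electro_kb=(6.02e4,)), GRID)
    out = baseline_correct(v, window_points=41)
    peak = find_peak_current(out, DGUO_WINDOW)
    assert peak.current == pytest.approx(1.2e-6, rel=0.02)


def test_baseline_correction_is_idempotent(truth):
    v = gen_voltammogram(truth, GRID)
    once = baseline_correct(v, 41)
    twice = baseline_correct(once, 41)
    scale = np.max(np.abs(once.current))
    assert np.max(np.abs(twice.current - once.current)) < 1e-3 * scale


def test_corrected_current_nonnegative(truth):
    v = gen_voltammogram(truth, GRID)
    out = baseline_correct(v, 21)
    assert np.all(out.current >= -1e-18)


@pytest.mark.parametrize("window", [2, 1, 400])
def test_invalid_baseline_window_rejected(truth, window):
    with pytest.raises(ParameterError):
        baseline_correct(gen_voltammogram(truth, GRID), window)


def test_single_peak_on_flat_baseline_found_exactly():
    height, center = 1.0e-6, 1.09
    current = height * np.exp(-((GRID - center) ** 2) / (2 * 0.03**2))
    peak = find_peak_current(_vgram(current), DGUO_WINDOW)
    assert peak.potential == pytest.approx(center, abs=0.0025)  # half a grid step
    assert peak.current == pytest.approx(height, rel=1e-3)


def test_both_dna_base_peaks_recovered(truth):
    v = baseline_correct(gen_voltammogram(truth, GRID), 41)
    dguo = find_peak_current(v, DGUO_WINDOW)
    dado = find_peak_current(v, DADO_WINDOW)
    assert dguo.potential == pytest.approx(1.09, abs=0.005)
    assert dado.potential == pytest.approx(1.36, abs=0.005)
    assert dguo.current > dado.current  # dGuo signal dominates by design


def test_zero_peak_heights_mean_no_peak(truth):
    flat = truth.with_(peak_heights=(0.0, 0.0))
    v = baseline_correct(gen_voltammogram(flat, GRID), 21)
    with pytest.raises(NoPeakError):
        find_peak_current(v, DGUO_WINDOW)


def test_pure_noise_has_no_peak():
    rng = np.random.default_rng(7)
    v = baseline_correct(_vgram(rng.normal(0, 1e-8, GRID.size)), 21)
    with pytest.raises(NoPeakError):
        find_peak_current(v, DGUO_WINDOW)


def test_window_outside_sweep_rejected(truth):
    v = gen_voltammogram(truth, GRID)
    with pytest.raises(ParameterError):
        find_peak_current(v, (2.0, 2.5))


def test_electro_fit_recovers_generating_constant(truth):
    kb, s_free = 6.02e4, 1.2e-6
    concs = np.linspace(5e-6, 40e-6, 8)
    currents = s_free / (1.0 + kb * concs)
    fit = electro_binding_fit(list(zip(concs, currents)), s_free)
    assert fit.kb == pytest.approx(kb, rel=1e-3)
    assert fit.slope == pytest.approx(1.0, abs=1e-9)
    assert not fit.warnings


def test_half_suppression_point_lies_on_the_line():
    """At [drug] = 1/Kb the complexed current is exactly half the free one."""
    kb, s_free = 6.02e4, 1.0e-6
    concs = np.array([0.5 / kb, 1.0 / kb, 2.0 / kb])
    currents = s_free / (1.0 + kb * concs)
    assert currents[1] == pytest.approx(s_free / 2, rel=1e-12)
    fit = electro_binding_fit(list(zip(concs, currents)), s_free)
    assert fit.kb == pytest.approx(kb, rel=1e-9)


def test_kb_invariant_to_current_units():
    kb, s_free = 5.75e3, 0.8e-6
    concs = np.linspace(5e-6, 40e-6, 6)
    currents = s_free / (1.0 + kb * concs)
    a = electro_binding_fit(list(zip(concs, currents)), s_free)
    b = electro_binding_fit(list(zip(concs, currents * 1e3)), s_free * 1e3)
    assert b.kb == pytest.approx(a.kb, rel=1e-12)


def test_super_free_currents_excluded_then_too_few_points_errors():
    s_free = 1e-6
    concs = np.linspace(5e-6, 20e-6, 4)
    currents = np.array([1.1e-6, 0.9e-6, 1.2e-6, 1.05e-6])  # 3 of 4 unusable
    with pytest.raises(FitError, match="usable"):
        electro_binding_fit(list(zip(concs, currents)), s_free)
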