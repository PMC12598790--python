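"""Relative-viscosity titrations and Herschel-Bulkley rheology."""

import numpy as np
import pytest

from dnabind import (
    FlowTimeSeries,
    Rheogram,
    gen_flow_times,
    gen_rheogram,
    herschel_bulkley_fit,
    relative_viscosity_series,
    viscosity_trend_test,
)
from dnabind.errors import FitError, ValidationError

# flow-curve viscosities (mPa s) for free DNA then ten drug additions, as a
# rheometer would report them over the r = 0.25..3.0 titration
DNA_SERIES_MPAS = [16.40, 16.35, 16.35, 16.38, 16.44, 16.52, 16.60, 16.60, 16.61, 16.67, 16.69]


def _flow(t0, times, concs, dna=120e-6):
    return FlowTimeSeries(t0=t0, t=np.asarray(times, float), ligand_conc=np.asarray(concs, float), dna_conc=dna)


def test_unchanged_flow_times_give_unit_relative_viscosity():
    concs = np.linspace(0, 3.6e-4, 7)
    series = relative_viscosity_series(_flow(100.0, np.full(7, 150.0), concs))
    assert all(p.value == pytest.approx(1.0, abs=1e-12) for p in series)


def test_doubled_specific_viscosity_gives_cube_root_of_two():
    # eta0 = 0.5; second point constructed so eta = 1.0
    series = relative_viscosity_series(_flow(100.0, [150.0, 200.0, 200.0], [0.0, 1e-4, 2e-4]))
    assert series[1].value == pytest.approx(2.0 ** (1.0 / 3.0), rel=1e-12)


def test_values_invariant_to_rescaling_all_flow_times():
    concs = np.linspace(0, 3e-4, 6)
    times = 150.0 + 10.0 * np.linspace(0, 1, 6)
    a = relative_viscosity_series(_flow(100.0, times, concs))
    b = relative_viscosity_series(_flow(100.0 * 3.7, times * 3.7, concs))
    for pa, pb in zip(a, b):
        assert pb.value == pytest.approx(pa.value, rel=1e-12)


def test_dna_not_above_buffer_is_an_error():
    with pytest.raises(ValidationError, match="eta0"):
        relative_viscosity_series(_flow(100.0, [100.0, 150.0, 160.0], [0.0, 1e-4, 2e-4]))


def test_sub_buffer_flow_time_is_flagged_not_dropped():
    series = relative_viscosity_series(_flow(100.0, [150.0, 90.0, 150.0], [0.0, 1e-4, 2e-4]))
    assert series[1].flagged and not series[0].flagged
    assert len(series) == 3


def test_constant_series_is_flat():
    pts = [(r, 1.0) for r in np.linspace(0, 3, 8)]
    assert viscosity_trend_test(pts).classification == "flat"


def test_groove_binder_generator_series_is_flat(truth):
    series = relative_viscosity_series(gen_flow_times(truth))
    assert viscosity_trend_test(series).classification == "flat"


def test_intercalator_generator_series_is_increasing(intercalator_truth):
    series = relative_viscosity_series(gen_flow_times(intercalator_truth))
    result = viscosity_trend_test(series)
    assert result.classification == "increasing"
    assert result.predicted_change > 0.15


def test_flow_curve_viscosity_series_is_flat():
    """A ~2% total drift in measured viscosity over the whole titration does
    not register as the monotone rise an intercalator produces."""
    eta0 = DNA_SERIES_MPAS[0]
    r = np.concatenate([[0.0], np.linspace(0.25, 3.0, 10)])
    values = [(v / eta0) ** (1.0 / 3.0) for v in DNA_SERIES_MPAS]
    assert viscosity_trend_test(list(zip(r, values))).classification == "flat"


def test_trend_needs_four_points():
    with pytest.raises(ValidationError):
        viscosity_trend_test([(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)])


def test_herschel_bulkley_noiseless_recovery(truth):
    fit = herschel_bulkley_fit(gen_rheogram(truth))
    tau0, k, n = truth.hb_params
    assert fit.tau0 == pytest.approx(tau0, rel=1e-3)
    assert fit.k == pytest.approx(k, rel=1e-3)
    assert fit.n == pytest.approx(n, rel=1e-3)
    # noiseless residuals vanish
    model = fit.tau0 + fit.k * gen_rheogram(truth).shear_rate ** fit.n
    rel = np.abs(model - gen_rheogram(truth).shear_stress) / gen_rheogram(truth).shear_stress
    assert np.max(rel) < 1e-8


def test_newtonian_reduction():
    rates = np.linspace(10, 500, 12)
    visc = 1.6e-2  # Pa s
    fit = herschel_bulkley_fit(Rheogram(shear_rate=rates, shear_stress=visc * rates))
    assert fit.n == pytest.approx(1.0, abs=1e-6)
    assert fit.k == pytest.approx(visc, rel=1e-6)
    assert fit.tau0 == pytest.approx(0.0, abs=1e-8)
    assert fit.apparent_viscosity(250.0) == pytest.approx(visc, rel=1e-6)


def test_zero_stress_fails():
    rates = np.linspace(10, 500, 8)
    with pytest.raises(FitError):
        herschel_bulkley_fit(Rheogram(shear_rate=rates, shear_stress=np.zeros(8)))
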