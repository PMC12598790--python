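"""Double-reciprocal binding analysis and spectral-trend classification."""

import numpy as np
import pytest

from dnabind import (
    SpectralChange,
    TitrationSeries,
    benesi_hildebrand_fit,
    classify_spectral_change,
    gen_uv_titration,
)
from dnabind.errors import FitError, ValidationError


def test_noiseless_recovery_is_exact_under_the_model_assumptions(truth):
    """With free ligand ~ total ligand (the approximation the linearization
    itself makes), the noiseless fit returns the generating Kb exactly."""
    fit = benesi_hildebrand_fit(gen_uv_titration(truth, free_ligand="total"))
    assert fit.kb == pytest.approx(truth.kb_true, rel=1e-9)
    assert fit.reliable
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_mass_action_depletion_biases_the_linearized_estimate(truth):
    """At 150 uM DNA and Kb ~ 3e4 the ligand pool is strongly depleted; the
    free ~ total assumption then fails and the double-reciprocal estimate is
    biased low by far more than a few percent.  This quantifies the known
    weakness of the method rather than hiding it."""
    fit = benesi_hildebrand_fit(gen_uv_titration(truth, free_ligand="exact"))
    assert fit.kb < 0.5 * truth.kb_true


def test_fully_saturated_series_is_flagged_unreliable(truth):
    # Kb*L >> 1 at every point: eps_a ~ eps_b everywhere, so the
    # double-reciprocal intercept vanishes into the measurement noise
    sat = truth.with_(kb_true=1e9, noise_uv=1e-5, seed=2)
    series = gen_uv_titration(sat, free_ligand="total")
    fit = benesi_hildebrand_fit(series)
    assert not fit.reliable
    assert any("intercept" in w for w in fit.warnings)


def test_kb_is_invariant_to_response_rescaling(truth):
    series = gen_uv_titration(truth, free_ligand="total")
    scaled = TitrationSeries(
        ligand_conc=series.ligand_conc,
        response=series.response * 7.3,
        macromolecule_conc=series.macromolecule_conc,
        wavelength_nm=series.wavelength_nm,
        kind=series.kind,
    )
    kb_a = benesi_hildebrand_fit(series).kb
    kb_b = benesi_hildebrand_fit(scaled).kb
    assert kb_b == pytest.approx(kb_a, rel=1e-9)


def test_hypochromic_series_yields_the_same_positive_kb(truth):
    """Both spectral directions carry the same isotherm; the slope/intercept
    ratio cancels the sign of (eps_b - eps_f)."""
    hypo = truth.with_(eps_b=truth.eps_f - (truth.eps_b - truth.eps_f))
    fit = benesi_hildebrand_fit(gen_uv_titration(hypo, free_ligand="total"))
    assert fit.kb == pytest.approx(truth.kb_true, rel=1e-9)


def test_missing_zero_ligand_point_is_an_error(truth):
    series = gen_uv_titration(truth, ligand_concs=np.linspace(25e-6, 300e-6, 6))
    with pytest.raises(FitError, match="zero-ligand"):
        benesi_hildebrand_fit(series)


def test_vary_dna_mode_accepted_and_others_rejected(truth):
    series = gen_uv_titration(truth, free_ligand="total")
    assert benesi_hildebrand_fit(series, mode="vary_dna").kb > 0
    with pytest.raises(ValidationError):
        benesi_hildebrand_fit(series, mode="vary_everything")


def _series(responses):
    n = len(responses)
    return TitrationSeries(
        ligand_conc=np.linspace(0, 1e-4, n),
        response=np.asarray(responses, dtype=float),
        macromolecule_conc=150e-6,
        wavelength_nm=260.0,
        kind="uv_absorbance",
    )


@pytest.mark.parametrize(
    "responses, expected",
    [
        ([1.00, 1.05, 1.11, 1.18, 1.22], SpectralChange.HYPERCHROMIC),
        ([1.0, 1.0, 1.0, 1.0, 1.0], SpectralChange.NONE),
        ([1.22, 1.18, 1.11, 1.05, 1.00], SpectralChange.HYPOCHROMIC),
    ],
)
def test_spectral_trend_classification(responses, expected):
    change, shift = classify_spectral_change(_series(responses))
    assert change is expected
    assert shift is None  # single-wavelength data carries no peak shift
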