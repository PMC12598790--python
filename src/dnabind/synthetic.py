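"""Synthetic instrument signals with known ground truth.

No raw instrument tables accompany the study this package models, so every
analysis stage is validated by parameter recovery: each generator produces
one signal type from an explicit physical model plus controlled Gaussian
noise, with the generating parameters recorded.  Defaults are the study's
printed estimates (Kb = 3.22e4 1/M from UV, Ksv = 1.17e2 / 1.63e3 1/M for
the EtBr and Hoechst probes, Tm = 72.2 C free / 77.6 C complexed, DPV peaks
at +1.09 and +1.36 V, calibration slope -5e-9 A/uM), so generated fixtures
resemble the published figures.

Reproducibility: every generator draws from ``numpy.random.default_rng(seed)``
with the seed taken from the GroundTruth (or an explicit argument) and echoes
it into the output metadata; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .types import (
    FlowTimeSeries,
    MeltingCurve,
    Rheogram,
    SeriesKind,
    TitrationSeries,
    Voltammogram,
)

__all__ = [
    "GroundTruth",
    "PAPER_TRUTH",
    "INTERCALATOR_TRUTH",
    "gen_uv_titration",
    "gen_quench_series",
    "gen_melting_curve",
    "gen_voltammogram",
    "gen_rheogram",
    "gen_flow_times",
    "gen_calibration",
    "gen_electro_peak_series",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for every synthetic signal type.

    Binding constants are per molar; extinction coefficients per (M cm);
    temperatures in deg C; potentials in V; currents in A; the
    Herschel-Bulkley triple is (yield stress Pa, consistency Pa s^n, flow
    index); calibration is (slope A/uM, intercept A, residual SD A).
    noise_* fields are relative Gaussian noise SDs (0 = exact model).
    """

    # 1:1 complexation seen by UV absorption
    kb_true: float = 3.22e4
    eps_f: float = 6600.0  # free dsDNA per-nucleotide at 260 nm
    eps_b: float = 8600.0  # fully complexed (hyperchromic ceiling)
    path_cm: float = 1.0
    # fluorescence quenching (probe displacement)
    ksv_etbr: float = 1.17e2
    ksv_hoechst: float = 1.63e3
    kb_double_log: float = 2.57e4
    n_true: float = 1.17
    i0: float = 1000.0  # zero-quencher intensity, a.u.
    # binding constant vs temperature (K, 1/M) for the van't Hoff stage
    kb_by_temperature: tuple[tuple[float, float], ...] = (
        (288.15, 3.71e4),
        (298.15, 3.22e4),
        (308.15, 3.12e4),
    )
    # melting
    tm_true: float = 72.2
    tm_complex: float = 77.6
    transition_width: float = 2.5  # logistic width, deg C
    melt_lower: float = 1.00
    melt_upper: float = 1.35
    # voltammetry: dGuo and dAdo oxidation signals
    peak_centers: tuple[float, ...] = (1.09, 1.36)
    peak_heights: tuple[float, ...] = (1.2e-6, 0.8e-6)
    peak_widths: tuple[float, ...] = (0.03, 0.03)  # Gaussian sigma, V
    electro_kb: tuple[float, ...] = (6.02e4, 5.75e3)  # per peak
    baseline_coeffs: tuple[float, ...] = (1.0e-7, 2.0e-7)  # polynomial in E
    # rheology / viscometry
    hb_params: tuple[float, float, float] = (0.32, 5.95e-5, 1.57)
    eta0_specific: float = 0.5  # (t_dna - t0)/t0 of free dsDNA
    flow_t0: float = 100.0  # buffer flow time, s
    visc_slope: float = 0.0  # d[(eta/eta0)^(1/3)]/dr; 0 = groove binder
    # calibration (residual SD consistent with the printed LOD/LOQ)
    calib_slope: float = -5e-9
    calib_intercept: float = 3e-7
    calib_residual_sd: float = 1.155e-9
    # relative noise per signal type
    noise_uv: float = 0.002
    noise_fluor: float = 0.005
    noise_melt: float = 0.003
    noise_dpv: float = 0.01
    noise_flow: float = 0.002
    noise_rheo: float = 0.01
    seed: int = 0

    def with_(self, **kwargs) -> "GroundTruth":
        return replace(self, **kwargs)

    def noiseless(self) -> "GroundTruth":
        return replace(
            self,
            noise_uv=0.0, noise_fluor=0.0, noise_melt=0.0,
            noise_dpv=0.0, noise_flow=0.0, noise_rheo=0.0,
            calib_residual_sd=0.0,
        )


#: Study conditions: all defaults are the printed estimates.
PAPER_TRUTH = GroundTruth()

#: A classical intercalator: Kb ~ 1e7, large Tm shift, rising viscosity,
#: EtBr (not Hoechst) displaced.  Used as the contrast fixture.
INTERCALATOR_TRUTH = GroundTruth(
    kb_true=1.0e7,
    kb_double_log=1.0e7,
    kb_by_temperature=((288.15, 1.15e7), (298.15, 1.0e7), (308.15, 0.88e7)),
    eps_b=5300.0,  # hypochromism with helix insertion
    ksv_etbr=2.0e4,
    ksv_hoechst=1.5e2,
    tm_complex=83.4,
    electro_kb=(1.0e7, 1.0e6),
    visc_slope=0.073,  # ~20% rise in (eta/eta0)^(1/3) over r = 0.25..3.0
)


def _rng(truth: GroundTruth, seed: int | None) -> tuple[np.random.Generator, int]:
    s = truth.seed if seed is None else seed
    return np.random.default_rng(s), s


def _check_concs(ligand_concs) -> np.ndarray:
    concs = np.asarray(ligand_concs, dtype=float)
    if np.any(concs < 0):
        raise ParameterError("ligand concentrations must be non-negative")
    if concs.size >= 2 and not np.all(np.diff(concs) > 0):
        raise ParameterError("ligand concentrations must be strictly increasing")
    return concs


def bound_fraction_exact(kb: float, dna_conc: float, ligand_conc) -> np.ndarray:
    """Complexed fraction of DNA from exact 1:1 mass action.

    Solves Kb = C / ((D-C)(L-C)) for the complex concentration C (the smaller
    quadratic root, which is the physical one) and returns C/D.
    """
    lig = np.asarray(ligand_conc, dtype=float)
    b = kb * (dna_conc + lig) + 1.0
    disc = b * b - 4.0 * kb * kb * dna_conc * lig
    c = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * kb)
    return c / dna_conc


def bound_fraction_ideal(kb: float, ligand_conc) -> np.ndarray:
    """Complexed fraction under the free-ligand ~ total-ligand approximation."""
    lig = np.asarray(ligand_conc, dtype=float)
    return kb * lig / (1.0 + kb * lig)


def gen_uv_titration(
    truth: GroundTruth,
    dna_conc: float = 150e-6,
    ligand_concs=None,
    *,
    free_ligand: str = "total",
    seed: int | None = None,
) -> TitrationSeries:
    """UV absorbance of fixed dsDNA titrated with ligand.

    The apparent extinction coefficient interpolates between the free and
    bound limits with the complexed fraction f:
    eps_a = eps_f + f*(eps_b - eps_f); response = eps_a * path * [DNA].

    free_ligand selects the ligand-depletion treatment: "total" uses the
    free ~ total approximation that the double-reciprocal analysis itself
    assumes (noiseless data is then recovered exactly); "exact" solves the
    1:1 mass-action quadratic, which at these concentrations depletes the
    ligand substantially and exposes the linearization bias.
    """
    if ligand_concs is None:
        ligand_concs = np.concatenate([[0.0], np.linspace(25e-6, 300e-6, 12)])
    concs = _check_concs(ligand_concs)
    if free_ligand == "exact":
        f = bound_fraction_exact(truth.kb_true, dna_conc, concs)
    elif free_ligand == "total":
        f = bound_fraction_ideal(truth.kb_true, concs)
    else:
        raise ParameterError("free_ligand must be 'total' or 'exact'")
    eps_a = truth.eps_f + f * (truth.eps_b - truth.eps_f)
    response = eps_a * truth.path_cm * dna_conc
    rng, used_seed = _rng(truth, seed)
    if truth.noise_uv > 0:
        response = response + rng.normal(0.0, truth.noise_uv * np.abs(response))
    return TitrationSeries(
        ligand_conc=concs,
        response=response,
        macromolecule_conc=dna_conc,
        wavelength_nm=260.0,
        kind=SeriesKind.UV_ABSORBANCE,
        metadata={"seed": used_seed, "free_ligand": free_ligand, "kb_true": truth.kb_true},
    )


def gen_quench_series(
    truth: GroundTruth,
    probe: str = "hoechst",
    ligand_concs=None,
    *,
    use_double_log_model: bool = False,
    seed: int | None = None,
) -> TitrationSeries:
    """Fluorescence of a probe-dsDNA complex quenched by the added ligand.

    Default model is linear Stern-Volmer quenching, I = I0/(1 + Ksv*[Q]),
    with Ksv selected by the probe (EtBr = intercalator site, Hoechst =
    minor-groove site).  With use_double_log_model=True the generalized
    isotherm I = I0/(1 + Kb*[Q]^n) is used, which makes the double-log
    analysis exact for n != 1.
    """
    if ligand_concs is None:
        ligand_concs = np.concatenate([[0.0], np.linspace(50e-6, 300e-6, 11)])
    concs = _check_concs(ligand_concs)
    if probe not in ("etbr", "hoechst"):
        raise ParameterError("probe must be 'etbr' or 'hoechst'")
    if use_double_log_model:
        occ = np.zeros_like(concs)
        positive = concs > 0
        occ[positive] = truth.kb_double_log * concs[positive] ** truth.n_true
        intensity = truth.i0 / (1.0 + occ)
    else:
        ksv = truth.ksv_etbr if probe == "etbr" else truth.ksv_hoechst
        intensity = truth.i0 / (1.0 + ksv * concs)
    rng, used_seed = _rng(truth, seed)
    if truth.noise_fluor > 0:
        intensity = intensity + rng.normal(0.0, truth.noise_fluor * np.abs(intensity))
    return TitrationSeries(
        ligand_conc=concs,
        response=intensity,
        macromolecule_conc=120e-6,
        wavelength_nm=460.0 if probe == "hoechst" else 600.0,
        kind=SeriesKind.FLUORESCENCE,
        metadata={"seed": used_seed, "probe": probe},
    )


def gen_melting_curve(
    truth: GroundTruth,
    temp_grid=None,
    *,
    tm: float | None = None,
    label: str = "dsDNA",
    seed: int | None = None,
) -> MeltingCurve:
    """Four-parameter logistic melting profile at 260 nm.

    A(T) = lower + (upper - lower) / (1 + exp(-(T - Tm)/width)).
    tm defaults to truth.tm_true; pass truth.tm_complex for the drug-bound
    sample.  upper == lower produces a transitionless (degenerate) curve.
    """
    if temp_grid is None:
        temp_grid = np.arange(20.0, 100.0 + 1e-9, 1.0)
    temps = np.asarray(temp_grid, dtype=float)
    midpoint = truth.tm_true if tm is None else tm
    amp = truth.melt_upper - truth.melt_lower
    absorbance = truth.melt_lower + amp / (1.0 + np.exp(-(temps - midpoint) / truth.transition_width))
    rng, used_seed = _rng(truth, seed)
    if truth.noise_melt > 0:
        absorbance = absorbance + rng.normal(0.0, truth.noise_melt * np.abs(absorbance))
    return MeltingCurve(
        temperature=temps,
        absorbance=absorbance,
        label=label,
        metadata={"seed": used_seed, "tm_true": midpoint},
    )


def _baseline(truth: GroundTruth, potential: np.ndarray) -> np.ndarray:
    return sum(c * potential**i for i, c in enumerate(truth.baseline_coeffs))


def gen_voltammogram(
    truth: GroundTruth,
    potential_grid=None,
    *,
    drug_conc: float = 0.0,
    seed: int | None = None,
) -> Voltammogram:
    """Differential-pulse voltammogram: Gaussian oxidation peaks on a drift.

    Peaks default to the dGuo (+1.09 V) and dAdo (+1.36 V) signals.  A
    nonzero drug_conc suppresses each peak by S(L) = 1/(1 + Kb*L) with the
    per-peak electrochemical binding constant, so a concentration series of
    noiseless peak currents lies exactly on the log-log binding line.
    """
    if potential_grid is None:
        potential_grid = np.arange(0.8, 1.6 + 1e-9, 0.005)
    pot = np.asarray(potential_grid, dtype=float)
    current = _baseline(truth, pot)
    for center, height, width, kb in zip(
        truth.peak_centers, truth.peak_heights, truth.peak_widths, truth.electro_kb
    ):
        suppression = 1.0 / (1.0 + kb * drug_conc)
        current = current + height * suppression * np.exp(-((pot - center) ** 2) / (2.0 * width**2))
    rng, used_seed = _rng(truth, seed)
    if truth.noise_dpv > 0:
        scale = truth.noise_dpv * max(truth.peak_heights, default=1e-9)
        current = current + rng.normal(0.0, scale, size=pot.size)
    meta = {
        "seed": used_seed,
        "drug_conc_M": drug_conc,
        "scan_rate_V_s": 0.01,
        "step_potential_V": 0.008,
        "modulation_amplitude_V": 0.05,
        "modulation_time_s": 0.05,
        "interval_time_s": 0.5,
    }
    return Voltammogram(potential=pot, current=current, metadata=meta)


def gen_electro_peak_series(
    truth: GroundTruth,
    drug_concs=None,
    *,
    peak_index: int = 0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Noisy (drug_conc, peak_current) pairs plus the drug-free current.

    Convenience wrapper over the per-peak suppression model; the returned
    free current is the noiseless peak height.
    """
    if drug_concs is None:
        drug_concs = np.linspace(5e-6, 40e-6, 8)
    concs = _check_concs(drug_concs)
    height = truth.peak_heights[peak_index]
    kb = truth.electro_kb[peak_index]
    currents = height / (1.0 + kb * concs)
    rng, used_seed = _rng(truth, seed)
    if truth.noise_dpv > 0:
        currents = currents + rng.normal(0.0, truth.noise_dpv * np.abs(currents))
    return concs, currents, height


def gen_rheogram(
    truth: GroundTruth,
    shear_rates=None,
    *,
    label: str = "buffer",
    seed: int | None = None,
) -> Rheogram:
    """Herschel-Bulkley flow curve: tau = tau0 + K * gamma_dot**n + noise."""
    if shear_rates is None:
        shear_rates = np.linspace(10.0, 1000.0, 25)
    rates = np.asarray(shear_rates, dtype=float)
    if np.any(rates <= 0):
        raise ParameterError("shear rates must be positive")
    tau0, k, n = truth.hb_params
    stress = tau0 + k * rates**n
    rng, used_seed = _rng(truth, seed)
    if truth.noise_rheo > 0:
        stress = stress + rng.normal(0.0, truth.noise_rheo * np.abs(stress))
    return Rheogram(
        shear_rate=rates,
        shear_stress=stress,
        label=label,
        metadata={"seed": used_seed, "hb_true": list(truth.hb_params)},
    )


def gen_flow_times(
    truth: GroundTruth,
    ligand_concs=None,
    dna_conc: float = 120e-6,
    *,
    seed: int | None = None,
) -> FlowTimeSeries:
    """Viscometer flow times for a dsDNA solution under ligand additions.

    The generating profile is linear in the conventional cube-root plot:
    (eta/eta0)^(1/3) = 1 + visc_slope * r with r = [ligand]/[DNA], so a
    groove binder (visc_slope = 0) gives flat relative viscosity and an
    intercalator a rising one.  Flow times follow from the specific
    viscosity: t = t0 * (1 + eta), eta = eta0_specific * (value)^3.
    """
    if ligand_concs is None:
        # r = 0 (free DNA) then r = 0.25 .. 3.0 as in the dye-comparison study
        ligand_concs = np.concatenate([[0.0], np.linspace(0.25, 3.0, 12) * dna_conc])
    concs = _check_concs(ligand_concs)
    r = concs / dna_conc
    value = 1.0 + truth.visc_slope * r
    eta = truth.eta0_specific * value**3
    t = truth.flow_t0 * (1.0 + eta)
    rng, used_seed = _rng(truth, seed)
    if truth.noise_flow > 0:
        t = t + rng.normal(0.0, truth.noise_flow * t)
    return FlowTimeSeries(
        t0=truth.flow_t0,
        t=t,
        ligand_conc=concs,
        dna_conc=dna_conc,
        metadata={"seed": used_seed, "visc_slope_true": truth.visc_slope},
    )


def gen_calibration(
    truth: GroundTruth,
    concs=None,
    replicates: int = 1,
    *,
    seed: int | None = None,
):
    """Concentration-current calibration table (conc uM, current A).

    Currents follow I = slope*C + intercept with Gaussian residuals of the
    ground-truth residual SD (absolute, in A).  Returns a pandas DataFrame in
    the "calibration" schema.
    """
    import pandas as pd

    if concs is None:
        concs = np.linspace(2.5, 20.0, 8)
    concs = np.asarray(concs, dtype=float)
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    all_conc = np.repeat(concs, replicates)
    currents = truth.calib_slope * all_conc + truth.calib_intercept
    rng, used_seed = _rng(truth, seed)
    if truth.calib_residual_sd > 0:
        currents = currents + rng.normal(0.0, truth.calib_residual_sd, size=all_conc.size)
    df = pd.DataFrame({"conc_uM": all_conc, "current_A": currents})
    df.attrs["metadata"] = {"seed": used_seed, "slope_true": truth.calib_slope}
    return df
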