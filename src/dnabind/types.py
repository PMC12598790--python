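"""Domain containers for titration, melting, rheology and voltammetry data.

All quantities are stored in SI-flavoured internal units: concentrations in
mol/L, temperatures in the unit the instrument reports (deg C for melting
curves, kelvin where a type says so), currents in amperes, potentials in
volts.  Micromolar appears only in the quantification reporting layer, where
calibration lines are conventionally printed per uM.

Each container validates its invariants on construction and raises
:class:`~dnabind.errors.ValidationError` with a message naming the offending
field, so that file loading can surface typed errors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError

__all__ = [
    "SeriesKind",
    "FitMethod",
    "ForceClass",
    "SpectralChange",
    "ModeCall",
    "TitrationSeries",
    "MeltingCurve",
    "Voltammogram",
    "FlowTimeSeries",
    "Rheogram",
    "BindingFit",
    "ThermoResult",
    "CalibrationResult",
    "ValidationStats",
    "BindingModeReport",
]


class SeriesKind(str, enum.Enum):
    UV_ABSORBANCE = "uv_absorbance"
    FLUORESCENCE = "fluorescence"


class FitMethod(str, enum.Enum):
    BENESI_HILDEBRAND = "benesi_hildebrand"
    STERN_VOLMER = "stern_volmer"
    DOUBLE_LOG = "double_log"
    ELECTROCHEMICAL = "electrochemical"
    VANT_HOFF_POINT = "vant_hoff_point"


class ForceClass(str, enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    VDW_OR_HBOND = "vdw_or_hbond"
    ELECTROSTATIC = "electrostatic"
    INDETERMINATE = "indeterminate"


class SpectralChange(str, enum.Enum):
    HYPERCHROMIC = "hyperchromic"
    HYPOCHROMIC = "hypochromic"
    NONE = "none"


class ModeCall(str, enum.Enum):
    MINOR_GROOVE = "minor_groove"
    INTERCALATION = "intercalation"
    ELECTROSTATIC = "electrostatic"
    INDETERMINATE = "indeterminate"


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _require_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size >= 2 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} not increasing")


@dataclass
class TitrationSeries:
    """Optical response of a fixed dsDNA solution titrated with a ligand.

    ligand_conc : mol/L per point, strictly increasing from 0 or above.
    response    : absorbance (AU) or fluorescence intensity (a.u.) per point.
    macromolecule_conc : fixed per-nucleotide dsDNA concentration, mol/L.
    wavelength_nm : observation wavelength.
    kind        : uv_absorbance or fluorescence.
    """

    ligand_conc: np.ndarray
    response: np.ndarray
    macromolecule_conc: float
    wavelength_nm: float
    kind: SeriesKind
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.ligand_conc = _as_array(self.ligand_conc, "ligand_conc")
        self.response = _as_array(self.response, "response")
        self.kind = SeriesKind(self.kind)
        if self.ligand_conc.size != self.response.size:
            raise ValidationError("ligand_conc and response differ in length")
        if self.ligand_conc.size < 3:
            raise ValidationError("titration needs at least 3 points")
        if np.any(self.ligand_conc < 0):
            raise ValidationError("ligand_conc must be non-negative")
        _require_strictly_increasing(self.ligand_conc, "ligand_conc")
        if not (self.macromolecule_conc > 0):
            raise ValidationError("macromolecule_conc must be positive")

    def __len__(self) -> int:
        return int(self.ligand_conc.size)


@dataclass
class MeltingCurve:
    """Absorbance at 260 nm versus temperature (deg C) for one sample."""

    temperature: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = _as_array(self.temperature, "temperature")
        self.absorbance = _as_array(self.absorbance, "absorbance")
        if self.temperature.size != self.absorbance.size:
            raise ValidationError("temperature and absorbance differ in length")
        if self.temperature.size < 5:
            raise ValidationError("melting curve needs at least 5 points")
        _require_strictly_increasing(self.temperature, "temperature")


@dataclass
class Voltammogram:
    """Current versus applied potential for one differential-pulse sweep."""

    potential: np.ndarray
    current: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.potential = _as_array(self.potential, "potential")
        self.current = _as_array(self.current, "current")
        if self.potential.size != self.current.size:
            raise ValidationError("potential and current differ in length")
        if self.potential.size < 20:
            raise ValidationError("voltammogram needs at least 20 points")
        d = np.diff(self.potential)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("potential not monotonic")


@dataclass
class FlowTimeSeries:
    """Capillary flow times of a dsDNA solution under ligand additions.

    t0 is the buffer flow time; the zero-ligand point defines the viscosity of
    free dsDNA.  Points with t < t0 are physically suspect and flagged by the
    analysis rather than rejected on load.
    """

    t0: float
    t: np.ndarray
    ligand_conc: np.ndarray
    dna_conc: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_array(self.t, "t")
        self.ligand_conc = _as_array(self.ligand_conc, "ligand_conc")
        if not (self.t0 > 0):
            raise ValidationError("t0 must be positive")
        if self.t.size != self.ligand_conc.size:
            raise ValidationError("t and ligand_conc differ in length")
        if np.any(self.ligand_conc < 0):
            raise ValidationError("ligand_conc must be non-negative")
        _require_strictly_increasing(self.ligand_conc, "ligand_conc")
        if not (self.dna_conc > 0):
            raise ValidationError("dna_conc must be positive")


@dataclass
class Rheogram:
    """Shear stress (Pa) versus shear rate (1/s) flow curve."""

    shear_rate: np.ndarray
    shear_stress: np.ndarray
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.shear_rate = _as_array(self.shear_rate, "shear_rate")
        self.shear_stress = _as_array(self.shear_stress, "shear_stress")
        if self.shear_rate.size != self.shear_stress.size:
            raise ValidationError("shear_rate and shear_stress differ in length")
        if np.any(self.shear_rate <= 0):
            raise ValidationError("shear_rate must be positive")
        _require_strictly_increasing(self.shear_rate, "shear_rate")


@dataclass
class BindingFit:
    """An estimated binding constant with its regression diagnostics.

    kb is in 1/M.  n_stoichiometry is None for methods that do not estimate
    it.  `reliable` is False when the underlying intercept is statistically
    indistinguishable from zero (Benesi-Hildebrand) or an expected-unity slope
    is badly violated; `warnings` carries the human-readable reasons.
    """

    kb: float
    kb_stderr: float
    method: FitMethod
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_stoichiometry: float | None = None
    reliable: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.method = FitMethod(self.method)
        if not (self.kb > 0):
            raise ValidationError("kb must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "kb": self.kb,
            "kb_stderr": self.kb_stderr,
            "method": self.method.value,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "n_stoichiometry": self.n_stoichiometry,
            "reliable": self.reliable,
            "warnings": list(self.warnings),
        }


@dataclass
class ThermoResult:
    """van't Hoff enthalpy/entropy with Gibbs energies per temperature.

    delta_h in kJ/mol, delta_s in J/(mol K); delta_g_per_temperature maps
    T (kelvin) -> delta_g (kJ/mol) and satisfies dG = dH - T*dS/1000 exactly.
    """

    delta_h: float
    delta_s: float
    delta_g_per_temperature: dict[float, float]
    force_class: ForceClass
    delta_h_stderr: float = float("nan")
    delta_s_stderr: float = float("nan")
    curvature_warning: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.force_class = ForceClass(self.force_class)
        for t, dg in self.delta_g_per_temperature.items():
            expected = self.delta_h - t * self.delta_s / 1000.0
            if not math.isclose(dg, expected, rel_tol=1e-12, abs_tol=1e-12):
                raise ValidationError(
                    f"delta_g at {t} K inconsistent with delta_h - T*delta_s"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "delta_h_kj_mol": self.delta_h,
            "delta_s_j_mol_k": self.delta_s,
            "delta_h_stderr": self.delta_h_stderr,
            "delta_s_stderr": self.delta_s_stderr,
            "delta_g_kj_mol": {str(t): g for t, g in self.delta_g_per_temperature.items()},
            "force_class": self.force_class.value,
            "curvature_warning": self.curvature_warning,
            "notes": list(self.notes),
        }


@dataclass
class CalibrationResult:
    """Calibration line I = slope*C + intercept with figures of merit.

    slope in A/uM, intercept and residual_sd in A, lod/loq in uM.  The
    loq/lod ratio is exactly 10/3 because both derive from the same residual
    SD and slope.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    lod: float
    loq: float
    linear_range: tuple[float, float]
    n_points: int = 0
    outlier_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.lod > 0 and not math.isclose(self.loq / self.lod, 10.0 / 3.0, rel_tol=1e-12):
            raise ValidationError("loq/lod must equal 10/3 exactly")
        if self.residual_sd > 0 and not self.lod > 0:
            raise ValidationError("lod must be positive when residual_sd > 0")

    def concentration(self, current: float) -> float:
        """Invert the line: C = (I - intercept)/slope (uM). Not clipped."""
        return (current - self.intercept) / self.slope

    def to_dict(self) -> dict[str, Any]:
        return {
            "slope_A_per_uM": self.slope,
            "intercept_A": self.intercept,
            "r_squared": self.r_squared,
            "residual_sd_A": self.residual_sd,
            "lod_uM": self.lod,
            "loq_uM": self.loq,
            "linear_range_uM": list(self.linear_range),
            "n_points": self.n_points,
            "outlier_indices": list(self.outlier_indices),
        }


@dataclass
class ValidationStats:
    """Replicate statistics: mean, sample SD (n-1), %RSD, optional %bias."""

    mean: float
    sd: float
    rsd_percent: float
    per_sample: list[float]
    bias_percent: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if self.mean != 0:
            expected = 100.0 * self.sd / abs(self.mean)
            if not math.isclose(self.rsd_percent, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError("rsd_percent inconsistent with sd/mean")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "mean": self.mean,
            "sd": self.sd,
            "rsd_percent": self.rsd_percent,
            "per_sample": list(self.per_sample),
        }
        if self.bias_percent is not None:
            d["bias_percent"] = self.bias_percent
        return d


@dataclass
class BindingModeReport:
    """Aggregated multi-technique evidence and the rule-based mode call.

    evidence maps evidence keys (e.g. "kb_by_method", "delta_tm_c") to the
    per-technique findings; rule_trace lists every fired rule with the
    evidence it consumed and the vote it cast, in firing order.  The call is
    reproducible from the serialized evidence alone.
    """

    evidence: dict[str, Any]
    mode_call: ModeCall
    rule_trace: list[dict[str, Any]]
    schema_version: int = 1

    def __post_init__(self):
        self.mode_call = ModeCall(self.mode_call)
        for fired in self.rule_trace:
            key = fired.get("evidence_key")
            if key is not None and key not in self.evidence:
                raise ValidationError(f"rule {fired.get('rule')} references missing evidence {key!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "evidence": self.evidence,
            "mode_call": self.mode_call.value,
            "rule_trace": self.rule_trace,
        }
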