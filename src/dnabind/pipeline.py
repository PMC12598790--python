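"""End-to-end orchestration: per-technique stages feeding the mode call.

A configuration names input files (or passes in-memory domain objects) for
any subset of the six techniques; :func:`run_report` runs each configured
stage, writes a JSON result per stage, assembles the evidence mapping and
hands it to the rule engine.  A failing stage does not abort the run - its
evidence is simply absent and the failure is recorded in the report.

Config layout (dict, or a TOML file via the CLI)::

    uv             = {path = "uv_titration.csv"}
    fluorescence   = {etbr = "quench_etbr.csv", hoechst = "quench_hoechst.csv"}
    thermodynamics = {path = "kb_vs_t.csv"}
    melting        = {sample = "melt_complex.csv", reference = "melt_free.csv"}
    viscosity      = {path = "flowtimes.csv"}
    voltammetry    = {peaks = "electro_peaks.csv"}     # s_free from metadata

All stage outputs are pure functions of the inputs, so two runs on the same
files produce identical JSON.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import io as dio
from .errors import DnabindError, UsageError
from .fluorescence import displacement_compare, double_log_fit, stern_volmer_fit
from .melting import delta_tm, fit_melting_curve
from .modes import RuleThresholds, aggregate_evidence
from .synthetic import (
    GroundTruth,
    gen_calibration,
    gen_electro_peak_series,
    gen_flow_times,
    gen_melting_curve,
    gen_quench_series,
    gen_rheogram,
    gen_uv_titration,
    gen_voltammogram,
)
from .thermodynamics import vant_hoff_fit
from .types import BindingModeReport, FlowTimeSeries, MeltingCurve, TitrationSeries
from .uv import benesi_hildebrand_fit, classify_spectral_change
from .viscosity import relative_viscosity_series, viscosity_trend_test
from .voltammetry import electro_binding_fit

__all__ = ["run_report", "write_fixture_set"]

log = logging.getLogger(__name__)

STAGES = ("uv", "fluorescence", "thermodynamics", "melting", "viscosity", "voltammetry")


def _load(value, schema: str):
    """Accept a path (load it) or an already-constructed object."""
    if isinstance(value, (str, Path)):
        return dio.read_table(value, schema)
    return value


def run_report(
    config: Mapping[str, Any],
    out_dir: str | Path | None = None,
    *,
    thresholds: RuleThresholds | None = None,
) -> BindingModeReport:
    """Run every configured stage and aggregate the evidence.

    Parameters
    ----------
    config : stage name -> stage inputs (paths or domain objects), see module
        docstring.  At least one known stage must be configured.
    out_dir : optional directory for per-stage JSON files plus report.json.

    Returns
    -------
    BindingModeReport; failed stages appear under evidence key
    "stage_errors" (descriptive only, no vote).
    """
    known = {k: v for k, v in config.items() if k in STAGES}
    if not known:
        raise UsageError(f"no technique configured; expected any of {STAGES}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    evidence: dict[str, Any] = {}
    stage_errors: dict[str, str] = {}
    stage_results: dict[str, Any] = {}
    kb_by_method: dict[str, float] = {}

    def record(stage: str, payload: Any) -> None:
        stage_results[stage] = payload
        if out is not None:
            dio.write_json(payload, out / f"{stage}.json")

    if "uv" in known:
        try:
            series: TitrationSeries = _load(known["uv"]["path"], "titration")
            change, shift = classify_spectral_change(series)
            evidence["spectral_change"] = change.value
            if shift is not None:
                evidence["peak_shift_nm"] = shift
            payload: dict[str, Any] = {"spectral_change": change.value}
            try:
                fit = benesi_hildebrand_fit(series, known["uv"].get("mode", "vary_ligand"))
                payload["fit"] = fit.to_dict()
                if fit.reliable:
                    kb_by_method[fit.method.value] = fit.kb
            except DnabindError as exc:
                # a saturated or degenerate titration still classifies spectrally
                payload["fit_error"] = str(exc)
                stage_errors["uv_fit"] = str(exc)
                log.error("uv binding fit failed: %s", exc)
            record("uv", payload)
        except DnabindError as exc:
            stage_errors["uv"] = str(exc)
            log.error("uv stage failed: %s", exc)

    if "fluorescence" in known:
        try:
            cfg = known["fluorescence"]
            etbr = _load(cfg["etbr"], "titration")
            hoechst = _load(cfg["hoechst"], "titration")
            fit_e = stern_volmer_fit(etbr)
            fit_h = stern_volmer_fit(hoechst)
            call = displacement_compare(fit_e, fit_h)
            # double-log binding analysis on the more strongly quenched probe
            quenched = hoechst if fit_h.kb >= fit_e.kb else etbr
            fit_dl = double_log_fit(quenched)
            kb_by_method[fit_dl.method.value] = fit_dl.kb
            evidence["displacement"] = call.value
            record(
                "fluorescence",
                {
                    "stern_volmer_etbr": fit_e.to_dict(),
                    "stern_volmer_hoechst": fit_h.to_dict(),
                    "double_log": fit_dl.to_dict(),
                    "displacement": call.value,
                },
            )
        except DnabindError as exc:
            stage_errors["fluorescence"] = str(exc)
            log.error("fluorescence stage failed: %s", exc)

    if "thermodynamics" in known:
        try:
            table = _load(known["thermodynamics"]["path"], "kb_vs_t")
            if isinstance(table, pd.DataFrame):
                points = list(zip(table["temperature_K"], table["kb_1_per_M"]))
            else:
                points = list(table)
            thermo = vant_hoff_fit(points)
            evidence["force_class"] = thermo.force_class.value
            record("thermodynamics", thermo.to_dict())
        except DnabindError as exc:
            stage_errors["thermodynamics"] = str(exc)
            log.error("thermodynamics stage failed: %s", exc)

    if "melting" in known:
        try:
            cfg = known["melting"]
            sample: MeltingCurve = _load(cfg["sample"], "melting")
            reference: MeltingCurve = _load(cfg["reference"], "melting")
            fit_s = fit_melting_curve(sample)
            fit_r = fit_melting_curve(reference)
            dtm = delta_tm(fit_s.tm, fit_r.tm)
            evidence["delta_tm_c"] = dtm
            record(
                "melting",
                {"sample": fit_s.to_dict(), "reference": fit_r.to_dict(), "delta_tm_c": dtm},
            )
        except DnabindError as exc:
            stage_errors["melting"] = str(exc)
            log.error("melting stage failed: %s", exc)

    if "viscosity" in known:
        try:
            flow: FlowTimeSeries = _load(known["viscosity"]["path"], "flowtimes")
            points = relative_viscosity_series(flow)
            trend = viscosity_trend_test(points)
            evidence["viscosity_trend"] = trend.classification
            record(
                "viscosity",
                {
                    "series": [{"r": p.r, "value": p.value, "flagged": p.flagged} for p in points],
                    "trend": trend.to_dict(),
                },
            )
        except DnabindError as exc:
            stage_errors["viscosity"] = str(exc)
            log.error("viscosity stage failed: %s", exc)

    if "voltammetry" in known:
        try:
            cfg = known["voltammetry"]
            table = _load(cfg["peaks"], "peak_series")
            if isinstance(table, pd.DataFrame):
                pairs = list(zip(table["ligand_conc_M"], table["peak_current_A"]))
                s_free = float(cfg.get("s_free", table.attrs.get("metadata", {}).get("s_free_A", np.nan)))
            else:
                pairs, s_free = table, float(cfg["s_free"])
            fit = electro_binding_fit(pairs, s_free)
            kb_by_method[fit.method.value] = fit.kb
            record("voltammetry", fit.to_dict())
        except DnabindError as exc:
            stage_errors["voltammetry"] = str(exc)
            log.error("voltammetry stage failed: %s", exc)

    if kb_by_method:
        evidence["kb_by_method"] = kb_by_method
    if stage_errors:
        evidence["stage_errors"] = stage_errors

    report = aggregate_evidence(evidence, thresholds)
    if out is not None:
        dio.write_json(report, out / "report.json")
    return report


def write_fixture_set(
    truth: GroundTruth, out_dir: str | Path, *, seed: int | None = None
) -> dict[str, Any]:
    """Emit the full canonical CSV fixture set plus a ground-truth sidecar.

    Returns a run_report-ready config mapping stage names to the written
    files.  Per-signal seeds are derived deterministically from the base
    seed, so identical seeds give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = (truth.seed if seed is None else seed) % (2**31 - 100)

    uv = gen_uv_titration(truth, seed=base + 1)
    etbr = gen_quench_series(truth, "etbr", seed=base + 2)
    hoechst = gen_quench_series(truth, "hoechst", seed=base + 3)
    melt_free = gen_melting_curve(truth, tm=truth.tm_true, label="dsDNA", seed=base + 4)
    melt_complex = gen_melting_curve(
        truth, tm=truth.tm_complex, label="dsDNA+drug", seed=base + 5
    )
    flow = gen_flow_times(truth, seed=base + 6)
    rheo = gen_rheogram(truth, seed=base + 7)
    dpv = gen_voltammogram(truth, seed=base + 8)
    concs, currents, s_free = gen_electro_peak_series(truth, seed=base + 9)
    calib = gen_calibration(truth, seed=base + 10)

    dio.write_table(uv, out / "uv_titration.csv")
    dio.write_table(etbr, out / "quench_etbr.csv")
    dio.write_table(hoechst, out / "quench_hoechst.csv")
    dio.write_table(melt_free, out / "melt_free.csv")
    dio.write_table(melt_complex, out / "melt_complex.csv")
    dio.write_table(flow, out / "flowtimes.csv")
    dio.write_table(rheo, out / "rheogram.csv")
    dio.write_table(dpv, out / "dpv.csv")

    peaks = pd.DataFrame({"ligand_conc_M": concs, "peak_current_A": currents})
    peaks.attrs["metadata"] = {"s_free_A": s_free, "seed": base + 9}
    dio.write_table(peaks, out / "electro_peaks.csv", schema="peak_series")
    dio.write_table(calib, out / "calibration.csv", schema="calibration")

    kbt = pd.DataFrame(
        {
            "temperature_K": [t for t, _ in truth.kb_by_temperature],
            "kb_1_per_M": [k for _, k in truth.kb_by_temperature],
        }
    )
    dio.write_table(kbt, out / "kb_vs_t.csv", schema="kb_vs_t")

    from dataclasses import asdict

    dio.write_json({"seed": base, **asdict(truth)}, out / "truth.json")

    return {
        "uv": {"path": str(out / "uv_titration.csv")},
        "fluorescence": {
            "etbr": str(out / "quench_etbr.csv"),
            "hoechst": str(out / "quench_hoechst.csv"),
        },
        "thermodynamics": {"path": str(out / "kb_vs_t.csv")},
        "melting": {
            "sample": str(out / "melt_complex.csv"),
            "reference": str(out / "melt_free.csv"),
        },
        "viscosity": {"path": str(out / "flowtimes.csv")},
        "voltammetry": {"peaks": str(out / "electro_peaks.csv")},
    }
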