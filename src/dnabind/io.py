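"""CSV readers/writers for instrument-export tables.

Canonical dialect: comma-separated, '.' decimal, one table per file.
Metadata travels in '#'-prefixed header lines of the form ``# key = value``
before the column header.  Numbers are written with 12 significant digits, so
write -> read -> write is byte-identical for values representable at that
precision.

Each schema names its required columns; matching is case-insensitive.  Load
failures raise :class:`~dnabind.errors.LoadError` naming the offending row
and column.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import LoadError, ValidationError
from .types import (
    FlowTimeSeries,
    MeltingCurve,
    Rheogram,
    SeriesKind,
    TitrationSeries,
    Voltammogram,
)

__all__ = ["SCHEMAS", "read_table", "write_table", "write_json", "read_json"]

_MAGIC = "# dnabind table v1"

# schema name -> (ordered column names, required metadata keys)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "titration": (("ligand_conc_M", "response"), ("kind", "macromolecule_conc_M", "wavelength_nm")),
    "melting": (("temperature_C", "absorbance"), ()),
    "voltammogram": (("potential_V", "current_A"), ()),
    "flowtimes": (("ligand_conc_M", "flow_time_s"), ("t0_s", "dna_conc_M")),
    "rheogram": (("shear_rate_1_per_s", "shear_stress_Pa"), ()),
    "calibration": (("conc_uM", "current_A"), ()),
    "kb_vs_t": (("temperature_K", "kb_1_per_M"), ()),
    "peak_series": (("ligand_conc_M", "peak_current_A"), ()),
}


def _fmt(value: Any) -> str:
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".12g")
    return str(value)


def _parse_meta_value(raw: str) -> Any:
    try:
        f = float(raw)
    except ValueError:
        return raw
    return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f


def _split_file(path: Path) -> tuple[dict[str, Any], str]:
    meta: dict[str, Any] = {}
    body_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, raw = stripped.partition("=")
                meta[key.strip()] = _parse_meta_value(raw.strip())
        elif line.strip():
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _read_columns(path: Path, schema: str) -> tuple[dict[str, Any], dict[str, np.ndarray]]:
    if schema not in SCHEMAS:
        raise LoadError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    if not Path(path).exists():
        raise LoadError(f"no such file: {path}")
    columns, required_meta = SCHEMAS[schema]
    meta, body = _split_file(Path(path))
    if not body:
        raise LoadError(f"{path}: empty table")
    df = pd.read_csv(_stdio.StringIO(body), dtype=str, skipinitialspace=True)
    lower_map = {c.lower(): c for c in df.columns}
    out: dict[str, np.ndarray] = {}
    for col in columns:
        actual = lower_map.get(col.lower())
        if actual is None:
            raise LoadError(f"{path}: missing column", column=col)
        values = np.empty(len(df), dtype=float)
        for i, cell in enumerate(df[actual]):
            try:
                values[i] = float(cell)
            except (TypeError, ValueError):
                raise LoadError(
                    f"{path}: non-numeric cell {cell!r}", row=i + 1, column=col
                ) from None
        out[col] = values
    for key in required_meta:
        if key not in meta:
            raise LoadError(f"{path}: missing metadata key {key!r}")
    return meta, out


def read_table(path, schema: str):
    """Load and validate a table of the given schema.

    Returns the corresponding domain type for instrument signals, or a
    pandas DataFrame for plain concentration-response tables
    ("calibration", "kb_vs_t", "peak_series").
    """
    path = Path(path)
    meta, cols = _read_columns(path, schema)
    extra = {k: v for k, v in meta.items() if k not in ("schema",)}
    try:
        if schema == "titration":
            return TitrationSeries(
                ligand_conc=cols["ligand_conc_M"],
                response=cols["response"],
                macromolecule_conc=float(meta["macromolecule_conc_M"]),
                wavelength_nm=float(meta["wavelength_nm"]),
                kind=SeriesKind(meta["kind"]),
                metadata=extra,
            )
        if schema == "melting":
            return MeltingCurve(
                temperature=cols["temperature_C"],
                absorbance=cols["absorbance"],
                label=str(meta.get("label", "")),
                metadata=extra,
            )
        if schema == "voltammogram":
            return Voltammogram(
                potential=cols["potential_V"], current=cols["current_A"], metadata=extra
            )
        if schema == "flowtimes":
            return FlowTimeSeries(
                t0=float(meta["t0_s"]),
                t=cols["flow_time_s"],
                ligand_conc=cols["ligand_conc_M"],
                dna_conc=float(meta["dna_conc_M"]),
                metadata=extra,
            )
        if schema == "rheogram":
            return Rheogram(
                shear_rate=cols["shear_rate_1_per_s"],
                shear_stress=cols["shear_stress_Pa"],
                label=str(meta.get("label", "")),
                metadata=extra,
            )
    except ValidationError as exc:
        raise LoadError(f"{path}: {exc}") from exc
    # plain tables
    column_names, _ = SCHEMAS[schema]
    df = pd.DataFrame({c: cols[c] for c in column_names})
    df.attrs["metadata"] = extra
    return df


def _table_payload(obj) -> tuple[str, dict[str, Any], dict[str, np.ndarray]]:
    """Map a domain object (or (schema, DataFrame)) to schema/meta/columns."""
    if isinstance(obj, TitrationSeries):
        meta = {
            "kind": obj.kind.value,
            "macromolecule_conc_M": obj.macromolecule_conc,
            "wavelength_nm": obj.wavelength_nm,
        }
        return "titration", {**meta, **obj.metadata}, {
            "ligand_conc_M": obj.ligand_conc,
            "response": obj.response,
        }
    if isinstance(obj, MeltingCurve):
        meta = {"label": obj.label} if obj.label else {}
        return "melting", {**meta, **obj.metadata}, {
            "temperature_C": obj.temperature,
            "absorbance": obj.absorbance,
        }
    if isinstance(obj, Voltammogram):
        return "voltammogram", dict(obj.metadata), {
            "potential_V": obj.potential,
            "current_A": obj.current,
        }
    if isinstance(obj, FlowTimeSeries):
        meta = {"t0_s": obj.t0, "dna_conc_M": obj.dna_conc}
        return "flowtimes", {**meta, **obj.metadata}, {
            "ligand_conc_M": obj.ligand_conc,
            "flow_time_s": obj.t,
        }
    if isinstance(obj, Rheogram):
        meta = {"label": obj.label} if obj.label else {}
        return "rheogram", {**meta, **obj.metadata}, {
            "shear_rate_1_per_s": obj.shear_rate,
            "shear_stress_Pa": obj.shear_stress,
        }
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_table(obj, path, schema: str | None = None) -> Path:
    """Write a domain object or DataFrame as a canonical-dialect CSV."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        if schema is None or schema not in SCHEMAS:
            raise TypeError("writing a DataFrame requires a known schema name")
        meta = dict(obj.attrs.get("metadata", {}))
        columns = {c: np.asarray(obj[c], dtype=float) for c in SCHEMAS[schema][0]}
    else:
        schema, meta, columns = _table_payload(obj)
    lines = [_MAGIC, f"# schema = {schema}"]
    for key in sorted(meta):
        lines.append(f"# {key} = {_fmt(meta[key])}")
    names = list(columns)
    lines.append(",".join(names))
    n = len(next(iter(columns.values())))
    for i in range(n):
        lines.append(",".join(_fmt(columns[name][i]) for name in names))
    path.write_text("\n".join(lines) + "\n")
    return path


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_JsonEncoder) + "\n")
    return path


def read_json(path) -> Any:
    return json.loads(Path(path).read_text())
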