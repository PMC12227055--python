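"""Readers and writers for the package's plain-text formats.

CSV dialect: comma separator, '.' decimal, '#'-prefixed ``key: value``
metadata lines before the header. Time-resolved matrices declare their
time and signal units in the metadata block; readers reject files
without a unit declaration and validate axis monotonicity. Result
objects serialize to JSON with stable key order, floats at 12
significant digits, and package-version / scenario / seed provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import CurrentTrace, TAMatrix, TitrationSpectra, TIME_UNITS

__all__ = ["read_matrix", "write_matrix", "write_results", "read_results"]


def _write_meta(fh, meta: dict) -> None:
    for key in sorted(meta):
        value = meta[key]
        if value is None:
            continue
        if isinstance(value, (list, tuple, np.ndarray)):
            value = ";".join(f"{v:.12g}" for v in np.asarray(value).ravel())
        fh.write(f"# {key}: {value}\n")


def _read_meta(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, skip


def _guard(path, force: bool) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    return path


def write_matrix(obj, path, force: bool = False) -> None:
    """Write a TAMatrix, TitrationSpectra or CurrentTrace as dialect CSV."""
    path = _guard(path, force)
    if isinstance(obj, TAMatrix):
        meta = {**obj.metadata, "dialect": "ta", "time_unit": obj.time_unit,
                "signal_unit": obj.signal_unit}
        header = ["wavelength_nm"] + [f"{t:.12g}" for t in obj.times]
        body = np.column_stack([obj.wavelengths, obj.values])
    elif isinstance(obj, TitrationSpectra):
        meta = {**obj.metadata, "dialect": "spectra"}
        header = ["wavelength_nm"] + [f"{p:.12g}" for p in obj.ph_values]
        body = np.column_stack([obj.wavelengths, obj.values])
    elif isinstance(obj, CurrentTrace):
        meta = {**obj.metadata, "dialect": "trace",
                "voltage_mV": obj.voltage, "excitation_nm": obj.excitation,
                "pulse_times_s": obj.pulse_times}
        header = ["time_s", "current_pA"]
        body = np.column_stack([obj.times, obj.current])
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write(",".join(header) + "\n")
        np.savetxt(fh, body, delimiter=",", fmt="%.12g")


def read_matrix(path, dialect: str | None = None):
    """Read a dialect CSV back into its typed container.

    `dialect` (ta | spectra | trace) defaults to the value declared in
    the file's metadata block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, skip = _read_meta(path)
    dialect = dialect or meta.get("dialect")
    if dialect not in ("ta", "spectra", "trace"):
        raise ValueError(f"unknown or undeclared dialect {dialect!r}")
    table = pd.read_csv(path, skiprows=skip)
    extra = {k: _coerce(v) for k, v in meta.items()
             if k not in ("dialect", "time_unit", "signal_unit",
                          "voltage_mV", "excitation_nm", "pulse_times_s")}
    if dialect == "ta":
        if "time_unit" not in meta:
            raise ValueError("time_unit metadata line is mandatory for the "
                             "ta dialect")
        if meta["time_unit"] not in TIME_UNITS:
            raise ValueError(f"unknown time unit {meta['time_unit']!r}")
        if table.columns[0] != "wavelength_nm":
            raise ValueError("first column must be wavelength_nm")
        times = np.asarray([float(c) for c in table.columns[1:]])
        return TAMatrix(table.iloc[:, 0].to_numpy(), times,
                        table.iloc[:, 1:].to_numpy(),
                        time_unit=meta["time_unit"],
                        signal_unit=meta.get("signal_unit", "mOD"),
                        metadata=extra)
    if dialect == "spectra":
        if table.columns[0] != "wavelength_nm":
            raise ValueError("first column must be wavelength_nm")
        ph = np.asarray([float(c) for c in table.columns[1:]])
        return TitrationSpectra(table.iloc[:, 0].to_numpy(), ph,
                                table.iloc[:, 1:].to_numpy(), metadata=extra)
    for key in ("voltage_mV", "excitation_nm", "pulse_times_s"):
        if key not in meta:
            raise ValueError(f"trace dialect requires metadata line {key!r}")
    pulses = np.asarray([float(x) for x in meta["pulse_times_s"].split(";")])
    return CurrentTrace(table["time_s"].to_numpy(),
                        table["current_pA"].to_numpy(),
                        voltage=float(meta["voltage_mV"]),
                        excitation=float(meta["excitation_nm"]),
                        pulse_times=pulses, metadata=extra)


def _coerce(value: str):
    try:
        f = float(value)
        return int(f) if f.is_integer() and "." not in value else f
    except (TypeError, ValueError):
        return value


# ---------------------------------------------------------------------------
# result serialization


def _jsonable(obj):
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_results(obj, path, fmt: str = "json", force: bool = False,
                  provenance: dict | None = None) -> None:
    """Serialize a result object with provenance; deterministic output."""
    path = _guard(path, force)
    if fmt == "json":
        payload = {"cryor_version": __version__, **(provenance or {}),
                   "result": _jsonable(obj)}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif fmt == "tsv":
        if isinstance(obj, pd.DataFrame):
            df = obj
        elif isinstance(obj, list):
            df = pd.DataFrame([dataclasses.asdict(o) for o in obj])
        else:
            raise TypeError("tsv output needs a DataFrame or dataclass list")
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
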