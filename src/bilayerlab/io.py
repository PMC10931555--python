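"""Readers and writers for the plain-text exchange formats.

Scattering curves travel as 2/3-column ASCII ``.dat`` files (q, I, optional
sigma) with ``#``-prefixed ``key: value`` header lines; thermograms, emission
spectra and time traces as CSV with a header row and the same ``#`` metadata
convention. Synthetic data can carry a ``<name>.truth.json`` sidecar with the
generator's ground-truth parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EmissionSpectrum, ScatteringCurve, Thermogram, TimeTrace

__all__ = [
    "read_dat", "write_dat",
    "read_thermogram_csv", "write_thermogram_csv",
    "read_trace_csv", "write_trace_csv",
    "read_spectrum_csv", "write_spectrum_csv",
    "write_truth_sidecar", "read_truth_sidecar",
]


def _parse_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "columns":
                    continue
                try:
                    meta[key] = json.loads(val)
                except (json.JSONDecodeError, ValueError):
                    meta[key] = val
    return meta


def _format_meta(meta: dict) -> str:
    lines = []
    for key, val in meta.items():
        if isinstance(val, (dict, list)):
            val = json.dumps(val)
        lines.append(f"# {key}: {val}")
    return "\n".join(lines)


def write_dat(curve: ScatteringCurve, path) -> Path:
    """Write a scattering curve as 3-column (or 2-column) ASCII."""
    path = Path(path)
    cols = [curve.q, curve.I]
    names = "q_nm^-1 I"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names += " sigma"
    header = _format_meta(curve.meta)
    if header:
        header += "\n"
    header += f"# columns: {names}"
    np.savetxt(path, np.column_stack(cols), header=header, comments="")
    return path


def read_dat(path) -> ScatteringCurve:
    path = Path(path)
    meta = _parse_meta(path)
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, meta)


def _write_csv(df: pd.DataFrame, meta: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        header = _format_meta(meta)
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, index=False)
    return path


def write_thermogram_csv(tg: Thermogram, path) -> Path:
    meta = dict(tg.meta)
    meta.update(scan_id=tg.scan_id, direction=tg.direction,
                sample_mass_normalized=tg.sample_mass_normalized)
    df = pd.DataFrame({"T_C": tg.T, "cp_excess_J_per_g_C": tg.cp_excess})
    return _write_csv(df, meta, path)


def read_thermogram_csv(path) -> Thermogram:
    meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    scan_id = int(meta.pop("scan_id", 0))
    direction = str(meta.pop("direction", "heating"))
    normed = bool(meta.pop("sample_mass_normalized", True))
    return Thermogram(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                      scan_id=scan_id, direction=direction,
                      sample_mass_normalized=normed, meta=meta)


def write_trace_csv(trace: TimeTrace, path) -> Path:
    meta = dict(trace.meta)
    if trace.wavelength is not None:
        meta["wavelength_nm"] = trace.wavelength
    df = pd.DataFrame({"t_s": trace.t, "intensity": trace.I})
    return _write_csv(df, meta, path)


def read_trace_csv(path) -> TimeTrace:
    meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    wl = meta.pop("wavelength_nm", None)
    wl = float(wl) if wl is not None else None
    return TimeTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                     wavelength=wl, meta=meta)


def write_spectrum_csv(spec: EmissionSpectrum, path) -> Path:
    df = pd.DataFrame({"wavelength_nm": spec.wavelength, "intensity": spec.I})
    return _write_csv(df, spec.meta, path)


def read_spectrum_csv(path) -> EmissionSpectrum:
    meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    return EmissionSpectrum(df.iloc[:, 0].to_numpy(),
                            df.iloc[:, 1].to_numpy(), meta=meta)


def write_truth_sidecar(params, path) -> Path:
    """Write generator ground-truth parameters next to a data file."""
    from dataclasses import asdict, is_dataclass

    path = Path(str(path) + ".truth.json")
    payload = asdict(params) if is_dataclass(params) else dict(params)
    payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in payload.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path


def read_truth_sidecar(data_path) -> dict:
    with open(str(data_path) + ".truth.json") as fh:
        return json.load(fh)
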