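"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`RunConfig` (optionally loaded from YAML) lists samples, the
modalities to run, ground-truth overrides for the simulator and analysis
settings. ``run_pipeline`` executes every (sample x modality) stage, writes
one JSON record per analysis plus a combined CSV summary table, and is
byte-deterministic for a fixed seed. A modality entry may point at an
existing data file via ``input`` instead of simulating.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import List, Optional

import pandas as pd
import yaml

from . import io as blio
from .composition import SampleComposition, molar_ratio, ratio_label
from .dsc import TransitionModel
from .fluorescence import LateralPressure
from .sans import KratkyPorod, subtract_incoherent_background
from .saxs import LamellarModel, WaxsModel
from .synthetic import (EndothermParams, FluorescenceParams,
                        LamellarModelParams, SansModelParams, gen_fluorescence,
                        gen_sans_curve, gen_saxs_waxs_pattern, gen_thermogram)

__all__ = ["RunConfig", "run_pipeline", "PipelineStageError"]

log = logging.getLogger("bilayerlab")

MODALITIES = ("sans", "saxs", "waxs", "dsc", "fluorescence")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "bilayerlab_run"
    modalities: List[str] = field(default_factory=lambda: list(MODALITIES))
    samples: List[dict] = field(
        default_factory=lambda: [{"label": "surfactant", "bud_wt_pct": 0.0}])
    sans: dict = field(default_factory=dict)
    saxs: dict = field(default_factory=dict)
    waxs: dict = field(default_factory=dict)
    dsc: dict = field(default_factory=dict)
    fluorescence: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}; "
                             f"choose from {MODALITIES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        payload = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path


def _stage_seed(base: int, sample_idx: int, modality: str) -> int:
    return (base * 1009 + sample_idx * 13
            + MODALITIES.index(modality)) % (2 ** 31)


def _build_params(cls, overrides: dict, **extra):
    known = {f.name for f in dc_fields(cls)}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} fields {sorted(bad)}")
    merged = dict(overrides)
    merged.update(extra)
    return cls(**merged)


def _load_or_none(path_value, reader, stage):
    if path_value is None:
        return None
    path = Path(path_value)
    if not path.exists():
        raise PipelineStageError(stage, f"input file not found: {path}")
    return reader(path)


def _write_record(record: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested (sample x modality) stage and write reports.

    Returns ``{"summary": DataFrame, "records": {stage_name: dict}}``.
    Deterministic: identical config and seed give byte-identical JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = {}
    rows = []

    for s_idx, sample in enumerate(config.samples):
        label = str(sample.get("label", f"sample{s_idx}"))
        wt = float(sample.get("bud_wt_pct", 0.0))
        row = {"sample": label, "bud_wt_pct": wt}
        comp = SampleComposition(bud_wt_pct=wt)
        if wt > 0:
            r = molar_ratio(comp)
            row["lipid_per_drug_mol"] = r
            row["mol_ratio_label"] = ratio_label(r)

        for modality in config.modalities:
            stage = f"{label}/{modality}"
            t0 = time.perf_counter()
            try:
                record = _run_stage(config, modality, label, wt,
                                    s_idx, outdir)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(stage, str(err)) from err
            log.info("stage %s finished in %.3f s", stage,
                     time.perf_counter() - t0)
            records[stage] = record
            _write_record(record, outdir / f"{label}_{modality}.result.json")
            row.update(record.get("summary_fields", {}))
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    return {"summary": summary, "records": records}


def _run_stage(config: RunConfig, modality: str, label: str, wt: float,
               s_idx: int, outdir: Path) -> dict:
    seed = _stage_seed(config.seed, s_idx, modality)
    stage = f"{label}/{modality}"

    if modality == "sans":
        opts = dict(config.sans)
        q_window = tuple(opts.pop("q_window", (0.31, 1.14)))
        tail = tuple(opts.pop("tail_window", (4.0, 5.0)))
        curve = _load_or_none(opts.pop("input", None), blio.read_dat, stage)
        if curve is None:
            params = _build_params(SansModelParams, opts, seed=seed)
            curve = gen_sans_curve(params)
            path = outdir / f"{label}_sans.dat"
            blio.write_dat(curve, path)
            blio.write_truth_sidecar(params, path)
        res = KratkyPorod(subtract_incoherent_background(curve, tail),
                          q_window=q_window).fit()
        return {"modality": "sans", "sample": label,
                "result": res.to_dict(),
                "summary_fields": {"d_g_nm": res.d_g,
                                   "d_g_sd_nm": res.d_g_sd}}

    if modality == "saxs":
        opts = dict(config.saxs)
        n_orders = int(opts.pop("fit_orders", 2))
        init_d = opts.pop("init_d", None)
        curve = _load_or_none(opts.pop("input", None), blio.read_dat, stage)
        if curve is None:
            params = _build_params(LamellarModelParams, opts, seed=seed)
            curve = gen_saxs_waxs_pattern(params)
            path = outdir / f"{label}_saxs_waxs.dat"
            blio.write_dat(curve, path)
            blio.write_truth_sidecar(params, path)
        res = LamellarModel(curve, n_orders=n_orders, init_d=init_d).fit()
        return {"modality": "saxs", "sample": label,
                "result": res.to_dict(),
                "summary_fields": {"d_nm": res.d, "d_sd_nm": res.d_sd}}

    if modality == "waxs":
        opts = dict(config.waxs)
        curve = _load_or_none(opts.pop("input", None), blio.read_dat, stage)
        if curve is None:
            params = _build_params(LamellarModelParams, dict(config.saxs),
                                   seed=seed)
            curve = gen_saxs_waxs_pattern(params)
        res = WaxsModel(curve, **opts).fit()
        return {"modality": "waxs", "sample": label,
                "result": res.to_dict(),
                "summary_fields": {
                    "waxs_classification": res.classification,
                    "n_crystalline_peaks": len(res.sharp_peaks)}}

    if modality == "dsc":
        opts = dict(config.dsc)
        pre = tuple(opts.pop("pre_window", (2.0, 8.0)))
        post = tuple(opts.pop("post_window", (36.0, 40.0)))
        tg = _load_or_none(opts.pop("input", None),
                           blio.read_thermogram_csv, stage)
        if tg is None:
            params = _build_params(EndothermParams, opts, seed=seed)
            tg = gen_thermogram(params)
            path = outdir / f"{label}_dsc.csv"
            blio.write_thermogram_csv(tg, path)
            blio.write_truth_sidecar(params, path)
        res = TransitionModel(tg, pre_window=pre, post_window=post).fit()
        return {"modality": "dsc", "sample": label,
                "result": res.to_dict(),
                "summary_fields": {"Tm_C": res.Tm, "dH_J_per_g": res.dH,
                                   "fwhm_C": res.fwhm}}

    if modality == "fluorescence":
        opts = dict(config.fluorescence)
        probes = opts.pop("probes", {"Pyr4PC": 1.87, "Pyr10PC": 1.13})
        mono_in = opts.pop("monomer_input", None)
        exc_in = opts.pop("excimer_input", None)
        summary_fields = {}
        result = {}
        if mono_in is not None or exc_in is not None:
            probe = opts.pop("probe", "Pyr10PC")
            mono = _load_or_none(mono_in, blio.read_trace_csv, stage)
            exc = _load_or_none(exc_in, blio.read_trace_csv, stage)
            res = LateralPressure(exc, mono, probe_label=probe).fit()
            result[probe] = res.to_dict()
            summary_fields[f"eta_{probe}"] = res.eta
        else:
            for p_idx, (probe, eta) in enumerate(sorted(probes.items())):
                params = _build_params(
                    FluorescenceParams, opts, eta_true=float(eta),
                    probe_label=probe, seed=seed + 101 * (p_idx + 1))
                spec, mono, exc = gen_fluorescence(params)
                base = outdir / f"{label}_{probe}"
                blio.write_spectrum_csv(spec, f"{base}_spectrum.csv")
                blio.write_trace_csv(mono, f"{base}_monomer.csv")
                blio.write_trace_csv(exc, f"{base}_excimer.csv")
                blio.write_truth_sidecar(params, f"{base}_traces")
                res = LateralPressure(exc, mono, probe_label=probe).fit()
                result[probe] = res.to_dict()
                summary_fields[f"eta_{probe}"] = res.eta
                summary_fields[f"eta_sd_{probe}"] = res.eta_sd
        return {"modality": "fluorescence", "sample": label,
                "result": result, "summary_fields": summary_fields}

    raise PipelineStageError(stage, f"unknown modality {modality!r}")


def configure_logging(verbose: bool = True) -> None:
    """Log stage progress to stderr, keeping stdout clean for results."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(message)s",
                                           datefmt="%H:%M:%S"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
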