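"""Readers/writers for the text formats, configs and run manifests.

Time series travel as comma-separated text with header
``time,S1,S2,X1,X2`` (dimensional) or ``time,u,v,x,y`` (dimensionless),
one row per grid point at full double precision.  Every pipeline run
writes a manifest listing the resolved configuration, the seeds used and
a SHA-256 digest of each output file, so a run can be replayed and
verified byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ad_models import (ADParams, DIMENSIONAL_COLUMNS, DIMENSIONLESS_COLUMNS,
                        TimeSeries, dimensional_equilibrium)
from .detection import (absolute_error_curve, detect_absolute,
                        detect_relative, relative_error_curve, smooth)
from .smap import SmapConfig, control_forecasts, monitoring_forecasts
from .synthetic_data import (NoiseModel, default_delta_eq, generate_ensemble,
                             ground_truth_end_time, subsample)
from .evaluation import UndefinedScoreError, pearson_corr, r2_identity

logger = logging.getLogger(__name__)

_LAYOUTS = {DIMENSIONAL_COLUMNS: "dimensional",
            DIMENSIONLESS_COLUMNS: "dimensionless"}


class FormatError(ValueError):
    """A file does not match the declared text layout."""


def write_timeseries(ts: TimeSeries, path) -> Path:
    """Write a series as delimiter-separated text at full precision."""
    path = Path(path)
    df = ts.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path) -> TimeSeries:
    """Parse a series file, validating the header and the uniform grid."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = tuple(df.columns)
    if len(cols) != 5 or cols[0] != "time" or cols[1:] not in _LAYOUTS:
        raise FormatError(
            f"{path}: header {','.join(cols)!r} matches neither "
            "time,S1,S2,X1,X2 nor time,u,v,x,y")
    times = df["time"].to_numpy(dtype=float)
    steps = np.diff(times)
    dt = steps[0] if len(steps) else 0.0
    if len(times) < 2 or dt <= 0:
        raise FormatError(f"{path}: need at least two increasing time rows")
    bad = np.flatnonzero(np.abs(steps - dt) > 1e-9 * dt)
    if bad.size:
        raise FormatError(
            f"{path}: non-uniform time grid at data row {int(bad[0]) + 2}")
    return TimeSeries(times=times,
                      states=df[list(cols[1:])].to_numpy(dtype=float),
                      frame=_LAYOUTS[cols[1:]])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    """Load a hierarchical YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


DEFAULT_CONFIG = {
    "model": {},              # ADParams overrides (field names as in the docs)
    "noise": {"sigma": 0.1, "dt": 0.01},
    "generate": {"n_series": 10, "t_max": 200.0, "seed": 0},
    "subsample": {"delta_t": 0.1},
    "smap": {"theta": 5.0, "h": 20, "mode": "monitoring"},
    "detection": {"rule": "rel", "delta": 0.5, "window": 10},
}


def resolve_config(config: dict | None) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    config = config or {}
    resolved = {}
    for section, defaults in DEFAULT_CONFIG.items():
        given = config.get(section, {})
        unknown = (set(given) - set(defaults)) if section != "model" else set()
        if unknown:
            raise FormatError(
                f"unknown key(s) {sorted(unknown)} in section {section!r}; "
                f"expected a subset of {sorted(defaults)}")
        resolved[section] = {**defaults, **given}
    extra = set(config) - set(DEFAULT_CONFIG)
    if extra:
        raise FormatError(
            f"unknown config section(s) {sorted(extra)}; expected a subset "
            f"of {sorted(DEFAULT_CONFIG)}")
    return resolved


def run_pipeline(config: dict | None, outdir) -> dict:
    """Generate -> forecast -> error curves -> detect -> evaluate.

    Writes every intermediate series and result under ``outdir`` plus a
    ``manifest.json`` capturing the resolved config, seeds, initial
    conditions and per-file SHA-256 digests.  Returns the manifest.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "setup"
    files: list[Path] = []
    try:
        params = (ADParams(**{**ADParams.default().__dict__,
                              **cfg["model"]})
                  if cfg["model"] else ADParams.default())
        noise = NoiseModel(**cfg["noise"])
        gen = cfg["generate"]
        s1_star = float(dimensional_equilibrium(params)[0][0])
        delta_eq = default_delta_eq(noise.sigma)

        stage = "generate"
        records = generate_ensemble(params, noise, int(gen["n_series"]),
                                    float(gen["t_max"]), int(gen["seed"]))
        mode = cfg["smap"]["mode"]
        if mode not in ("monitoring", "control"):
            raise FormatError(f"unknown smap mode {mode!r}")
        control_full = records[0]["series"] if mode == "control" else None
        work_records = records[1:] if mode == "control" else records

        stage = "forecast"
        smap_cfg = SmapConfig(theta=float(cfg["smap"]["theta"]),
                              h=int(cfg["smap"]["h"]))
        delta_t = float(cfg["subsample"]["delta_t"])
        rule = cfg["detection"]["rule"]
        if rule not in ("abs", "rel"):
            raise FormatError(f"unknown detection rule {rule!r}")
        control_ts = (subsample(control_full, delta_t)
                      if control_full is not None else None)
        per_series = []
        for i, rec in enumerate(work_records):
            working = subsample(rec["series"], delta_t)
            files.append(write_timeseries(working,
                                          outdir / f"series_{i:04d}.csv"))
            if mode == "monitoring":
                fc = monitoring_forecasts(working, smap_cfg)
            else:
                fc = control_forecasts(control_ts, working, smap_cfg)
            fpath = outdir / f"forecast_{i:04d}.csv"
            fc.to_frame().to_csv(fpath, index=False, float_format="%.17g")
            files.append(fpath)
            per_series.append((rec, working, fc))

        stage = "detect"
        det = cfg["detection"]
        results = []
        for i, (rec, working, fc) in enumerate(per_series):
            err = (absolute_error_curve(fc) if rule == "abs"
                   else relative_error_curve(fc))
            curve = smooth(err, window=int(det["window"]))
            epath = outdir / f"errors_{i:04d}.csv"
            curve.to_frame().to_csv(epath, index=False, float_format="%.17g")
            files.append(epath)
            d = (detect_absolute(curve, float(det["delta"])) if rule == "abs"
                 else detect_relative(curve, float(det["delta"])))
            gt = ground_truth_end_time(working, s1_star, delta_eq)
            results.append({
                "series": i, "t_pred": d.t_pred,
                "t_end": None if gt is None else gt.t_end,
                "init": [float(v) for v in rec["init"]],
                "spawn_key": [int(k) for k in rec["spawn_key"]]})

        stage = "evaluate"
        pairs = [(r["t_pred"], r["t_end"]) for r in results
                 if r["t_pred"] is not None and r["t_end"] is not None]
        summary = {"n_series": len(results),
                   "n_predicted": sum(r["t_pred"] is not None
                                      for r in results),
                   "n_paired": len(pairs), "s1_star": s1_star,
                   "delta_eq": delta_eq,
                   "r2_identity": None, "pearson_r": None}
        if len(pairs) >= 2:
            pred, tru = map(np.asarray, zip(*pairs))
            try:
                summary["r2_identity"] = r2_identity(pred, tru)
            except UndefinedScoreError:
                pass
            try:
                summary["pearson_r"] = pearson_corr(pred, tru)
            except UndefinedScoreError:
                pass
        dpath = outdir / "detections.json"
        dpath.write_text(json.dumps({"results": results,
                                     "summary": summary}, indent=2))
        files.append(dpath)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} "
            f"(partial outputs: {[f.name for f in files]})") from exc

    manifest = {
        "tool": "transientad", "version": __version__,
        "command": "pipeline", "config": cfg,
        "base_seed": int(cfg["generate"]["seed"]),
        "elapsed_s": time.perf_counter() - t0,
        "outputs": {f.name: _sha256(f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline wrote %d files to %s in %.1f s",
                len(files) + 1, outdir, manifest["elapsed_s"])
    return manifest
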