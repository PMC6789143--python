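"""Orchestration: track -> linear metrics -> nonlinear analysis.

``run_single`` analyzes one recording (video stack or waveform CSV) and
returns a JSON-serializable report; ``run_batch`` maps a manifest of
labelled inputs through ``run_single`` and summarizes each metric per group
(mean ± sd, two grouping axes). Stage failures in batch mode are recorded
as flags on the affected sample; the batch keeps running.

Reports are deterministic: given the same input and the echoed config they
serialize bit-identically (timings go to the logger, never the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DegenerateInputError, InvalidInputError
from .io import load_frame_sequence, read_waveform_csv, write_waveform_csv
from .linmetrics import beat_metrics, detect_peaks
from .motiontrack import FrameSequence, MotionWaveform, track
from .nonlin import acf_lag, capacity_dimension, correlation_dimension, fnn_embedding_dim, variogram

logger = logging.getLogger("cardiodyn.pipeline")

__all__ = ["AnalysisConfig", "run_single", "run_batch", "summarize_groups"]

MANIFEST_REQUIRED = ("path", "sample_id", "group")

#: report metrics aggregated in group summaries
SUMMARY_METRICS = (
    "beat_rate_bpm",
    "pp_interval_s",
    "contraction_velocity_um_s",
    "relaxation_velocity_um_s",
    "D_capacity_mean",
    "D_steady",
)


@dataclass
class AnalysisConfig:
    """Every knob of the pipeline, echoed verbatim into each report."""

    # motion tracking
    block_size: int = 16
    search_radius: int = 7
    subpixel: bool = False
    fps: float | None = None  # required for video inputs
    um_per_px: float | None = None
    # peak detection
    min_prominence_frac: float = 0.15
    min_separation_s: float = 0.1
    larger_is_contraction: bool = False
    # nonlinear analysis
    tau: int | None = None  # None = auto via ACF 1/e
    m_min: int = 2
    m_max: int = 12
    n_bins: int = 32
    log_bins: bool = True
    theiler: int = 0
    tau_max: int | None = None
    compute_fnn: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _clean(obj):
    """Make a report JSON-safe: NaN/inf -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_json(report: dict) -> str:
    """Canonical serialization used for determinism checks."""
    return json.dumps(_clean(report), sort_keys=True, indent=1)


def _load_input(inp, config: AnalysisConfig):
    if isinstance(inp, MotionWaveform):
        return inp, None
    if isinstance(inp, FrameSequence):
        return None, inp
    p = str(inp)
    if p.endswith(".csv"):
        return read_waveform_csv(p), None
    if config.fps is None or config.um_per_px is None:
        raise InvalidInputError("video input requires fps and um_per_px in the config")
    return None, load_frame_sequence(p, config.fps, config.um_per_px)


def run_single(inp, config: AnalysisConfig | None = None, labels: dict | None = None) -> dict:
    """Analyze one recording end to end.

    ``inp`` may be a waveform CSV path, a video stack path/glob, or an
    in-memory :class:`MotionWaveform` / :class:`FrameSequence`. Waveform
    inputs skip the tracking stage. Degenerate samples (e.g. constant
    waveforms) produce flagged sentinel fields, not failures.
    """
    config = config or AnalysisConfig()
    report: dict = {
        "version": __version__,
        "input": str(inp) if isinstance(inp, (str, os.PathLike)) else "<in-memory>",
        "labels": dict(labels or {}),
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    wave, seq = _load_input(inp, config)

    if seq is not None:
        t0 = time.perf_counter()
        wave = track(seq, config.block_size, config.search_radius, config.subpixel)
        logger.info("stage=track n_frames=%d dt=%.3fs", seq.n_frames, time.perf_counter() - t0)
        report["stages"]["track"] = {
            "n_frames": seq.n_frames,
            "block_size": config.block_size,
            "search_radius": config.search_radius,
        }
    report["n_samples"] = wave.n
    report["fps"] = wave.fps

    t0 = time.perf_counter()
    peaks = detect_peaks(
        wave,
        min_prominence_frac=config.min_prominence_frac,
        min_separation_s=config.min_separation_s,
        larger_is_contraction=config.larger_is_contraction,
    )
    metrics = beat_metrics(wave, peaks)
    logger.info("stage=metrics n_peaks=%d dt=%.3fs", len(peaks), time.perf_counter() - t0)
    report["stages"]["metrics"] = metrics.to_dict()
    report["warnings"] += metrics.flags

    t0 = time.perf_counter()
    v = capacity_dimension(variogram(wave.S, tau_max=config.tau_max))
    logger.info("stage=variogram dt=%.3fs", time.perf_counter() - t0)
    report["stages"]["variogram"] = v.to_dict()
    if v.degenerate:
        report["warnings"].append("variogram_degenerate")

    t0 = time.perf_counter()
    corr: dict = {}
    try:
        lag = acf_lag(wave.S)
        tau = config.tau if config.tau is not None else lag.tau_star
        corr["acf_tau_star"] = lag.tau_star
        corr["acf_warning"] = lag.warning
        if config.compute_fnn and not lag.warning:
            fnn = fnn_embedding_dim(wave.S, tau, m_max=config.m_max)
            corr["m_fnn"] = fnn.m
            corr["fnn_warning"] = fnn.warning
        cres = correlation_dimension(
            wave.S,
            tau=tau,
            m_values=range(config.m_min, config.m_max + 1),
            n_bins=config.n_bins,
            log_bins=config.log_bins,
            theiler=config.theiler,
        )
        corr.update(cres.to_dict())
        report["warnings"] += cres.warnings
    except (DegenerateInputError, InvalidInputError) as exc:
        corr["error"] = str(exc)
        report["warnings"].append(f"correlation_failed: {exc}")
    logger.info("stage=correlation dt=%.3fs", time.perf_counter() - t0)
    report["stages"]["correlation"] = corr
    return _clean(report)


def _flat_metrics(report: dict) -> dict:
    """Pull the summary scalars out of a report for tabulation."""
    out = {}
    m = report["stages"].get("metrics", {})
    for key in SUMMARY_METRICS[:4]:
        out[key] = (m.get(key) or {}).get("mean")
    out["D_capacity_mean"] = report["stages"].get("variogram", {}).get("D_capacity_mean")
    out["D_steady"] = report["stages"].get("correlation", {}).get("D_steady")
    return out


def summarize_groups(samples: pd.DataFrame, axes: tuple[str, ...] = ("group", "sample_id")) -> pd.DataFrame:
    """Per-group mean ± sd of every summary metric, one row per (axis, level, metric).

    Singleton groups report sd as NaN (ddof=1), matching the undefined-sd
    sentinel convention.
    """
    rows = []
    for axis in axes:
        if axis not in samples.columns:
            continue
        for level, sub in samples.groupby(axis, sort=True):
            for metric in SUMMARY_METRICS:
                vals = pd.to_numeric(sub[metric], errors="coerce").dropna()
                rows.append(
                    {
                        "axis": axis,
                        "level": level,
                        "metric": metric,
                        "mean": vals.mean() if len(vals) else float("nan"),
                        "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                        "n": int(len(vals)),
                    }
                )
    return pd.DataFrame(rows)


def run_batch(
    manifest, config: AnalysisConfig | None = None, out_dir: str | os.PathLike | None = None
) -> tuple[list[dict], pd.DataFrame, pd.DataFrame]:
    """Run every manifest row through :func:`run_single` and summarize.

    ``manifest`` is a DataFrame or a CSV/TSV path with columns
    ``path, sample_id, group`` (optional ``fps``, ``um_per_px`` override the
    config per row). Returns (reports, per-sample table, group summary).
    Failed samples carry an ``error`` field and NaN metrics.
    """
    config = config or AnalysisConfig()
    if isinstance(manifest, (str, os.PathLike)):
        sep = "\t" if str(manifest).endswith((".tsv", ".txt")) else ","
        manifest = pd.read_csv(manifest, sep=sep)
    if manifest is None or len(manifest) == 0:
        raise InvalidInputError("empty manifest")
    missing = [c for c in MANIFEST_REQUIRED if c not in manifest.columns]
    if missing:
        raise InvalidInputError(f"manifest lacks required columns: {missing}")

    reports: list[dict] = []
    rows = []
    for _, row in manifest.iterrows():
        cfg = config
        overrides = {}
        for key in ("fps", "um_per_px"):
            if key in manifest.columns and pd.notna(row[key]):
                overrides[key] = float(row[key])
        if overrides:
            cfg = AnalysisConfig.from_dict({**config.to_dict(), **overrides})
        labels = {k: row[k] for k in ("sample_id", "group") if k in manifest.columns}
        try:
            rep = run_single(row["path"], cfg, labels=labels)
        except Exception as exc:  # keep the batch alive
            logger.warning("sample %s failed: %s", row["path"], exc)
            rep = {
                "version": __version__,
                "input": str(row["path"]),
                "labels": labels,
                "config": cfg.to_dict(),
                "stages": {},
                "warnings": [f"sample_failed: {exc}"],
                "error": str(exc),
            }
        reports.append(rep)
        rows.append({**labels, "path": row["path"], **_flat_metrics(rep)})
    table = pd.DataFrame(rows)
    summary = summarize_groups(table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(reports):
            sid = rep["labels"].get("sample_id", f"sample{i}")
            (out / f"{sid}_{i:03d}.json").write_text(report_json(rep))
        table.to_csv(out / "samples.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(_clean(config.to_dict()), sort_keys=True, indent=1))
    return reports, table, summary
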