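"""Signal file I/O, pipeline configuration and the end-to-end runner.

CSV is the canonical interchange format: signals as ``time_s,value``
rows, annotations and feature tables as plain CSV, models as JSON.  All
sample indices in files are 0-based and all times are in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    FEATURE_NAMES,
    StandardTemplate,
    default_template,
    extract_features,
    segment_breath_frames,
)
from .jpeaks import DetectorParams, JPeakResult, detect_jpeaks
from .logit import LogitModel, classify, predict_proba
from .synth import RawRecord
from .wavelets import SeparatedSignals, separate

__all__ = [
    "PipelineConfig",
    "read_signal",
    "write_signal",
    "features_table",
    "run_pipeline",
]

logger = logging.getLogger("bedapnea")


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's parameters; defaults follow the method's stated values
    (fs 50 Hz, db5, 5 levels, USH 0.02, DSH 0.22 s, 220 ms refractory,
    close-peak factor 0.4, missed-peak factor 1.66, decision cut 0.5)."""

    fs: float = 50.0
    wavelet: str = "db5"
    levels: int = 5
    include_d5_respiration: bool = False
    threshold_levels: tuple[int, ...] = (1,)
    detrend: str = "mean"
    ush_base: float = 0.02
    bias: float = 0.0
    adaptive_bias: bool = True
    dsh: float = 0.22
    refractory_ms: float = 220.0
    low_factor: float = 0.4
    high_factor: float = 1.66
    threshold_relax: float = 0.5
    decision_threshold: float = 0.5

    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            ush_base=self.ush_base,
            bias=self.bias,
            adaptive_bias=self.adaptive_bias,
            dsh=self.dsh,
            refractory_ms=self.refractory_ms,
            low_factor=self.low_factor,
            high_factor=self.high_factor,
            threshold_relax=self.threshold_relax,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "threshold_levels" in data:
            data["threshold_levels"] = tuple(data["threshold_levels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["threshold_levels"] = list(data["threshold_levels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_signal(record: RawRecord, path: str | Path) -> None:
    """Write one channel as ``time_s,value`` CSV."""
    df = pd.DataFrame({"time_s": record.time_s, "value": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_signal(path: str | Path, fs: float | None = None, fmt: str = "csv") -> RawRecord:
    """Read a single-channel recording.

    CSV with ``time_s,value`` columns (sampling rate inferred and checked
    for uniformity) or a single ``value`` column with ``fs`` declared.
    Irregular sampling (timestamp jitter above 0.1/fs) is refused with
    the offending rows named.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}: only 'csv' is supported")
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column, got {list(df.columns)}")
    values = df["value"].to_numpy(dtype=float)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError(f"{path}: need at least 2 samples")
        fs_est = 1.0 / float(np.median(dt))
        jitter = np.abs(dt - 1.0 / fs_est)
        bad = np.flatnonzero(jitter > 0.1 / fs_est)
        if bad.size:
            rows = ", ".join(str(int(b) + 1) for b in bad[:5])
            raise ValueError(
                f"{path}: irregular sampling at data rows {rows}"
                + ("..." if bad.size > 5 else "")
            )
        fs = fs_est
    elif fs is None:
        raise ValueError(f"{path}: no time_s column; declare the sampling rate")
    return RawRecord(samples=values, fs=float(fs), meta={"source": str(path)})


def features_table(
    frames,
    template: StandardTemplate | None = None,
) -> pd.DataFrame:
    """Per-frame feature table with frame bounds, one row per breath frame."""
    template = template or default_template()
    rows = []
    for fr in frames:
        fv = extract_features(fr, template)
        rows.append(
            {
                "frame_start": fr.start_sample,
                "frame_end": fr.end_sample,
                **dict(zip(FEATURE_NAMES, fv.as_array())),
                "fallback": fr.fallback,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["frame_start", "frame_end", *FEATURE_NAMES, "fallback"],
    )


def run_pipeline(
    record: RawRecord,
    config: PipelineConfig | None = None,
    model: LogitModel | None = None,
    template: StandardTemplate | None = None,
    stop_after: str | None = None,
) -> dict:
    """Separate -> detect -> segment -> features -> classify.

    Returns a dict with the intermediate products of every executed
    stage; classification is skipped when no model is supplied, and
    ``stop_after`` ∈ {separate, detect, features} truncates the run.
    Identical config and input give identical outputs.
    """
    config = config or PipelineConfig()
    out: dict = {"config": config}

    logger.info("stage separate: wavelet=%s levels=%d", config.wavelet, config.levels)
    sep: SeparatedSignals = separate(
        record,
        wavelet=config.wavelet,
        levels=config.levels,
        include_d5_respiration=config.include_d5_respiration,
        threshold_levels=config.threshold_levels,
        detrend=config.detrend,
    )
    out["separated"] = sep
    if stop_after == "separate":
        return out

    logger.info("stage detect")
    peaks: JPeakResult = detect_jpeaks(sep.bcg, record.fs, config.detector_params())
    out["jpeaks"] = peaks
    if stop_after == "detect":
        return out

    logger.info("stage features")
    frames = segment_breath_frames(sep.respiration, record.fs, peaks.peaks)
    out["frames"] = frames
    out["features"] = features_table(frames, template)
    if stop_after == "features" or model is None:
        return out

    logger.info("stage classify")
    X = out["features"][list(FEATURE_NAMES)].to_numpy(dtype=float)
    calls = out["features"][["frame_start", "frame_end"]].copy()
    calls["p_apnea"] = predict_proba(model, X)
    calls["label"] = np.asarray(classify(model, X)).ravel()
    out["calls"] = calls
    return out
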