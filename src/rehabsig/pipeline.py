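"""Pipeline configuration and the end-to-end processing run.

:func:`run_pipeline` is the software-platform stand-in: it conditions the
ECG, extracts R peaks / R-R intervals / HRV, applies the fatigue rule,
computes per-segment EMG RMS on both channels, normalizes, detects motion
events, and writes every artifact plus a JSON summary (heart rate, per-bout
mean RMS per channel, status timeline, alerts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import ecg as _ecg
from . import emg as _emg
from . import fatigue as _fatigue
from . import io as _io
from .errors import ConfigError, RehabSigError
from .types import Status

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("rehabsig")


@dataclass
class PipelineConfig:
    """Validated knobs for one processing run. Unknown keys are rejected."""

    seed: int = 0
    # ECG conditioning / detection
    ecg_cutoff_hz: float = 40.0
    baseline_window_ms: float = 600.0
    artifact_filter: bool = True
    k_mad: float = 8.0
    min_rr_ms: float = 300.0
    # HRV / fatigue
    hrv_k: int = 10
    fatigue_epsilon_ms: float = 5.0
    svm_smoothing: int = 3
    # EMG
    segment_n: int = 200
    activity_threshold: float = 0.2
    min_duration_segments: int = 3
    rms_m_fcr: float | None = None
    rms_m_ecrl: float | None = None
    # heart-rate reporting
    hr_window_s: float = 30.0
    # paths
    ecg_csv: str | None = None
    emg_csv: str | None = None
    out_dir: str = "results"

    def __post_init__(self):
        checks = [
            (self.ecg_cutoff_hz > 0, "ecg_cutoff_hz must be positive"),
            (self.baseline_window_ms > 0, "baseline_window_ms must be positive"),
            (self.k_mad > 0, "k_mad must be positive"),
            (self.min_rr_ms > 0, "min_rr_ms must be positive"),
            (self.hrv_k >= 2, "hrv_k must be >= 2"),
            (self.fatigue_epsilon_ms > 0, "fatigue_epsilon_ms must be positive"),
            (self.svm_smoothing >= 1, "svm_smoothing must be >= 1"),
            (self.segment_n >= 1, "segment_n must be >= 1"),
            (self.activity_threshold > 0, "activity_threshold must be positive"),
            (self.min_duration_segments >= 1, "min_duration_segments must be >= 1"),
            (self.hr_window_s > 0, "hr_window_s must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        for name in ("rms_m_fcr", "rms_m_ecrl"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigError(f"{name} must be positive when given")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset; handles both
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _heart_rate_series(rr, window_s: float) -> list[dict]:
    """Sliding-window heart rate: 60000 / mean R-R over the trailing window."""
    out = []
    t = rr.anchor_times
    for i in range(t.size):
        lo = np.searchsorted(t, t[i] - window_s * 1000.0)
        mean_rr = float(np.mean(rr.intervals[lo : i + 1]))
        out.append({"time_ms": float(t[i]), "hr_bpm": 60000.0 / mean_rr})
    return out


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, RehabSigError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            elif exc is None:
                log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full ECG + EMG processing chain and write artifacts.

    Requires ``config.ecg_csv`` and/or ``config.emg_csv``; at least one must
    be present. Returns the summary dict (also written to
    ``out_dir/summary.json`` with sorted keys, so identical inputs give
    byte-identical output).
    """
    if not config.ecg_csv and not config.emg_csv:
        raise ConfigError("no input files configured (need ecg_csv and/or emg_csv)")
    for p in (config.ecg_csv, config.emg_csv):
        if p and not Path(p).exists():
            raise ConfigError(f"input file does not exist: {p}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"config": config.to_dict()}

    if config.ecg_csv:
        with _stage("ecg-read"):
            sig = _io.read_signal_csv(config.ecg_csv)["ECG"]
            log.info("ecg: %d samples at %.1f Hz", len(sig), sig.fs)
        with _stage("ecg-condition"):
            cond = _ecg.condition(
                sig,
                cutoff=config.ecg_cutoff_hz,
                baseline_window_ms=config.baseline_window_ms,
                artifact_filter=config.artifact_filter,
                k_mad=config.k_mad,
            )
        with _stage("ecg-detect"):
            peaks = _ecg.detect_r_peaks(cond, min_rr_ms=config.min_rr_ms)
            _io.write_jsonl(out_dir / "r_peaks.jsonl", _io.peaks_to_records(peaks))
            log.info("ecg: %d R peaks", len(peaks))
        with _stage("hrv"):
            rr = _ecg.compute_rr(peaks)
            stats = _ecg.hrv_windows(rr, k=config.hrv_k)
            _io.write_jsonl(out_dir / "hrv.jsonl", _io.hrv_to_records(stats))
            hr = _heart_rate_series(rr, config.hr_window_s)
        with _stage("fatigue-rule"):
            params = _fatigue.FatigueRuleParams(k=config.hrv_k, epsilon_ms=config.fatigue_epsilon_ms)
            flag, first = _fatigue.rule_fatigue(stats, params)
            timeline = [
                {
                    "time_ms": s.anchor_time_ms,
                    "status": (
                        Status.FATIGUE if s.variation < params.epsilon_ms else Status.EXCITED
                    ).value,
                }
                for s in stats
            ]
            alerts = [
                timeline[i]["time_ms"]
                for i in range(len(timeline))
                if timeline[i]["status"] == "fatigue"
                and (i == 0 or timeline[i - 1]["status"] == "excited")
            ]
            _io.write_jsonl(out_dir / "status_timeline.jsonl", timeline)
        summary["ecg"] = {
            "n_samples": len(sig),
            "fs_hz": sig.fs,
            "n_r_peaks": len(peaks),
            "mean_hr_bpm": float(np.mean([h["hr_bpm"] for h in hr])) if hr else None,
            "fatigue_flag": bool(flag),
            "first_fatigue_window": first,
            "n_alerts": len(alerts),
            "alert_times_ms": alerts,
        }

    if config.emg_csv:
        with _stage("emg-read"):
            chans = _io.read_signal_csv(config.emg_csv, expected_channels=["FCR", "ECRL"])
        with _stage("emg-features"):
            series = {}
            for name in ("FCR", "ECRL"):
                feats = _emg.rms_segments(chans[name], n=config.segment_n)
                rms_m = config.rms_m_fcr if name == "FCR" else config.rms_m_ecrl
                if rms_m is None:
                    # Self-calibration: the session's own maximum segment RMS.
                    rms_m = float(feats.rms.max())
                cal = _emg.CalibrationRecord(channel=name, trial_rms=[rms_m], rms_m=rms_m)
                series[name] = _emg.normalize(feats, cal)
            records = [
                {
                    "channel": name,
                    "segment_start_ms": float(t),
                    "rms_V": float(r),
                    "rms_normalized": float(rn),
                }
                for name, s in series.items()
                for t, r, rn in zip(s.segment_start_ms, s.rms, s.rms_normalized)
            ]
            _io.write_jsonl(out_dir / "emg_features.jsonl", records)
        with _stage("emg-events"):
            events = _emg.detect_motion_events(
                series["FCR"],
                series["ECRL"],
                threshold=config.activity_threshold,
                min_duration_segments=config.min_duration_segments,
            )
            _io.write_jsonl(
                out_dir / "motion_events.jsonl",
                [
                    {
                        "onset_ms": e.onset_ms,
                        "offset_ms": e.offset_ms,
                        "motion_group": e.motion_group.value,
                        "dominant_channel": e.dominant_channel,
                        "peak_rms_n_fcr": e.peak_rms_n_fcr,
                        "peak_rms_n_ecrl": e.peak_rms_n_ecrl,
                        "possibly_saturated": e.possibly_saturated,
                    }
                    for e in events
                ],
            )
            log.info("emg: %d motion events", len(events))
        bout_means = {}
        for name, s in series.items():
            minutes = (s.segment_start_ms // 60000.0).astype(int)
            bout_means[name] = [
                float(s.rms[minutes == m].mean()) for m in range(int(minutes.max()) + 1)
            ]
        summary["emg"] = {
            "n_segments": {name: len(s) for name, s in series.items()},
            "bout_mean_rms_V": bout_means,
            "n_motion_events": len(events),
            "events_by_group": {
                g.value: sum(1 for e in events if e.motion_group is g)
                for g in set(e.motion_group for e in events)
            },
        }

    (out_dir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
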