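"""On-disk interchange formats.

CSV for sampled signals and session traces (one ``time_ms`` column plus one
``<name>_V`` column per channel), JSONL for event/feature/label streams,
JSON for models, calibrations and summaries. Readers validate uniform
sampling and report the 1-based line number of the first offending record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .types import Channel, HRVWindowStat, RPeakSeries, SampledSignal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "write_jsonl",
    "read_jsonl",
    "peaks_to_records",
    "hrv_to_records",
]

#: Maximum timestep jitter as a fraction of the nominal sampling period.
MAX_JITTER_FRAC = 0.01

_COLUMN_CHANNEL = {"value_v": None, "ecg_v": "ECG", "fcr_v": "FCR", "ecrl_v": "ECRL"}


def read_signal_csv(
    path, expected_channels: list[str] | None = None, default_channel: str = "ECG"
) -> dict[str, SampledSignal]:
    """Read one or more sampled-signal channels from a CSV file.

    The header must declare ``time_ms`` plus at least one value column
    (``value_V``, ``ecg_V``, ``fcr_V`` or ``ecrl_V``). Timestamps must be
    strictly increasing and uniform to within 1% of the nominal period; the
    sampling rate is inferred from the median timestep. Returns a mapping
    from channel label to :class:`SampledSignal`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - passthrough of pandas message
        raise FormatError(f"cannot parse {path}: {e}") from e
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_ms" not in cols:
        raise FormatError(f"{path}: missing required column time_ms")
    value_cols = [c for c in cols if c in _COLUMN_CHANNEL]
    if not value_cols:
        raise FormatError(
            f"{path}: no value column found (expected one of {sorted(_COLUMN_CHANNEL)})"
        )

    def numeric(col_key: str) -> np.ndarray:
        raw = df[cols[col_key]]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            # +2: one for the header row, one for 1-based numbering
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[bad[0]]!r} in column "
                f"{cols[col_key]}",
                line=int(bad[0]) + 2,
            )
        return vals

    t = numeric("time_ms")
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-increasing time_ms ({t[bad[0]]} -> {t[bad[0] + 1]})",
            line=int(bad[0]) + 3,
        )
    dt_med = float(np.median(dt))
    if np.any(np.abs(dt - dt_med) > MAX_JITTER_FRAC * dt_med):
        i = int(np.argmax(np.abs(dt - dt_med)))
        raise FormatError(
            f"{path}: non-uniform sampling (step {dt[i]:.6g} ms vs nominal {dt_med:.6g} ms)",
            line=i + 3,
        )
    fs = 1000.0 / dt_med

    out: dict[str, SampledSignal] = {}
    for key in value_cols:
        channel = _COLUMN_CHANNEL[key] or default_channel
        out[channel] = SampledSignal(numeric(key), fs=fs, t0=float(t[0]), channel=channel)
    if expected_channels is not None:
        missing = [c for c in expected_channels if Channel(c).value not in out]
        if missing:
            raise FormatError(f"{path}: missing expected channels {missing}")
    return out


def write_signal_csv(path, *signals: SampledSignal) -> None:
    """Write one or more channels sharing a clock to a signal CSV."""
    if not signals:
        raise FormatError("nothing to write")
    ref = signals[0]
    for s in signals[1:]:
        if len(s) != len(ref) or s.fs != ref.fs or s.t0 != ref.t0:
            raise FormatError("channels must share length, fs and t0")
    data = {"time_ms": ref.times_ms}
    for s in signals:
        name = "value_V" if len(signals) == 1 and s.channel == "ECG" else f"{s.channel.lower()}_V"
        data[name] = s.samples
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format="%.9g")


def write_jsonl(path, records) -> None:
    """One JSON object per line, keys sorted for reproducibility."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r, sort_keys=True) + "\n")


def read_jsonl(path) -> list[dict]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as e:
                raise FormatError(f"{path}: invalid JSON", line=i) from e
    return out


def peaks_to_records(peaks: RPeakSeries) -> list[dict]:
    return [
        {"time_ms": float(t), "index": int(i), "amplitude_V": float(a)}
        for t, i, a in zip(peaks.peak_times, peaks.peak_indices, peaks.peak_amplitudes)
    ]


def hrv_to_records(stats: list[HRVWindowStat]) -> list[dict]:
    return [
        {
            "anchor_time_ms": s.anchor_time_ms,
            "window_size": s.window_size,
            "start_index": s.start_index,
            "variation_ms": s.variation,
            "mean_rr_ms": s.mean_rr,
            "sdnn_ms": s.sdnn,
            "rmssd_ms": s.rmssd,
        }
        for s in stats
    ]
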