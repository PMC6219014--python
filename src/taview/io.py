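"""ECG record I/O and preprocessing.

Records round-trip through a simple delimited-text (CSV) dialect: header row,
first column time in seconds, one column per lead, amplitudes in mV.
Preprocessing removes powerline interference with a zero-phase IIR notch
(Q = 30) and baseline wander / slow electrode-motion drift with a zero-phase
4th-order Butterworth high-pass (default cutoff 0.5 Hz); zero-phase
(forward-backward) filtering preserves wave latencies.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, InvalidArgumentError
from .forward import ECGRecord

NOTCH_Q = 30.0
HIGHPASS_ORDER = 4
DEFAULT_BASELINE_CUTOFF_HZ = 0.5


def write_ecg(path: str | Path, record: ECGRecord) -> None:
    """Write the CSV dialect: time column + one column per lead."""
    df = pd.DataFrame(
        {"time_s": record.times, **{n: record.samples[i] for i, n in enumerate(record.lead_names)}}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_ecg(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read an ECG record; only the CSV dialect is supported.

    The first column must be a time axis (seconds) or a sample index; the
    sampling rate is inferred from it.  A header row is required.
    """
    path = Path(path)
    if format == "wfdb":
        raise FormatError(
            "WFDB input is not supported in this build; convert to the CSV dialect"
        )
    if format != "csv":
        raise FormatError(f"unknown ECG format {format!r}")
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path.name}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: need a time column plus at least one lead")
    if df.isna().any().any():
        raise FormatError(f"{path.name}: missing values (truncated or ragged rows)")
    first = df.columns[0]
    try:
        tcol = df[first].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: header row required; first column must be numeric") from exc
    if len(tcol) < 2:
        raise FormatError(f"{path.name}: need at least 2 samples")
    dt = np.diff(tcol)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise FormatError(f"{path.name}: time column is not uniformly increasing")
    # integer sample index counts in samples; a float axis counts in seconds
    fs = 1.0 / dt.mean() if not np.allclose(dt, 1.0) else 1.0
    leads = tuple(df.columns[1:])
    samples = df.iloc[:, 1:].to_numpy(dtype=float).T
    return ECGRecord(fs=float(fs), lead_names=leads, samples=samples)


def preprocess(
    record: ECGRecord,
    powerline_hz: float = 50.0,
    baseline_cutoff_hz: float = DEFAULT_BASELINE_CUTOFF_HZ,
) -> ECGRecord:
    """Zero-phase powerline notch + baseline-wander high-pass; length preserved."""
    if powerline_hz not in (50.0, 60.0, 50, 60):
        raise InvalidArgumentError("powerline_hz must be 50 or 60")
    if record.fs <= 2.0 * powerline_hz:
        raise InvalidArgumentError(
            f"fs={record.fs} Hz too low for a {powerline_hz} Hz notch"
        )
    b_notch, a_notch = signal.iirnotch(powerline_hz, NOTCH_Q, fs=record.fs)
    # second-order sections keep the near-DC high-pass numerically well
    # conditioned (the transfer-function form loses ~5 digits here)
    sos_hp = signal.butter(
        HIGHPASS_ORDER, baseline_cutoff_hz, btype="highpass", fs=record.fs, output="sos"
    )
    x = record.samples
    y = signal.filtfilt(b_notch, a_notch, x, axis=1)
    y = signal.sosfiltfilt(sos_hp, y, axis=1)
    return ECGRecord(
        fs=record.fs,
        lead_names=record.lead_names,
        samples=y,
        annotations=record.annotations,
    )
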