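"""Reading, writing and windowing of physiological records.

A record bundles a PPG waveform (typically 125 Hz) with an optional
reference respiration waveform on the same grid and a 1 Hz reference
respiratory-rate series.  Records are segmented into overlapping 32-s
analysis windows advanced by an 8-s stride (24 s overlap), each carrying
the median reference RR over its span as the training label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysioRecord",
    "AnalysisWindow",
    "read_record",
    "write_record",
    "segment_windows",
]


class RecordValidationError(ValueError):
    """Raised when a record file violates the format contract."""


@dataclass
class PhysioRecord:
    """One subject's synchronized PPG / respiration / reference-RR series.

    Parameters
    ----------
    subject_id : str
        Free-text identifier, carried through to windows and features.
    ppg : ndarray
        PPG waveform in arbitrary units, sampled at ``ppg_fs``.
    ppg_fs : float
        PPG sampling rate in Hz (125 for bedside-monitor data).
    rr_ref : ndarray
        Reference respiratory rate in breaths/min, sampled at ``rr_fs``.
    rr_fs : float
        Reference RR sampling rate in Hz (1 Hz for monitor annotations).
    resp : ndarray or None
        Optional reference respiration waveform on the PPG grid.
    """

    subject_id: str
    ppg: np.ndarray
    ppg_fs: float = 125.0
    rr_ref: np.ndarray = field(default_factory=lambda: np.empty(0))
    rr_fs: float = 1.0
    resp: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.rr_ref = np.asarray(self.rr_ref, dtype=float)
        if self.resp is not None:
            self.resp = np.asarray(self.resp, dtype=float)
            if self.resp.size != self.ppg.size:
                raise RecordValidationError(
                    f"resp length {self.resp.size} != ppg length {self.ppg.size}"
                )
        if self.ppg_fs <= 0 or self.rr_fs <= 0:
            raise RecordValidationError("sampling rates must be positive")

    @property
    def duration_s(self) -> float:
        return self.ppg.size / self.ppg_fs


@dataclass
class AnalysisWindow:
    """A 32-s PPG segment with provenance and its reference RR label."""

    subject_id: str
    start_s: float
    ppg_segment: np.ndarray
    fs: float
    rr_label: float

    def __post_init__(self) -> None:
        self.ppg_segment = np.asarray(self.ppg_segment, dtype=float)
        if self.rr_label is not None and not (
            math.isfinite(self.rr_label) and self.rr_label > 0
        ):
            raise RecordValidationError(
                f"rr_label must be finite and positive, got {self.rr_label}"
            )


def read_record(path, format: str = "csv") -> PhysioRecord:
    """Read a physiological record from disk.

    The CSV dialect has header ``t,ppg,resp,rr``; ``t`` is seconds, the
    ``rr`` column is populated only on whole-second rows, and ``resp``
    may be entirely empty.  ``format="wfdb"`` maps a WFDB record (the
    PhysioNet monitor format) onto the same type and requires the
    optional ``wfdb`` package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown record format: {format!r}")


def _read_csv_record(path: Path) -> PhysioRecord:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reported with file context
        raise RecordValidationError(f"cannot parse {path}: {exc}") from exc
    for col in ("t", "ppg"):
        if col not in df.columns:
            raise RecordValidationError(f"{path}: missing required column '{col}'")
    if "rr" not in df.columns:
        raise RecordValidationError(f"{path}: missing required column 'rr'")

    t = df["t"].to_numpy(dtype=float)
    ppg = df["ppg"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ppg)):
        bad = int(np.flatnonzero(~np.isfinite(ppg))[0])
        raise RecordValidationError(f"{path}: non-finite ppg value at row {bad}")
    if t.size < 2:
        raise RecordValidationError(f"{path}: need at least 2 samples")
    ppg_fs = 1.0 / float(np.median(np.diff(t)))

    rr_mask = df["rr"].notna().to_numpy()
    rr_ref = df.loc[rr_mask, "rr"].to_numpy(dtype=float)
    duration_s = ppg.size / ppg_fs
    if rr_ref.size == 0:
        raise RecordValidationError(f"{path}: rr column contains no values")
    rr_fs = rr_ref.size / duration_s

    resp = None
    if "resp" in df.columns and df["resp"].notna().all():
        resp = df["resp"].to_numpy(dtype=float)

    subject_id = path.stem
    record = PhysioRecord(
        subject_id=subject_id, ppg=ppg, ppg_fs=ppg_fs,
        rr_ref=rr_ref, rr_fs=rr_fs, resp=resp,
    )
    # declared grids must be consistent with the sample counts
    if abs(round(duration_s * rr_fs) - rr_ref.size) > 0:
        raise RecordValidationError(
            f"{path}: rr length {rr_ref.size} inconsistent with duration "
            f"{duration_s:.3f}s at {rr_fs:.3f} Hz"
        )
    return record


def _read_wfdb_record(path: Path) -> PhysioRecord:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "WFDB reading requires the optional 'wfdb' package "
            "(pip install wfdb); CSV records need no extra dependency"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    names = [n.upper() for n in rec.sig_name]  # pragma: no cover
    ppg = rec.p_signal[:, names.index("PLETH")]  # pragma: no cover
    resp = (
        rec.p_signal[:, names.index("RESP")] if "RESP" in names else None
    )  # pragma: no cover
    num = wfdb.rdrecord(str(path) + "n")  # pragma: no cover
    nnames = [n.upper() for n in num.sig_name]  # pragma: no cover
    rr = num.p_signal[:, nnames.index("RESP")]  # pragma: no cover
    return PhysioRecord(  # pragma: no cover
        subject_id=path.stem, ppg=ppg, ppg_fs=float(rec.fs),
        rr_ref=rr, rr_fs=float(num.fs), resp=resp,
    )


def write_record(record: PhysioRecord, path) -> None:
    """Write a record in the canonical CSV dialect (``t,ppg,resp,rr``)."""
    path = Path(path)
    n = record.ppg.size
    t = np.arange(n) / record.ppg_fs
    rr_col = np.full(n, np.nan)
    # reference RR values sit on their own (typically 1 Hz) grid
    rr_idx = np.round(
        np.arange(record.rr_ref.size) / record.rr_fs * record.ppg_fs
    ).astype(int)
    rr_idx = rr_idx[rr_idx < n]
    rr_col[rr_idx] = record.rr_ref[: rr_idx.size]
    df = pd.DataFrame(
        {
            "t": t,
            "ppg": record.ppg,
            "resp": record.resp if record.resp is not None else np.full(n, np.nan),
            "rr": rr_col,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def segment_windows(
    record: PhysioRecord,
    window_s: float = 32.0,
    stride_s: float = 8.0,
) -> list[AnalysisWindow]:
    """Cut a record into overlapping analysis windows.

    Windows are sample-aligned half-open intervals ``[k*stride, k*stride
    + window_s)`` for k = 0, 1, ...; a record shorter than one window
    yields an empty list.  Each window's label is the median of the
    reference RR samples falling inside its span; windows with no
    reference sample are skipped.
    """
    fs = record.ppg_fs
    win_n = int(round(window_s * fs))
    stride_n = int(round(stride_s * fs))
    if stride_n <= 0 or win_n <= 0:
        raise ValueError("window_s and stride_s must be positive")
    n = record.ppg.size
    if n < win_n:
        return []
    count = (n - win_n) // stride_n + 1
    windows: list[AnalysisWindow] = []
    rr_times = np.arange(record.rr_ref.size) / record.rr_fs
    for k in range(count):
        start = k * stride_n
        start_s = start / fs
        in_span = (rr_times >= start_s) & (rr_times < start_s + window_s)
        labels = record.rr_ref[in_span]
        labels = labels[np.isfinite(labels)]
        if labels.size == 0:
            continue
        windows.append(
            AnalysisWindow(
                subject_id=record.subject_id,
                start_s=start_s,
                ppg_segment=record.ppg[start : start + win_n],
                fs=fs,
                rr_label=float(np.median(labels)),
            )
        )
    return windows
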