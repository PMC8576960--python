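"""Reading and writing ECG sample series and RR-interval series.

The native on-disk format is a plain-text CSV dialect: one sample per line,
with ``#``-prefixed header lines carrying metadata (``# fs=128``,
``# subject_id=p01``, ``# label=PAF``).  This round-trips bit-exactly via
``repr`` of Python floats.  A minimal reader for WFDB-layout records
(``.hea`` header plus ``.dat`` signal, formats 16 and 212) is provided so
that PhysioNet-style 30-min single-lead records can be fed to the pipeline
directly; amplitudes are converted to mV using the header gain.

RR intervals are stored one interval (ms) per line with the same header
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InsufficientDataError, ParseError

__all__ = [
    "ECGRecord",
    "RRSeries",
    "read_ecg",
    "write_ecg",
    "read_rr",
    "write_rr",
    "rr_from_peaks",
]


@dataclass
class ECGRecord:
    """A single-lead ECG sample series.

    Parameters
    ----------
    samples : array of float
        Amplitudes in mV, in acquisition order.
    fs : float
        Sampling frequency in Hz (> 0).
    subject_id : str
        Identifier of the subject/record.
    label : str or None
        Optional class tag, ``"PAF"`` or ``"normal"``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise FormatError("ECGRecord requires a non-empty sample series")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("ECGRecord samples must all be finite")
        if not (self.fs > 0):
            raise FormatError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class RRSeries:
    """Ordered inter-beat (R-to-R) intervals.

    ``intervals`` are in milliseconds; ``beat_times`` are the beat instants in
    seconds (one more entry than intervals when derived from peaks).
    """

    intervals: np.ndarray
    beat_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size == 0:
            raise InsufficientDataError("RRSeries requires at least one interval")
        if not np.all(np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            raise FormatError("RR intervals must be finite and positive")
        if self.beat_times is None:
            # reconstruct beat instants assuming the first beat occurs at t=0
            self.beat_times = np.concatenate([[0.0], np.cumsum(self.intervals) / 1000.0])
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if np.any(np.diff(self.beat_times) <= 0):
                raise FormatError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return self.intervals.size


def rr_from_peaks(peaks, fs: float) -> RRSeries:
    """Convert R-peak sample indices to an RR-interval series.

    ``intervals[k] = (peaks[k+1] - peaks[k]) / fs * 1000`` (ms).

    Raises
    ------
    InsufficientDataError
        If fewer than two peaks are given.
    ValueError
        If the peaks are not strictly increasing or fs is not positive.
    """
    peaks = np.asarray(peaks, dtype=float)
    if not (fs > 0):
        raise ValueError(f"fs must be positive, got {fs}")
    if peaks.size < 2:
        raise InsufficientDataError("need at least 2 peaks to form an RR interval")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    intervals = np.diff(peaks) / fs * 1000.0
    beat_times = peaks / fs
    return RRSeries(intervals=intervals, beat_times=beat_times)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _parse_headers(lines):
    meta = {}
    body_start = 0
    for k, line in enumerate(lines):
        s = line.strip()
        if s.startswith("#"):
            body_start = k + 1
            kv = s.lstrip("#").strip()
            if "=" in kv:
                key, _, val = kv.partition("=")
                meta[key.strip()] = val.strip()
        elif s == "":
            body_start = k + 1
        else:
            break
    return meta, body_start


def _read_csv_ecg(path: str) -> ECGRecord:
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty file")
    meta, start = _parse_headers(lines)
    if "fs" not in meta:
        raise FormatError(f"{path}: missing 'fs' header line (expected '# fs=<Hz>')")
    try:
        fs = float(meta["fs"])
    except ValueError as e:
        raise FormatError(f"{path}: invalid sampling rate {meta['fs']!r}") from e
    try:
        samples = np.array(
            [float(line) for line in lines[start:] if line.strip()], dtype=float
        )
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric sample value") from e
    if samples.size == 0:
        raise ParseError(f"{path}: no samples after header")
    return ECGRecord(
        samples=samples,
        fs=fs,
        subject_id=meta.get("subject_id", os.path.splitext(os.path.basename(path))[0]),
        label=meta.get("label") or None,
    )


def write_ecg(record: ECGRecord, path: str) -> None:
    """Write an ECGRecord in the CSV dialect (bit-exact round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={float(record.fs)!r}\n")
        fh.write(f"# subject_id={record.subject_id}\n")
        if record.label is not None:
            fh.write(f"# label={record.label}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Minimal WFDB-layout reader (header + signal file, formats 16 and 212)
# ---------------------------------------------------------------------------

def _read_wfdb_ecg(path: str, channel: int | str = 0) -> ECGRecord:
    """Read a WFDB header/signal pair.

    ``path`` may point at the ``.hea`` file or be the record path without
    extension.  Supports single-segment records with all channels in one
    signal file, formats 16 (little-endian int16) and 212 (packed 12-bit).
    Amplitudes are converted to mV as (adc - baseline) / gain.
    """
    if path.endswith(".hea"):
        hea_path = path
        base = path[:-4]
    else:
        base = path
        hea_path = path + ".hea"
    if not os.path.exists(hea_path):
        raise FormatError(f"missing WFDB header file {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"{hea_path}: malformed record line")
    record_name = head[0]
    n_sig = int(head[1])
    try:
        fs = float(head[2].split("/")[0])
    except ValueError as e:
        raise FormatError(f"{hea_path}: invalid sampling rate field {head[2]!r}") from e
    n_samples = int(head[3]) if len(head) > 3 else None

    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"{hea_path}: expected {n_sig} signal spec lines")
    specs = []
    for ln in sig_lines:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        gain = 200.0
        baseline = 0
        if len(parts) > 2:
            gain_field = parts[2]
            # gain may look like "200", "200(0)", "200(0)/mV"
            gain_field = gain_field.split("/")[0]
            if "(" in gain_field:
                gain_s, base_s = gain_field.rstrip(")").split("(")
                gain = float(gain_s)
                baseline = int(float(base_s))
            else:
                gain = float(gain_field)
            if gain == 0:
                gain = 200.0
        desc = parts[8] if len(parts) > 8 else f"ch{len(specs)}"
        specs.append({"file": fname, "fmt": fmt, "gain": gain,
                      "baseline": baseline, "desc": " ".join(parts[8:]) or desc})

    if isinstance(channel, str):
        names = [s["desc"] for s in specs]
        matches = [k for k, nm in enumerate(names) if channel.lower() in nm.lower()]
        if not matches:
            raise FormatError(f"channel {channel!r} not found among {names}")
        ch = matches[0]
    else:
        ch = int(channel)
        if not (0 <= ch < n_sig):
            raise FormatError(f"channel index {ch} out of range for {n_sig} signals")

    sig_file = os.path.join(os.path.dirname(base) or ".", specs[ch]["file"])
    if len({s["file"] for s in specs}) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    fmt = specs[ch]["fmt"]
    raw = np.fromfile(sig_file, dtype=np.uint8)
    if fmt == "16":
        adc = raw.view("<i2").astype(np.int32)
        adc = adc.reshape(-1, n_sig)
    elif fmt == "212":
        # 3 bytes encode 2 samples of 12 bits each
        usable = (raw.size // 3) * 3
        b = raw[:usable].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        adc = np.empty(b.shape[0] * 2, dtype=np.int32)
        adc[0::2] = s0
        adc[1::2] = s1
        adc = adc[: (adc.size // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt!r}")
    if n_samples is not None:
        adc = adc[:n_samples]
    samples_mv = (adc[:, ch] - specs[ch]["baseline"]) / specs[ch]["gain"]
    return ECGRecord(samples=samples_mv, fs=fs, subject_id=record_name)


def read_ecg(path: str, format: str = "csv", channel: int | str = 0) -> ECGRecord:
    """Read an ECG record from disk.

    Parameters
    ----------
    path : str
        File path (CSV) or record path / ``.hea`` path (WFDB layout).
    format : {"csv", "wfdb"}
        On-disk layout.
    channel : int or str
        WFDB only: channel index or a substring of the signal description
        (e.g. ``"II"`` for lead II).
    """
    if format == "csv":
        return _read_csv_ecg(path)
    if format in ("wfdb", "wfdb-layout"):
        return _read_wfdb_ecg(path, channel=channel)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


# ---------------------------------------------------------------------------
# RR-series text format
# ---------------------------------------------------------------------------

def write_rr(rr: RRSeries, path: str) -> None:
    """Write an RR series, one interval (ms) per line."""
    with open(path, "w") as fh:
        fh.write("# units=ms\n")
        for v in rr.intervals:
            fh.write(f"{float(v)!r}\n")


def read_rr(path: str) -> RRSeries:
    """Read an RR series written by :func:`write_rr` (or any one-per-line file)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty file")
    _, start = _parse_headers(lines)
    try:
        intervals = np.array(
            [float(line) for line in lines[start:] if line.strip()], dtype=float
        )
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric interval") from e
    if intervals.size == 0:
        raise ParseError(f"{path}: no intervals after header")
    return RRSeries(intervals=intervals)
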