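"""R-peak detection and P-wave delineation.

The QRS detector is a derivative–square–moving-window-integration scheme in
the Pan–Tompkins tradition: bandpass the signal around the QRS energy band
(5–15 Hz), differentiate, square, integrate over a 150 ms window, pick peaks
of the integrated energy with a 200 ms refractory period, and refine each to
the nearest local maximum of the raw signal.

P-waves are delineated in a fixed window before each R-peak ([250, 60] ms by
default).  The baseline is the median of the first 20 ms of the window; the
P-peak is the window maximum above baseline; onset and offset are the 5 %
threshold crossings of the local P amplitude on each side of the peak.
Beats whose window leaves the record, whose P amplitude is negligible, or
whose onset/offset cannot be found are dropped rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord
from .errors import DelineationError, DetectionError, InsufficientDataError

__all__ = [
    "FiducialSet",
    "PWaveBasic",
    "detect_r_peaks",
    "delineate_p_wave",
    "pwave_basic_features",
    "p_wave_segments",
]

#: Minimum raw-signal amplitude (mV) above baseline for a P-peak to count.
MIN_P_AMPLITUDE = 0.02

#: Fraction of the local P amplitude defining onset/offset crossings.
ONSET_THRESHOLD = 0.05

#: Beats closer than this (ms) to either record boundary are discarded.
BOUNDARY_GUARD_MS = 300.0


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices (parallel arrays, retained beats only)."""

    r_peaks: np.ndarray
    p_onset: np.ndarray
    p_peak: np.ndarray
    p_offset: np.ndarray
    baseline: np.ndarray  # baseline amplitude (mV) used for each beat

    def __post_init__(self):
        for name in ("r_peaks", "p_onset", "p_peak", "p_offset"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.baseline = np.asarray(self.baseline, dtype=float)
        ok = (self.p_onset < self.p_peak) & (self.p_peak < self.p_offset) & (
            self.p_offset < self.r_peaks
        )
        if self.r_peaks.size and not np.all(ok):
            raise ValueError("fiducial ordering violated: need onset < peak < offset < R")

    def __len__(self) -> int:
        return self.r_peaks.size

    def to_table(self) -> np.ndarray:
        """(n_beats, 5) integer-ish table: beat, onset, peak, offset, R."""
        return np.column_stack(
            [np.arange(len(self)), self.p_onset, self.p_peak, self.p_offset, self.r_peaks]
        )


@dataclass
class PWaveBasic:
    """Subject-level direct P-wave morphology parameters.

    PW: wave width (ms); PA: peak amplitude above baseline (mV);
    PD: onset-to-peak time (ms).  Subject value = median across beats.
    """

    PW: float
    PA: float
    PD: float

    def __post_init__(self):
        if not (self.PW > 0 and self.PD > 0):
            raise ValueError("PW and PD must be positive")
        if self.PD > self.PW + 1e-9:
            raise ValueError("PD cannot exceed PW (peak lies inside the wave)")


def detect_r_peaks(record: ECGRecord, refractory_ms: float = 200.0) -> np.ndarray:
    """Detect R-peak sample indices.

    Raises
    ------
    InsufficientDataError
        If the record is shorter than 10 s.
    DetectionError
        If no peaks are found (e.g. a flat signal).
    """
    if record.duration_s < 10.0:
        raise InsufficientDataError("R-peak detection requires at least 10 s of signal")
    x = record.samples
    fs = record.fs
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.95 * nyq) / nyq], btype="band")
    filt = sps.filtfilt(b, a, x)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    peak_level = np.percentile(integ, 99)
    if peak_level <= 0 or not np.isfinite(peak_level):
        raise DetectionError("no QRS energy found (flat or degenerate signal)")
    height = 0.3 * peak_level
    distance = max(1, int(round(refractory_ms / 1000.0 * fs)))
    locs, _ = sps.find_peaks(integ, height=height, distance=distance)
    if locs.size == 0:
        raise DetectionError("no R-peaks detected")

    # refine to the raw-signal local maximum near each energy peak
    half = int(round(0.075 * fs))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(np.asarray(refined, dtype=int))

    # enforce refractory after refinement and implied HR in [20, 300] bpm
    min_gap = int(round(refractory_ms / 1000.0 * fs))
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= min_gap:
            kept.append(int(p))
        elif x[p] > x[kept[-1]]:
            kept[-1] = int(p)
    peaks = np.asarray(kept, dtype=int)
    if peaks.size >= 2:
        rr_s = np.diff(peaks) / fs
        hr = 60.0 / rr_s
        # drop peaks implying impossible rates (spurious double detections)
        good = np.concatenate([[True], (hr >= 20) & (hr <= 300)])
        peaks = peaks[good]
    if peaks.size == 0:
        raise DetectionError("no R-peaks detected after rate filtering")
    return peaks


def _p_window(record: ECGRecord, r: int, search_window_ms=(250.0, 60.0)):
    """Sample bounds (start, stop) of the pre-R search window, or None."""
    fs = record.fs
    start = r - int(round(search_window_ms[0] / 1000.0 * fs))
    stop = r - int(round(search_window_ms[1] / 1000.0 * fs))
    guard = int(round(BOUNDARY_GUARD_MS / 1000.0 * fs))
    if start < guard or stop <= start or r > record.samples.size - guard:
        return None
    return start, stop


def delineate_p_wave(
    record: ECGRecord,
    r_peaks: np.ndarray,
    search_window_ms: tuple[float, float] = (250.0, 60.0),
    min_p_amplitude: float = MIN_P_AMPLITUDE,
) -> FiducialSet:
    """Locate P onset/peak/offset before each R-peak.

    Beats failing any delineation step are dropped; raises
    :class:`DelineationError` only if every beat fails.
    """
    fs = record.fs
    x = record.samples
    base_len = max(1, int(round(0.020 * fs)))  # first 20 ms of the window
    rs, onsets, peaks_, offsets, bases = [], [], [], [], []
    for r in np.asarray(r_peaks, dtype=int):
        w = _p_window(record, r, search_window_ms)
        if w is None:
            continue
        start, stop = w
        seg = x[start:stop]
        baseline = float(np.median(seg[:base_len]))
        sub = seg - baseline
        pk = int(np.argmax(sub))
        amp = sub[pk]
        if amp < min_p_amplitude:
            continue
        thr = ONSET_THRESHOLD * amp
        below_before = np.nonzero(sub[:pk] <= thr)[0]
        below_after = np.nonzero(sub[pk + 1 :] <= thr)[0]
        if below_before.size == 0 or below_after.size == 0:
            continue  # wave truncated by the window
        onset = int(below_before[-1])
        offset = pk + 1 + int(below_after[0])
        if not (onset < pk < offset):
            continue
        rs.append(int(r))
        onsets.append(start + onset)
        peaks_.append(start + pk)
        offsets.append(start + offset)
        bases.append(baseline)
    if not rs:
        raise DelineationError("P-wave delineation failed on every beat")
    return FiducialSet(
        r_peaks=np.array(rs),
        p_onset=np.array(onsets),
        p_peak=np.array(peaks_),
        p_offset=np.array(offsets),
        baseline=np.array(bases),
    )


def pwave_basic_features(record: ECGRecord, fiducials: FiducialSet) -> PWaveBasic:
    """PW / PA / PD, aggregated as the median across retained beats."""
    if len(fiducials) == 0:
        raise InsufficientDataError("empty fiducial set")
    fs = record.fs
    pw = (fiducials.p_offset - fiducials.p_onset) / fs * 1000.0
    pd_ = (fiducials.p_peak - fiducials.p_onset) / fs * 1000.0
    pa = record.samples[fiducials.p_peak] - fiducials.baseline
    return PWaveBasic(
        PW=float(np.median(pw)), PA=float(np.median(pa)), PD=float(np.median(pd_))
    )


def p_wave_segments(record: ECGRecord, fiducials: FiducialSet) -> list[np.ndarray]:
    """Baseline-subtracted P-wave segments (onset..offset inclusive), per beat."""
    segs = []
    for on, off, base in zip(fiducials.p_onset, fiducials.p_offset, fiducials.baseline):
        segs.append(record.samples[on : off + 1] - base)
    return segs
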