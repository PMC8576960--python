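"""Time-domain heart-rate-variability parameters.

Eleven statistics of the RR-interval series: mean RR, SDNN, mean/SD of the
instantaneous heart rate, per-minute min/max heart rate, RMSSD, NN50 and
pNN50, and the two geometric measures from the RR histogram (HRV triangular
index and TINN).  Sample (n-1) variance convention throughout.

The RR histogram uses a fixed bin width of 1/128 s = 7.8125 ms by default,
the sampling resolution of 128 Hz recordings and the conventional choice in
HRV toolkits.  TINN is found by exhaustive search over triangle base
endpoints (N, M) on the bin-centre grid, minimising the squared error of the
triangular interpolation against the histogram; ties prefer the narrower
base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import RRSeries
from .errors import InsufficientDataError

__all__ = ["TimeDomainFeatures", "time_domain_features"]

DEFAULT_BIN_WIDTH_MS = 1000.0 / 128.0  # 7.8125 ms


@dataclass
class TimeDomainFeatures:
    RRmean: float      # ms
    SDNN: float        # ms
    HRmean: float      # 1/min
    SDHR: float        # 1/min
    MinHR: float       # beats/min (per-minute window minimum)
    MaxHR: float       # beats/min (per-minute window maximum)
    RMSSD: float       # ms
    NN50: int          # count
    pNN50: float       # %
    HRVTriangularIndex: float
    TINN: float        # ms


def _histogram(intervals: np.ndarray, bin_width: float):
    lo = np.floor(intervals.min() / bin_width) * bin_width
    hi = np.ceil(intervals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(intervals, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def _tinn(counts: np.ndarray, centers: np.ndarray, bin_width: float) -> float:
    """Baseline width of the best-fit triangular interpolation (ms)."""
    if np.count_nonzero(counts) <= 1:
        return 0.0
    x_idx = int(np.argmax(counts))  # histogram mode (first max on ties)
    y = counts[x_idx]
    xs = centers
    best_err = np.inf
    best_width = np.inf
    # candidate bases one bin beyond the occupied range, so q can reach zero
    n_candidates = [i for i in range(0, x_idx + 1)]
    m_candidates = [j for j in range(x_idx, len(xs))]
    for ni in n_candidates:
        xn = xs[ni] - bin_width
        for mj in m_candidates:
            xm = xs[mj] + bin_width
            q = np.zeros_like(counts)
            left = (xs > xn) & (xs <= xs[x_idx])
            right = (xs > xs[x_idx]) & (xs < xm)
            q[left] = y * (xs[left] - xn) / (xs[x_idx] - xn)
            q[right] = y * (xm - xs[right]) / (xm - xs[x_idx])
            err = float(np.sum((counts - q) ** 2))
            width = xm - xn
            if err < best_err - 1e-12 or (abs(err - best_err) <= 1e-12 and width < best_width):
                best_err = err
                best_width = width
    return float(best_width)


def time_domain_features(
    rr: RRSeries,
    pnn50_denominator: str = "pairs",
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
) -> TimeDomainFeatures:
    """Compute the eleven time-domain parameters of an RR series.

    Parameters
    ----------
    rr : RRSeries
    pnn50_denominator : {"pairs", "intervals"}
        Denominator convention for pNN50: number of successive-difference
        pairs (n-1, toolkit convention, default) or number of intervals (n).
    bin_width_ms : float
        RR histogram bin width for the geometric measures.
    """
    x = rr.intervals
    n = x.size
    if n < 2:
        raise InsufficientDataError("time-domain HRV needs at least 2 RR intervals")
    if pnn50_denominator not in ("pairs", "intervals"):
        raise ValueError("pnn50_denominator must be 'pairs' or 'intervals'")

    rr_mean = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    hr = 60000.0 / x
    hr_mean = float(np.mean(hr))
    sdhr = float(np.std(hr, ddof=1))

    # per-minute windowed min/max heart rate (interval assigned by start time)
    t0 = rr.beat_times[0]
    starts = rr.beat_times[:-1] - t0
    total = rr.beat_times[-1] - t0
    if total < 60.0:
        min_hr, max_hr = float(np.min(hr)), float(np.max(hr))
    else:
        win = np.floor(starts / 60.0).astype(int)
        means = [float(np.mean(hr[win == w])) for w in np.unique(win) if np.any(win == w)]
        min_hr, max_hr = float(np.min(means)), float(np.max(means))

    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    denom = d.size if pnn50_denominator == "pairs" else n
    pnn50 = 100.0 * nn50 / denom

    counts, centers = _histogram(x, bin_width_ms)
    tri = float(n / counts.max())
    tinn = _tinn(counts, centers, bin_width_ms)

    return TimeDomainFeatures(
        RRmean=rr_mean,
        SDNN=sdnn,
        HRmean=hr_mean,
        SDHR=sdhr,
        MinHR=min_hr,
        MaxHR=max_hr,
        RMSSD=rmssd,
        NN50=nn50,
        pNN50=pnn50,
        HRVTriangularIndex=tri,
        TINN=tinn,
    )
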