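"""Nonlinear heart-rate-variability parameters.

Poincaré plot dispersions SD1/SD2 and their ratio, approximate and sample
entropy, and the two detrended-fluctuation-analysis scaling exponents.

* SD1/SD2 follow the rotated-axes definition: for consecutive pairs
  (RRn, RRn+1), SD1 = sd((RRn - RRn+1)/sqrt(2)) and
  SD2 = sd((RRn + RRn+1)/sqrt(2)), sample (n-1) convention.
* ApEn is the Pincus definition (self-matches included, Chebyshev distance):
  ApEn = Phi_m(r) - Phi_{m+1}(r) with Phi the mean log match frequency.
* SampEn is the Richman–Moorman definition (self-matches excluded):
  SampEn = -log(A/B) with A, B the m+1- and m-length template match counts;
  undefined (NaN) when either count is zero — except the exactly constant
  series, where A = B and the entropy is 0.
* DFA integrates the mean-centred series, removes a least-squares line from
  each non-overlapping box of size n, and fits log F(n) vs log n separately
  over the short-range (4–16 beats) and long-range (16–64 beats) box sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import RRSeries
from .errors import InsufficientDataError

__all__ = [
    "NonlinearFeatures",
    "poincare_sd",
    "apen",
    "sampen",
    "dfa",
    "nonlinear_features",
]

DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.2
DFA_SHORT_RANGE = tuple(range(4, 17))
DFA_LONG_RANGE = tuple(range(16, 65))


@dataclass
class NonlinearFeatures:
    SD1: float      # ms
    SD2: float      # ms
    SD2_SD1: float  # ratio (NaN if SD1 == 0)
    ApEn: float
    SampEn: float
    alpha1: float
    alpha2: float


def poincare_sd(rr: RRSeries) -> tuple[float, float, float]:
    """Poincaré SD1, SD2 and SD2/SD1 from consecutive RR pairs."""
    x = rr.intervals
    if x.size < 3:
        raise InsufficientDataError("Poincaré analysis needs at least 3 intervals")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((a - b) / np.sqrt(2.0), ddof=1))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=1))
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return sd1, sd2, ratio


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """(n-m+1, m) matrix of m-length templates."""
    n = x.size
    return np.lib.stride_tricks.sliding_window_view(x, m) if n >= m else np.empty((0, m))


def _chebyshev_dists(templates: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distance matrix between template rows."""
    d = np.abs(templates[:, None, 0] - templates[None, :, 0])
    for k in range(1, templates.shape[1]):
        np.maximum(d, np.abs(templates[:, None, k] - templates[None, :, k]), out=d)
    return d


def apen(series, m: int = DEFAULT_M, r: float | None = None) -> float:
    """Approximate entropy (self-matches included)."""
    x = np.asarray(series, dtype=float)
    if r is None:
        r = DEFAULT_R_FACTOR * np.std(x, ddof=1)
    if not (r > 0):
        raise ValueError(f"tolerance r must be positive, got {r}")
    if x.size < m + 2:
        raise InsufficientDataError(f"ApEn needs at least m+2={m+2} points")

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        d = _chebyshev_dists(t)
        c = np.mean(d <= r, axis=1)  # self-match included
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(series, m: int = DEFAULT_M, r: float | None = None) -> float:
    """Sample entropy (self-matches excluded); NaN when undefined."""
    x = np.asarray(series, dtype=float)
    if r is None:
        r = DEFAULT_R_FACTOR * np.std(x, ddof=1)
        if r == 0:  # constant series: all templates match, entropy 0
            return 0.0
    if not (r > 0):
        raise ValueError(f"tolerance r must be positive, got {r}")
    if x.size < m + 2:
        raise InsufficientDataError(f"SampEn needs at least m+2={m+2} points")
    # use the same number of templates (n-m) for both lengths, the
    # Richman–Moorman convention
    n_t = x.size - m
    tm = _embed(x, m)[:n_t]
    tm1 = _embed(x, m + 1)
    dm = _chebyshev_dists(tm)
    dm1 = _chebyshev_dists(tm1)
    iu = np.triu_indices(n_t, k=1)
    b = int(np.sum(dm[iu] <= r))
    iu1 = np.triu_indices(tm1.shape[0], k=1)
    a = int(np.sum(dm1[iu1] <= r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def dfa(
    series,
    short_range=DFA_SHORT_RANGE,
    long_range=DFA_LONG_RANGE,
) -> tuple[float, float]:
    """Short- and long-range DFA scaling exponents (alpha1, alpha2)."""
    x = np.asarray(series, dtype=float)
    box_sizes = sorted(set(short_range) | set(long_range))
    if x.size < 4 * max(box_sizes):
        raise InsufficientDataError(
            f"DFA needs at least 4x the largest box size ({4 * max(box_sizes)} points)"
        )
    y = np.cumsum(x - np.mean(x))

    fluct = {}
    for n in box_sizes:
        n_boxes = y.size // n
        z = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n, dtype=float)
        t_mean = t.mean()
        t_c = t - t_mean
        denom = np.sum(t_c**2)
        slope = (z @ t_c) / denom
        intercept = z.mean(axis=1) - slope * t_mean
        resid = z - (slope[:, None] * t[None, :] + intercept[:, None])
        fluct[n] = float(np.sqrt(np.mean(resid**2)))

    def fit_alpha(ns):
        ns = np.asarray(sorted(set(ns)), dtype=float)
        fs = np.array([fluct[int(n)] for n in ns])
        good = fs > 0
        if np.sum(good) < 2:
            return float("nan")
        return float(np.polyfit(np.log(ns[good]), np.log(fs[good]), 1)[0])

    return fit_alpha(short_range), fit_alpha(long_range)


def nonlinear_features(
    rr: RRSeries,
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
    short_range=DFA_SHORT_RANGE,
    long_range=DFA_LONG_RANGE,
) -> NonlinearFeatures:
    """All seven nonlinear parameters of an RR series.

    The entropy tolerance is ``r = r_factor * SDNN`` of the analysed series.
    """
    x = rr.intervals
    sd1, sd2, ratio = poincare_sd(rr)
    sd = float(np.std(x, ddof=1))
    if sd > 0:
        r = r_factor * sd
        ap = apen(x, m=m, r=r)
        se = sampen(x, m=m, r=r)
    else:
        ap, se = 0.0, 0.0
    a1, a2 = dfa(x, short_range=short_range, long_range=long_range)
    return NonlinearFeatures(
        SD1=sd1, SD2=sd2, SD2_SD1=ratio, ApEn=ap, SampEn=se, alpha1=a1, alpha2=a2
    )
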