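"""Frequency-domain heart-rate-variability parameters.

The irregularly sampled RR series is converted to a uniform tachogram by
cubic-spline interpolation (4 Hz default), mean-removed, and its power
spectral density estimated by Welch's averaged periodogram (Hann window,
256-sample segments, 50 % overlap) and, alternatively, by an autoregressive
model (Burg, order 16).  Band powers are obtained by trapezoidal integration
over the standard short-term bands VLF 0–0.04 Hz, LF 0.04–0.15 Hz and
HF 0.15–0.4 Hz.  Total power TP is the power over [0, 0.4] Hz (= VLF+LF+HF),
so the normalised powers nLF = LF/(TP−VLF) and nHF = HF/(TP−VLF) sum to one.
An LF/HF ratio with zero HF power is reported as missing (NaN), never as
infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

from .ecg_io import RRSeries
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "SpectralEstimate",
    "FreqDomainFeatures",
    "resample_rr",
    "welch_psd",
    "ar_psd",
    "band_powers",
    "freq_domain_features",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
DEFAULT_RESAMPLE_FS = 4.0
DEFAULT_WELCH_NPERSEG = 256
DEFAULT_AR_ORDER = 16


@dataclass
class SpectralEstimate:
    freqs: np.ndarray  # Hz, ascending, nonnegative
    psd: np.ndarray    # ms^2 / Hz, nonnegative
    method: str        # "welch" or "ar"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs < 0):
            raise ValueError("frequency grid must be nonnegative and ascending")
        # clip tiny negative values from numerical noise
        self.psd = np.maximum(self.psd, 0.0)


@dataclass
class FreqDomainFeatures:
    VLFpower: float  # ms^2
    LFpower: float   # ms^2
    HFpower: float   # ms^2
    LF_HF: float     # ratio (NaN if HF power is zero)
    TP: float        # ms^2
    nLF: float
    nHF: float


def resample_rr(rr: RRSeries, target_fs: float = DEFAULT_RESAMPLE_FS):
    """Cubic-spline resampling of the RR tachogram onto a uniform grid.

    The interval value is anchored at the time of the beat that terminates
    it.  Returns ``(times, values)``; no extrapolation beyond the anchored
    range.
    """
    if len(rr) < 4:
        raise InsufficientDataError("cubic-spline resampling needs at least 4 intervals")
    t = rr.beat_times[1:]
    cs = CubicSpline(t, rr.intervals)
    n_out = math.floor((t[-1] - t[0]) * target_fs) + 1
    grid = t[0] + np.arange(n_out) / target_fs
    return grid, cs(grid)


def welch_psd(
    tachogram: np.ndarray,
    fs: float,
    nperseg: int = DEFAULT_WELCH_NPERSEG,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Welch PSD of the (mean-removed) tachogram in ms^2/Hz."""
    x = np.asarray(tachogram, dtype=float)
    if x.size < 8:
        raise InsufficientDataError("tachogram too short for Welch estimation")
    nper = int(min(nperseg, x.size))
    x = x - np.mean(x)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=int(nper * overlap),
        detrend="constant",
    )
    return SpectralEstimate(freqs=freqs, psd=psd, method="welch")


def ar_psd(
    tachogram: np.ndarray,
    fs: float,
    order: int = DEFAULT_AR_ORDER,
    n_freqs: int = 1024,
) -> SpectralEstimate:
    """Autoregressive (Burg) PSD of the mean-removed tachogram.

    One-sided density: P(f) = 2*sigma2 / (fs * |1 - sum a_k e^{-j2πfk/fs}|^2).
    """
    x = np.asarray(tachogram, dtype=float)
    if order >= x.size:
        raise ConfigurationError(f"AR order {order} requires more than {order} samples")
    x = x - np.mean(x)
    rho, sigma2 = burg(x, order=order)
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    a = np.concatenate([[1.0], -rho])
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(order + 1)) / fs)
    denom = np.abs(z @ a) ** 2
    psd = 2.0 * sigma2 / (fs * denom)
    return SpectralEstimate(freqs=freqs, psd=psd, method="ar")


def _band_power(freqs, psd, lo, hi):
    """Trapezoidal band power with interpolated band-edge points."""
    grid = freqs
    inside = (grid > lo) & (grid < hi)
    f = np.concatenate([[lo], grid[inside], [hi]])
    p = np.interp(f, grid, psd)
    return float(np.trapezoid(p, f))


def band_powers(spec: SpectralEstimate) -> FreqDomainFeatures:
    """Integrate a spectral estimate into the Table-standard band powers."""
    if spec.freqs[-1] < HF_BAND[1]:
        raise ValueError(
            f"spectral grid must reach {HF_BAND[1]} Hz, got {spec.freqs[-1]:.3f}"
        )
    vlf = _band_power(spec.freqs, spec.psd, *VLF_BAND)
    lf = _band_power(spec.freqs, spec.psd, *LF_BAND)
    hf = _band_power(spec.freqs, spec.psd, *HF_BAND)
    tp = vlf + lf + hf
    lf_hf = lf / hf if hf > 0 else float("nan")
    denom = tp - vlf
    nlf = lf / denom if denom > 0 else float("nan")
    nhf = hf / denom if denom > 0 else float("nan")
    return FreqDomainFeatures(
        VLFpower=vlf, LFpower=lf, HFpower=hf, LF_HF=lf_hf, TP=tp, nLF=nlf, nHF=nhf
    )


def freq_domain_features(
    rr: RRSeries,
    estimator: str = "welch",
    resample_fs: float = DEFAULT_RESAMPLE_FS,
    welch_nperseg: int = DEFAULT_WELCH_NPERSEG,
    welch_overlap: float = 0.5,
    ar_order: int = DEFAULT_AR_ORDER,
) -> FreqDomainFeatures:
    """Resample the RR series and reduce its spectrum to the 7 band features."""
    _, tach = resample_rr(rr, target_fs=resample_fs)
    if estimator == "welch":
        spec = welch_psd(tach, resample_fs, nperseg=welch_nperseg, overlap=welch_overlap)
    elif estimator == "ar":
        spec = ar_psd(tach, resample_fs, order=ar_order)
    else:
        raise ConfigurationError(f"unknown spectral estimator {estimator!r}")
    return band_powers(spec)
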