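"""Seeded synthetic single-lead ECG generator with ground truth.

Emulates the acquisition regime of the screening study this package targets:
single-lead (lead II semantics), 128 Hz, 30-minute records, two labelled
cohorts of 50 subjects each ("normal" and "PAF"), none containing an AF
episode.  Each record is a concatenation of beats; within a beat the P-wave
is rendered *exactly* as a Gaussian bump (so the Gaussian-fitting stage has
analytic ground truth), the QRS as a tall narrow positive peak flanked by
small negative Q/S lobes, and the T-wave as a wide low Gaussian.

RR-interval structure is controllable per class:

    RR[k] = mean_RR + LF sinusoid (0.1 Hz) + HF sinusoid (0.25 Hz)
            + AR(1) noise,

with an optional "shuffle fraction" that randomly permutes that fraction of
the AR-noise values, destroying serial correlation (raising entropy, pushing
DFA toward white-noise scaling) without changing the amplitude distribution.

Class effect sizes below are the package's frozen study conditions: the PAF
class has wider and lower-amplitude P-waves, shorter mean RR, an LF-shifted
spectral balance, larger erratic beat-to-beat variability and a shuffled
(more irregular) noise component — a stylised rendering of the atrial
substrate and autonomic signatures reported in the PAF-screening literature.
Changing them is a breaking change to the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_io import ECGRecord, RRSeries
from .errors import ParameterError

__all__ = [
    "BeatParams",
    "ClassParams",
    "CohortSpec",
    "SyntheticRecord",
    "synth_beat",
    "synth_rr_series",
    "synth_record",
    "synth_cohort",
    "DEFAULT_NORMAL",
    "DEFAULT_PAF",
    "null_class_params",
]

#: R-peak offset from the start of each beat (s); P and T placed around it.
R_OFFSET_S = 0.30
#: P-wave centre precedes the R-peak by this much (s) — inside the
#: delineation search window of (250, 60) ms before R.
P_LEAD_S = 0.16
#: T-wave centre follows the R-peak by this much (s).
T_LAG_S = 0.30

QRS_SIGMA_S = 0.012
QRS_AMP_MV = 1.0
Q_S_AMP_MV = 0.15
T_SIGMA_S = 0.055
T_AMP_MV = 0.30


@dataclass
class BeatParams:
    """Morphology of one beat; P-wave is the controlled, exactly-Gaussian part."""

    rr_ms: float = 1000.0
    p_amp_mv: float = 0.15
    p_sigma_ms: float = 24.0  # Gaussian width parameter of the P bump, in ms


@dataclass
class ClassParams:
    """Between-subject distributions of the generator knobs for one class."""

    p_amp_mean: float = 0.15     # mV
    p_amp_sd: float = 0.02
    p_sigma_mean: float = 24.0   # ms
    p_sigma_sd: float = 3.0
    mean_rr_mean: float = 900.0  # ms
    mean_rr_sd: float = 40.0
    lf_amp_mean: float = 30.0    # ms, 0.1 Hz sinusoid amplitude
    lf_amp_sd: float = 6.0
    hf_amp_mean: float = 35.0    # ms, 0.25 Hz sinusoid amplitude
    hf_amp_sd: float = 6.0
    ar_sd_mean: float = 18.0     # ms, sd of the AR(1) innovation-driven noise
    ar_sd_sd: float = 4.0
    ar_phi: float = 0.9          # AR(1) coefficient
    shuffle_frac: float = 0.0    # fraction of noise values randomly permuted


#: Frozen study conditions for the two cohorts.
DEFAULT_NORMAL = ClassParams()
DEFAULT_PAF = ClassParams(
    p_amp_mean=0.10,
    p_amp_sd=0.02,
    p_sigma_mean=33.0,
    p_sigma_sd=4.0,
    mean_rr_mean=820.0,
    mean_rr_sd=40.0,
    lf_amp_mean=45.0,
    lf_amp_sd=8.0,
    hf_amp_mean=18.0,
    hf_amp_sd=5.0,
    ar_sd_mean=32.0,
    ar_sd_sd=6.0,
    ar_phi=0.9,
    shuffle_frac=0.5,
)


def null_class_params() -> tuple[ClassParams, ClassParams]:
    """Identical class distributions (zero effect sizes) for null-cohort checks."""
    return ClassParams(), ClassParams()


@dataclass
class CohortSpec:
    n_per_class: int = 50
    fs: float = 128.0
    duration_s: float = 1800.0
    seed: int = 0
    noise_sd_mv: float = 0.01
    class_params: dict = field(
        default_factory=lambda: {"normal": DEFAULT_NORMAL, "PAF": DEFAULT_PAF}
    )

    def __post_init__(self):
        if self.n_per_class < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("n_per_class >= 1, fs > 0 and duration > 0 required")


@dataclass
class SyntheticRecord:
    """A generated record together with its generating ground truth."""

    record: ECGRecord
    truth: dict  # keys: rr (RRSeries), p_amp_mv, p_sigma_ms, p_gauss_W_samples, ...


def _gauss_bump(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-(((t - center) / sigma) ** 2))


def synth_beat(
    fs: float, params: BeatParams | None = None, rng: np.random.Generator | None = None,
    noise_sd_mv: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Render one beat of length ``round(rr * fs / 1000)`` samples.

    Returns ``(waveform, truth)`` where truth carries the P-wave Gaussian
    parameters in the beat's own (1-based) sample coordinates:
    ``A`` (mV), ``C`` (sample index of the P centre), ``W`` (samples).
    Raises :class:`ParameterError` when wave supports would overlap.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if params is None:
        params = BeatParams()
    n = int(round(params.rr_ms * fs / 1000.0))
    if n < 4:
        raise ParameterError(f"beat of {params.rr_ms} ms at {fs} Hz is too short")
    t = np.arange(n) / fs
    r_c = R_OFFSET_S
    p_c = r_c - P_LEAD_S
    t_c = r_c + T_LAG_S
    p_sigma_s = params.p_sigma_ms / 1000.0
    # support checks: 2.5 sigma of P must clear 3 sigma of QRS, and waves
    # must fit inside the beat
    if p_c - 2.5 * p_sigma_s < 0:
        raise ParameterError("P-wave support extends before the beat start")
    if p_c + 2.5 * p_sigma_s > r_c - 3.0 * QRS_SIGMA_S:
        raise ParameterError("P-wave support overlaps the QRS complex")
    if t_c + 2.0 * T_SIGMA_S > n / fs:
        raise ParameterError("T-wave support extends past the beat end")

    w = _gauss_bump(t, p_c, p_sigma_s, params.p_amp_mv)
    w += _gauss_bump(t, r_c, QRS_SIGMA_S, QRS_AMP_MV)
    w -= _gauss_bump(t, r_c - 2.5 * QRS_SIGMA_S, QRS_SIGMA_S * 0.8, Q_S_AMP_MV)
    w -= _gauss_bump(t, r_c + 2.5 * QRS_SIGMA_S, QRS_SIGMA_S * 0.8, Q_S_AMP_MV)
    w += _gauss_bump(t, t_c, T_SIGMA_S, T_AMP_MV)
    if noise_sd_mv > 0:
        if rng is None:
            rng = np.random.default_rng()
        w = w + rng.normal(0.0, noise_sd_mv, size=n)
    truth = {
        "A": params.p_amp_mv,
        "C": p_c * fs + 1.0,           # 1-based sample coordinate of the P centre
        "W": p_sigma_s * fs,           # Gaussian width in samples
        "r_index": int(round(r_c * fs)),
        "p_center_s": p_c,
    }
    return w, truth


def synth_rr_series(
    n_beats: int,
    mean_rr_ms: float = 900.0,
    lf_amp_ms: float = 30.0,
    hf_amp_ms: float = 35.0,
    ar_sd_ms: float = 18.0,
    ar_phi: float = 0.9,
    shuffle_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> RRSeries:
    """Generate an RR series with controlled spectral and nonlinear structure.

    ``RR[k] = mean + LF sin(2π·0.1·t_k) + HF sin(2π·0.25·t_k) + AR(1) noise``
    with beat times approximated as ``t_k = k·mean/1000`` (the modulation
    frequencies are nominal).  ``shuffle_frac`` of the noise values are
    randomly permuted to destroy serial correlation.
    """
    if n_beats < 2:
        raise ParameterError("need at least 2 beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_beats) * mean_rr_ms / 1000.0
    rr = mean_rr_ms + lf_amp_ms * np.sin(2 * np.pi * 0.1 * t)
    rr = rr + hf_amp_ms * np.sin(2 * np.pi * 0.25 * t)
    if ar_sd_ms > 0:
        innov_sd = ar_sd_ms * np.sqrt(1 - ar_phi**2)
        e = rng.normal(0.0, innov_sd, size=n_beats)
        noise = np.empty(n_beats)
        noise[0] = rng.normal(0.0, ar_sd_ms)
        for k in range(1, n_beats):
            noise[k] = ar_phi * noise[k - 1] + e[k]
        if shuffle_frac > 0:
            k = int(round(shuffle_frac * n_beats))
            idx = rng.choice(n_beats, size=k, replace=False)
            noise[np.sort(idx)] = noise[idx]  # permute the chosen positions
        rr = rr + noise
    if np.any(rr <= 0):
        raise ParameterError("parameters produced a non-positive RR interval")
    return RRSeries(intervals=rr)


def synth_record(
    subject_id: str,
    label: str,
    cp: ClassParams,
    fs: float = 128.0,
    duration_s: float = 1800.0,
    noise_sd_mv: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> SyntheticRecord:
    """Generate one labelled record by concatenating rendered beats."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # subject-level draws
    p_amp = max(0.04, rng.normal(cp.p_amp_mean, cp.p_amp_sd))
    p_sigma = float(np.clip(rng.normal(cp.p_sigma_mean, cp.p_sigma_sd), 10.0, 45.0))
    mean_rr = max(450.0, rng.normal(cp.mean_rr_mean, cp.mean_rr_sd))
    lf_amp = max(0.0, rng.normal(cp.lf_amp_mean, cp.lf_amp_sd))
    hf_amp = max(0.0, rng.normal(cp.hf_amp_mean, cp.hf_amp_sd))
    ar_sd = max(1.0, rng.normal(cp.ar_sd_mean, cp.ar_sd_sd))

    n_beats = int(np.ceil(duration_s * 1000.0 / mean_rr)) + 8
    rr = synth_rr_series(
        n_beats,
        mean_rr_ms=mean_rr,
        lf_amp_ms=lf_amp,
        hf_amp_ms=hf_amp,
        ar_sd_ms=ar_sd,
        ar_phi=cp.ar_phi,
        shuffle_frac=cp.shuffle_frac,
        seed=rng,
    )
    # a beat must fit its P/QRS/T layout: clip pathologically short intervals
    min_rr = 1000.0 * (R_OFFSET_S + T_LAG_S + 2.0 * T_SIGMA_S) + 10.0
    intervals = np.maximum(rr.intervals, min_rr)

    n_total = int(round(duration_s * fs))
    pieces = []
    r_indices = []
    pos = 0
    for rr_ms in intervals:
        w, truth = synth_beat(
            fs,
            BeatParams(rr_ms=rr_ms, p_amp_mv=p_amp, p_sigma_ms=p_sigma),
            rng=None,
            noise_sd_mv=0.0,
        )
        r_indices.append(pos + truth["r_index"])
        pieces.append(w)
        pos += w.size
        if pos >= n_total:
            break
    samples = np.concatenate(pieces)[:n_total]
    if noise_sd_mv > 0:
        samples = samples + rng.normal(0.0, noise_sd_mv, size=samples.size)
    record = ECGRecord(samples=samples, fs=fs, subject_id=subject_id, label=label)
    r_indices = np.asarray([r for r in r_indices if r < n_total], dtype=int)
    p_sigma_samples = p_sigma / 1000.0 * fs
    truth = {
        "rr": RRSeries(intervals=intervals[: len(pieces)]),
        "r_indices": r_indices,
        "p_amp_mv": p_amp,
        "p_sigma_ms": p_sigma,
        "p_gauss_A": p_amp,
        "p_gauss_W_samples": p_sigma_samples,
        "mean_rr_ms": mean_rr,
        "lf_amp_ms": lf_amp,
        "hf_amp_ms": hf_amp,
        "ar_sd_ms": ar_sd,
    }
    return SyntheticRecord(record=record, truth=truth)


def synth_cohort(spec: CohortSpec | None = None) -> list[SyntheticRecord]:
    """Generate the two labelled cohorts; reproducible from (spec, seed)."""
    if spec is None:
        spec = CohortSpec()
    root = np.random.SeedSequence(spec.seed)
    out = []
    labels = sorted(spec.class_params)  # deterministic order
    children = root.spawn(len(labels) * spec.n_per_class)
    k = 0
    for label in labels:
        cp = spec.class_params[label]
        for j in range(spec.n_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            out.append(
                synth_record(
                    subject_id=f"{label}{j:03d}",
                    label=label,
                    cp=cp,
                    fs=spec.fs,
                    duration_s=spec.duration_s,
                    noise_sd_mv=spec.noise_sd_mv,
                    seed=rng,
                )
            )
    return out
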