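"""Assembly of the 31-parameter subject feature vector.

Six P-wave morphology parameters (PW, PA, PD directly from delineation;
A, C, W from the HTGA Gaussian fit) plus 25 HRV parameters (11 time-domain,
7 frequency-domain, 7 nonlinear), in a fixed canonical column order.

Missing values (e.g. P-wave parameters on a record whose P-waves could not
be delineated) are carried as NaN — explicitly flagged, never silently zero.
Imputation is not performed here; the cross-validation stage fits median
imputation on training folds only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hrv_frequency, hrv_nonlinear, hrv_time
from .config import PipelineConfig
from .delineation import (
    delineate_p_wave,
    detect_r_peaks,
    p_wave_segments,
    pwave_basic_features,
)
from .ecg_io import ECGRecord, rr_from_peaks
from .errors import (
    DelineationError,
    DetectionError,
    FeatureExtractionError,
    InsufficientDataError,
    PafScreenError,
)
from .gaussfit import HTGAConfig, PWaveSegment, htga_fit

__all__ = ["FEATURE_NAMES", "FeatureVector", "extract_features", "feature_table",
           "write_feature_table", "read_feature_table"]

#: Canonical order of the 31 feature columns.
FEATURE_NAMES = (
    "PW", "PA", "PD", "A", "C", "W",
    "RRmean", "SDNN", "HRmean", "SDHR", "MinHR", "MaxHR",
    "RMSSD", "NN50", "pNN50", "HRVTriangularIndex", "TINN",
    "VLFpower", "LFpower", "HFpower", "LF_HF", "TP", "nLF", "nHF",
    "SD1", "SD2", "SD2_SD1", "ApEn", "SampEn", "alpha1", "alpha2",
)


@dataclass
class FeatureVector:
    subject_id: str
    label: str | None
    values: dict  # name -> float (NaN marks a missing feature)

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature vector must have exactly the 31 slots; "
                             f"missing={sorted(missing)}, extra={sorted(extra)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


def _subject_seed(config_seed: int, subject_id: str) -> int:
    return (config_seed * 1000003 + zlib.crc32(subject_id.encode())) % (2**31)


def _fit_gaussian_params(record, fiducials, config: PipelineConfig):
    """Median HTGA (A, C, W) over an evenly spaced subsample of beats."""
    segs = p_wave_segments(record, fiducials)
    segs = [s for s in segs if s.size >= 4]
    if not segs:
        return float("nan"), float("nan"), float("nan")
    k = min(config.max_fitted_beats, len(segs))
    pick = np.unique(np.linspace(0, len(segs) - 1, k).astype(int))
    base_seed = _subject_seed(config.seed, record.subject_id)
    fits = []
    for j, idx in enumerate(pick):
        cfg = HTGAConfig(
            population_size=config.htga_population_size,
            generations=config.htga_generations,
            crossover_rate=config.htga_crossover_rate,
            mutation_rate=config.htga_mutation_rate,
            seed=(base_seed + j) % (2**31),
        )
        params, _ = htga_fit(PWaveSegment(values=segs[idx]), cfg)
        fits.append([params.A, params.C, params.W])
    med = np.median(np.asarray(fits), axis=0)
    return float(med[0]), float(med[1]), float(med[2])


def extract_features(record: ECGRecord, config: PipelineConfig | None = None) -> FeatureVector:
    """Run the full per-subject feature extraction pipeline.

    P-wave morphology failures leave the six P slots NaN while the HRV slots
    are still populated; failures that prevent any HRV computation raise
    :class:`FeatureExtractionError` naming the stage.
    """
    if config is None:
        config = PipelineConfig()
    try:
        peaks = detect_r_peaks(record)
    except (DetectionError, InsufficientDataError) as e:
        raise FeatureExtractionError("r-peak detection", str(e)) from e
    try:
        rr = rr_from_peaks(peaks, record.fs)
    except InsufficientDataError as e:
        raise FeatureExtractionError("rr derivation", str(e)) from e

    values = {k: float("nan") for k in FEATURE_NAMES}

    # --- P-wave morphology (missing on failure, never fatal) ---
    try:
        fiducials = delineate_p_wave(
            record, peaks,
            search_window_ms=config.p_search_window_ms,
            min_p_amplitude=config.min_p_amplitude,
        )
        basic = pwave_basic_features(record, fiducials)
        values["PW"], values["PA"], values["PD"] = basic.PW, basic.PA, basic.PD
        values["A"], values["C"], values["W"] = _fit_gaussian_params(
            record, fiducials, config
        )
    except (DelineationError, InsufficientDataError):
        pass

    # --- HRV ---
    try:
        td = hrv_time.time_domain_features(
            rr,
            pnn50_denominator=config.pnn50_denominator,
            bin_width_ms=config.histogram_bin_width_ms,
        )
        for k in ("RRmean", "SDNN", "HRmean", "SDHR", "MinHR", "MaxHR",
                  "RMSSD", "NN50", "pNN50", "HRVTriangularIndex", "TINN"):
            values[k] = float(getattr(td, k))
    except InsufficientDataError as e:
        raise FeatureExtractionError("time-domain HRV", str(e)) from e
    try:
        fd = hrv_frequency.freq_domain_features(
            rr,
            estimator=config.spectral_estimator,
            resample_fs=config.resample_fs,
            welch_nperseg=config.welch_nperseg,
            welch_overlap=config.welch_overlap,
            ar_order=config.ar_order,
        )
        for k in ("VLFpower", "LFpower", "HFpower", "LF_HF", "TP", "nLF", "nHF"):
            values[k] = float(getattr(fd, k))
    except (InsufficientDataError, PafScreenError):
        pass  # short record: frequency slots stay missing
    try:
        nl = hrv_nonlinear.nonlinear_features(
            rr,
            m=config.entropy_m,
            r_factor=config.entropy_r_factor,
            short_range=config.dfa_short_range,
            long_range=config.dfa_long_range,
        )
        for k in ("SD1", "SD2", "SD2_SD1", "ApEn", "SampEn", "alpha1", "alpha2"):
            values[k] = float(getattr(nl, k))
    except InsufficientDataError:
        pass  # short record: nonlinear slots stay missing

    return FeatureVector(subject_id=record.subject_id, label=record.label, values=values)


def feature_table(records, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Extract features for a collection of records into a labelled table.

    Accepts ECGRecords or already-extracted FeatureVectors.  Rows are
    subjects; columns are the 31 canonical features plus ``label``.
    """
    rows = []
    ids = set()
    for item in records:
        fv = item if isinstance(item, FeatureVector) else extract_features(item, config)
        if fv.subject_id in ids:
            raise ValueError(f"duplicate subject_id {fv.subject_id!r}")
        ids.add(fv.subject_id)
        row = {"subject_id": fv.subject_id, **{k: fv.values[k] for k in FEATURE_NAMES},
               "label": fv.label}
        rows.append(row)
    if not rows:
        raise ValueError("no records given")
    df = pd.DataFrame(rows).set_index("subject_id")
    return df[list(FEATURE_NAMES) + ["label"]]


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, float_format="%.10g")


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    expected = list(FEATURE_NAMES) + ["label"]
    if list(df.columns) != expected:
        raise ValueError("feature CSV columns do not match the canonical order")
    return df
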