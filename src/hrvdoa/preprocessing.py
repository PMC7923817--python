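"""ECG cleaning, R-peak detection and RR-interval artifact filtering.

Body movement and medical-device interference dominate intra-operative ECG
artifacts, so the stage chain is: zero-phase band-pass + mains notch,
a derivative/square/moving-window-integration QRS detector with an adaptive
threshold (Pan-Tompkins family), and a two-rule RR artifact filter
(physiological bounds plus running-median deviation). All thresholds are
configuration, not constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter

from .errors import ConfigurationError, DataError
from .types import BeatSeries, ECGRecord, RRSeries


@dataclass
class PreprocessConfig:
    """Defaults are standard clinical-ECG choices; all are overridable."""

    band_low_hz: float = 0.5
    band_high_hz: float = 40.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    # QRS detector
    qrs_band: tuple = (5.0, 15.0)
    integration_window_s: float = 0.150
    refractory_s: float = 0.250
    threshold_frac: float = 0.35  # of segment-wise robust MWI amplitude
    threshold_segment_s: float = 10.0
    # RR artifact rules
    rr_min_ms: float = 333.0
    rr_max_ms: float = 2000.0
    median_dev_frac: float = 0.20
    median_window: int = 11


def filter_ecg(
    ecg: ECGRecord,
    band_low_hz: float = 0.5,
    band_high_hz: float = 40.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> ECGRecord:
    """Zero-phase band-pass plus mains notch.

    A 4th-order Butterworth band-pass and an IIR notch are both applied with
    ``filtfilt``, so the cascade is zero-phase (no timing shift of the R peak)
    and the output length equals the input length.
    """
    nyq = ecg.fs / 2.0
    if not (0 < band_low_hz < band_high_hz < nyq):
        raise ConfigurationError(
            f"band ({band_low_hz}, {band_high_hz}) Hz invalid for fs={ecg.fs} Hz"
        )
    if not (0 < notch_hz < nyq):
        raise ConfigurationError(f"notch {notch_hz} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(4, [band_low_hz, band_high_hz], btype="bandpass", fs=ecg.fs, output="sos")
    out = signal.sosfiltfilt(sos, ecg.samples)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=ecg.fs)
    out = signal.filtfilt(b, a, out)
    return ECGRecord(samples=out, fs=ecg.fs, case_id=ecg.case_id, start_time_s=ecg.start_time_s)


def _mwi(ecg: ECGRecord, config: PreprocessConfig) -> np.ndarray:
    """Band-pass -> derivative -> square -> moving-window integration."""
    sos = signal.butter(3, list(config.qrs_band), btype="bandpass", fs=ecg.fs, output="sos")
    x = signal.sosfiltfilt(sos, ecg.samples)
    dx = np.gradient(x) * ecg.fs
    sq = dx * dx
    w = max(int(round(config.integration_window_s * ecg.fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(sq, kernel, mode="same")


def detect_r_peaks(ecg: ECGRecord, config: PreprocessConfig | None = None) -> BeatSeries:
    """Detect R peaks with an adaptive-threshold energy detector.

    The moving-window-integrated QRS energy is thresholded at
    ``threshold_frac`` of a per-segment robust amplitude (95th percentile over
    ``threshold_segment_s`` blocks), peaks closer than the refractory period
    are suppressed, and each detection is refined to the argmax of the
    band-passed ECG within ±100 ms. Returns an empty series (with a warning)
    when nothing crosses threshold.
    """
    config = config or PreprocessConfig()
    if ecg.duration_s < 10.0:
        raise DataError("R-peak detection requires at least 10 s of ECG")
    mwi = _mwi(ecg, config)
    n = mwi.size
    seg = max(int(config.threshold_segment_s * ecg.fs), 1)
    thresh = np.empty(n)
    for s0 in range(0, n, seg):
        block = mwi[s0 : s0 + seg]
        thresh[s0 : s0 + len(block)] = config.threshold_frac * np.percentile(block, 95)
    floor = 0.01 * np.percentile(mwi, 95)  # reject silent segments
    thresh = np.maximum(thresh, floor)
    distance = max(int(config.refractory_s * ecg.fs), 1)
    peaks, _ = signal.find_peaks(mwi, height=thresh, distance=distance)
    if peaks.size == 0:
        warnings.warn("no R peaks detected", stacklevel=2)
        return BeatSeries(r_times_s=np.array([]))
    # refine on the band-passed ECG (R is the dominant positive deflection)
    sos = signal.butter(3, list(config.qrs_band), btype="bandpass", fs=ecg.fs, output="sos")
    xb = signal.sosfiltfilt(sos, ecg.samples)
    half = int(0.100 * ecg.fs)
    refined = []
    for p in peaks:
        i0, i1 = max(p - half, 0), min(p + half + 1, n)
        refined.append(i0 + int(np.argmax(xb[i0:i1])))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= distance:
            keep.append(int(r))
    times = ecg.start_time_s + np.asarray(keep) / ecg.fs
    return BeatSeries(r_times_s=times)


def beats_to_rr(beats: BeatSeries) -> RRSeries:
    """Successive beat-time differences in ms; all intervals start accepted."""
    if len(beats) < 2:
        raise DataError("need at least 2 beats to form RR intervals")
    intervals = np.diff(beats.r_times_s) * 1000.0
    return RRSeries(interval_ms=intervals, onset_time_s=beats.r_times_s[:-1])


def filter_rr(
    rr: RRSeries,
    min_ms: float = 333.0,
    max_ms: float = 2000.0,
    median_dev_frac: float = 0.20,
    median_window: int = 11,
) -> RRSeries:
    """Flag artifact intervals; keep the series in time order.

    An interval is rejected when it falls outside ``[min_ms, max_ms]`` or
    deviates from the running median (edge-reflected window over the raw
    interval sequence) by more than ``median_dev_frac`` of that median.
    Flags are recomputed from the raw intervals, so the operation is
    idempotent. Rejected intervals remain in the series (time order preserved)
    but are excluded downstream.
    """
    if len(rr) == 0:
        raise DataError("empty RR series")
    x = rr.interval_ms
    med = median_filter(x, size=median_window, mode="reflect")
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(x - med) / med
    accepted = (x >= min_ms) & (x <= max_ms) & (dev <= median_dev_frac)
    if not accepted.any():
        warnings.warn("all RR intervals rejected by artifact filter", stacklevel=2)
    return RRSeries(interval_ms=x.copy(), onset_time_s=rr.onset_time_s.copy(), accepted=accepted)


def match_beats(true_times_s, detected_times_s, tol_s: float = 0.010):
    """Greedy one-to-one matching of detected beats to ground truth.

    Returns ``(matched_true_idx, matched_det_idx)`` for pairs within
    ``tol_s``. Used to score detector sensitivity and RR recovery error
    against a generator's known beat times.
    """
    true_times_s = np.asarray(true_times_s, dtype=float)
    detected_times_s = np.asarray(detected_times_s, dtype=float)
    ti, di = [], []
    j = 0
    for i, t in enumerate(true_times_s):
        while j < detected_times_s.size and detected_times_s[j] < t - tol_s:
            j += 1
        if j < detected_times_s.size and abs(detected_times_s[j] - t) <= tol_s:
            ti.append(i)
            di.append(j)
            j += 1
    return np.asarray(ti, dtype=int), np.asarray(di, dtype=int)


def preprocess_ecg(ecg: ECGRecord, config: PreprocessConfig | None = None) -> RRSeries:
    """Full chain: filter -> detect R peaks -> RR -> artifact filter."""
    config = config or PreprocessConfig()
    clean = filter_ecg(ecg, config.band_low_hz, config.band_high_hz, config.notch_hz, config.notch_q)
    beats = detect_r_peaks(clean, config)
    rr = beats_to_rr(beats)
    return filter_rr(rr, config.rr_min_ms, config.rr_max_ms, config.median_dev_frac, config.median_window)
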