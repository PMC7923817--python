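"""Core domain containers for the anaesthesia-state HRV pipeline.

The pipeline moves through four representations: a raw voltage trace
(:class:`ECGRecord`), detected R-peak times (:class:`BeatSeries`), the
inter-beat interval series (:class:`RRSeries`), and per-window feature rows
(a pandas DataFrame, see :mod:`hrvdoa.features`). Clinical context travels
alongside as an event timeline (:class:`AnaesthesiaTimeline`) and a 0-100
consciousness score trace (:class:`EACLTrace`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

#: Ordered anaesthesia states: induction, maintenance, recovery.
STATES = ("I", "II", "III")

#: Event names a timeline must contain, in order.
TIMELINE_EVENTS = (
    "induction_start",
    "LOC",
    "maintenance_start",
    "recovery_start",
    "ROC",
    "end",
)


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling rate in Hz (the study hardware sampled at 500 Hz).
    case_id : str
        Case identifier.
    start_time_s : float
        Absolute time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    case_id: str = "case"
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if self.samples.size < 2:
            raise DataError("ECG record needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """R-peak times in seconds, strictly increasing. May be empty."""

    r_times_s: np.ndarray

    def __post_init__(self):
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        if self.r_times_s.size and np.any(np.diff(self.r_times_s) <= 0):
            raise DataError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.r_times_s.size


@dataclass
class RRSeries:
    """Consecutive inter-beat intervals with per-interval quality flags.

    ``interval_ms[i]`` spans from ``onset_time_s[i]`` (the earlier beat of the
    pair) to the next beat. ``accepted`` marks intervals that survived artifact
    filtering; rejected intervals stay in place so timing is preserved but are
    excluded from feature computation.
    """

    interval_ms: np.ndarray
    onset_time_s: np.ndarray
    accepted: np.ndarray = None

    def __post_init__(self):
        self.interval_ms = np.asarray(self.interval_ms, dtype=float)
        self.onset_time_s = np.asarray(self.onset_time_s, dtype=float)
        if self.interval_ms.shape != self.onset_time_s.shape:
            raise DataError("interval and onset arrays must have equal length")
        if self.accepted is None:
            self.accepted = np.ones(self.interval_ms.shape, dtype=bool)
        else:
            self.accepted = np.asarray(self.accepted, dtype=bool)
            if self.accepted.shape != self.interval_ms.shape:
                raise DataError("quality flags must match interval length")

    def __len__(self) -> int:
        return self.interval_ms.size

    @property
    def accepted_intervals(self) -> np.ndarray:
        return self.interval_ms[self.accepted]

    @property
    def accepted_onsets(self) -> np.ndarray:
        return self.onset_time_s[self.accepted]


@dataclass
class AnaesthesiaTimeline:
    """Ordered clinical events bracketing the three anaesthesia states.

    State I (induction) runs ``[induction_start, maintenance_start)``,
    state II (maintenance) ``[maintenance_start, recovery_start)`` and
    state III (recovery) ``[recovery_start, end]``. LOC / ROC mark loss and
    recovery of consciousness inside induction and recovery respectively.
    """

    case_id: str
    events: list  # list of (event_name, time_s) in order

    def __post_init__(self):
        names = [e[0] for e in self.events]
        if tuple(names) != TIMELINE_EVENTS:
            raise DataError(
                f"timeline must contain events {TIMELINE_EVENTS} in order, got {names}"
            )
        times = np.array([e[1] for e in self.events], dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DataError("timeline event times must be strictly increasing")
        if times[0] != 0.0:
            raise DataError("induction_start must be at time 0")

    def time_of(self, event_name: str) -> float:
        for name, t in self.events:
            if name == event_name:
                return float(t)
        raise KeyError(event_name)

    @property
    def end_s(self) -> float:
        return self.time_of("end")

    def state_at(self, t: float) -> str:
        """State label at absolute time ``t`` (half-open boundaries)."""
        if t < 0 or t > self.end_s:
            raise DataError(f"time {t} outside timeline [0, {self.end_s}]")
        if t < self.time_of("maintenance_start"):
            return "I"
        if t < self.time_of("recovery_start"):
            return "II"
        return "III"


@dataclass
class EACLTrace:
    """Expert assessment of consciousness level, 0-100.

    ``score`` is the arithmetic mean of five simulated raters' traces, matching
    the clinical definition (five anaesthesiologists' retrospective scores,
    100 = fully awake, 0 = isoelectricity).
    """

    times_s: np.ndarray
    score: np.ndarray
    per_rater_scores: np.ndarray  # shape (5, n)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        self.per_rater_scores = np.asarray(self.per_rater_scores, dtype=float)
        if self.per_rater_scores.shape != (5, self.times_s.size):
            raise DataError("per_rater_scores must be 5 x len(times)")
        if self.score.shape != self.times_s.shape:
            raise DataError("score length must match times")
        if np.any(self.score < 0) or np.any(self.score > 100):
            raise DataError("EACL scores must lie in [0, 100]")
        if not np.allclose(self.score, self.per_rater_scores.mean(axis=0)):
            raise DataError("score must equal the mean of the five rater traces")

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the mean score at time(s) ``t``."""
        return np.interp(t, self.times_s, self.score)


@dataclass
class Tachogram:
    """Evenly resampled, mean-removed RR series for spectral analysis."""

    values_ms: np.ndarray
    fs_resample: float
    window_start_s: float = 0.0

    def __post_init__(self):
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        if self.fs_resample <= 0:
            raise DataError("resample rate must be positive")
        if not np.all(np.isfinite(self.values_ms)):
            raise DataError("tachogram values must be finite")

    def __len__(self) -> int:
        return self.values_ms.size
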