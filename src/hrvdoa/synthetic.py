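"""Synthetic anaesthesia cohort generator with known ground truth.

Clinical ECG from anaesthesia cases is not publicly available, so every
downstream stage (R-peak detection, RR filtering, wavelet band power, state
classification) is exercised against simulated cases whose generating
parameters are known exactly.

A case is built in four layers:

1. a timeline of the six clinical events (induction start, LOC, maintenance
   start, recovery start, ROC, end) with per-phase durations drawn around
   configured means;
2. an EACL trace: a smooth 0-100 consciousness trajectory (descent during
   induction, plateau near 50 during maintenance, ascent during recovery),
   observed by five simulated raters whose scores carry independent smooth
   noise and are averaged, mirroring the clinical five-anaesthesiologist
   protocol;
3. an RR-interval series: per-phase mean RR plus sinusoidal modulation at
   0.10 Hz (LF) and 0.25 Hz (HF) with phase-dependent amplitudes plus white
   Gaussian jitter. Direct sinusoidal modulation keeps the band powers
   analytically known (a tone of amplitude ``a`` contributes variance a²/2);
4. optionally, a rendered 500 Hz ECG waveform: each beat is a sum-of-Gaussians
   PQRST complex centred on the true beat time, plus baseline wander, mains
   interference, white noise and optional burst artifacts.

Default amplitude orderings encode the clinically reported directions:
HF modulation recovery > induction > maintenance, LF modulation
induction > maintenance > recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, DataError
from .types import AnaesthesiaTimeline, EACLTrace, ECGRecord, RRSeries, STATES

# PQRST template: (offset from R in s, Gaussian width in s, amplitude in mV)
_PQRST = (
    ("P", -0.20, 0.025, 0.15),
    ("Q", -0.05, 0.010, -0.10),
    ("R", 0.00, 0.012, 1.20),
    ("S", 0.05, 0.010, -0.25),
    ("T", 0.30, 0.060, 0.35),
)


def _phase_map(value) -> dict:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in STATES}
    raise ConfigurationError(f"expected per-phase mapping over {STATES}, got {value!r}")


@dataclass
class SimConfig:
    """Cohort generation parameters.

    Phase keys are "I" (induction), "II" (maintenance), "III" (recovery).
    Defaults target a mean case of ~133 min so a 64 s window at 4 s stride
    yields roughly 2000 analysis windows per case, i.e. ~46,000 for the
    23-case cohort.
    """

    n_cases: int = 23
    phase_mean_s: dict = field(
        default_factory=lambda: {"I": 600.0, "II": 6470.0, "III": 900.0}
    )
    phase_sd_frac: float = 0.20  # per-phase duration SD as fraction of mean
    mean_rr_ms: dict = field(
        default_factory=lambda: {"I": 850.0, "II": 1000.0, "III": 800.0}
    )
    lf_amp_ms: dict = field(
        default_factory=lambda: {"I": 40.0, "II": 25.0, "III": 12.0}
    )
    hf_amp_ms: dict = field(
        default_factory=lambda: {"I": 20.0, "II": 8.0, "III": 35.0}
    )
    lf_hz: float = 0.10
    hf_hz: float = 0.25
    rr_noise_sd_ms: float = 15.0
    # EACL trajectory
    eacl_awake: float = 95.0
    eacl_plateau: float = 50.0
    eacl_wander_amp: float = 3.0
    eacl_wander_period_s: float = 600.0
    rater_noise_sd: float = 5.0
    rater_noise_smooth_s: float = 10.0
    eacl_fs: float = 1.0
    # ECG rendering
    ecg_fs: float = 500.0
    ecg_noise_mv: float = 0.02
    baseline_wander_mv: float = 0.10
    baseline_wander_hz: float = 0.25
    mains_hz: float = 50.0
    mains_amp_mv: float = 0.05
    artifact_rate_per_min: float = 0.5
    artifact_burst_s: float = 0.5
    artifact_amp_mv: float = 1.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        for name in ("phase_mean_s", "mean_rr_ms", "lf_amp_ms", "hf_amp_ms"):
            mapping = _phase_map(getattr(self, name))
            setattr(self, name, mapping)
            bad = [s for s, v in mapping.items() if v < 0]
            if bad:
                raise ConfigurationError(f"{name} must be non-negative, got {mapping}")
        if any(v <= 0 for v in self.phase_mean_s.values()):
            raise ConfigurationError("phase durations must be positive")
        if not 0 <= self.phase_sd_frac < 0.5:
            raise ConfigurationError("phase_sd_frac must be in [0, 0.5)")
        for s in STATES:
            worst = self.mean_rr_ms[s] - self.lf_amp_ms[s] - self.hf_amp_ms[s]
            if worst <= 250.0:
                raise ConfigurationError(
                    f"phase {s}: deterministic RR minimum {worst:.0f} ms <= 250 ms"
                )
        if self.ecg_fs <= 0 or self.eacl_fs <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.rr_noise_sd_ms < 0 or self.rater_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if self.artifact_rate_per_min < 0:
            raise ConfigurationError("artifact rate must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SimulatedCase:
    """One fully specified case: ground truth for every downstream stage."""

    case_id: str
    timeline: AnaesthesiaTimeline
    eacl: EACLTrace
    rr: RRSeries
    beat_times_s: np.ndarray
    ecg: ECGRecord | None = None


def _rng(config: SimConfig, case_index: int, stream: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, case, stage)
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(case_index, stream))
    )


def simulate_timeline(config: SimConfig, case_index: int) -> AnaesthesiaTimeline:
    """Draw a six-event timeline for one case.

    Phase durations are truncated-Gaussian around ``phase_mean_s`` (clipped to
    ±2 SD). LOC falls inside induction, ROC inside recovery. Deterministic for
    a given (seed, case_index); with ``phase_sd_frac = 0`` the configured means
    are used exactly.
    """
    if case_index >= config.n_cases or case_index < 0:
        raise ConfigurationError(
            f"case_index {case_index} outside cohort of {config.n_cases}"
        )
    rng = _rng(config, case_index, 0)
    durations = {}
    for s in STATES:
        mean = config.phase_mean_s[s]
        sd = config.phase_sd_frac * mean
        d = float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd)) if sd > 0 else mean
        durations[s] = d
    t_maint = durations["I"]
    t_rec = t_maint + durations["II"]
    t_end = t_rec + durations["III"]
    loc = durations["I"] * rng.uniform(0.3, 0.7)
    roc = t_rec + durations["III"] * rng.uniform(0.4, 0.8)
    events = [
        ("induction_start", 0.0),
        ("LOC", loc),
        ("maintenance_start", t_maint),
        ("recovery_start", t_rec),
        ("ROC", roc),
        ("end", t_end),
    ]
    return AnaesthesiaTimeline(case_id=f"case{case_index:03d}", events=events)


def _base_eacl(times: np.ndarray, timeline: AnaesthesiaTimeline, config: SimConfig) -> np.ndarray:
    """Smooth reference trajectory: descent, wandering plateau, ascent."""
    t_m = timeline.time_of("maintenance_start")
    t_r = timeline.time_of("recovery_start")
    t_e = timeline.end_s
    base = np.empty_like(times)
    awake, plateau = config.eacl_awake, config.eacl_plateau

    ind = times < t_m
    u = times[ind] / t_m
    base[ind] = plateau + (awake - plateau) * (1 + np.cos(np.pi * u)) / 2

    mnt = (times >= t_m) & (times < t_r)
    base[mnt] = plateau + config.eacl_wander_amp * np.sin(
        2 * np.pi * (times[mnt] - t_m) / config.eacl_wander_period_s
    )

    rec = times >= t_r
    u = (times[rec] - t_r) / max(t_e - t_r, 1e-9)
    base[rec] = plateau + (awake - 5.0 - plateau) * (1 - np.cos(np.pi * u)) / 2
    return base


def simulate_eacl(
    timeline: AnaesthesiaTimeline, config: SimConfig, case_index: int = 0
) -> EACLTrace:
    """Simulate the five-rater consciousness score trace for one case.

    Each rater observes the base trajectory plus independent smooth noise
    (white Gaussian, low-pass filtered, rescaled to ``rater_noise_sd``). The
    reported score is the arithmetic mean of the five raters, clipped to
    [0, 100] per rater before averaging.
    """
    rng = _rng(config, case_index, 1)
    n = int(np.floor(timeline.end_s * config.eacl_fs)) + 1
    times = np.arange(n) / config.eacl_fs
    base = _base_eacl(times, timeline, config)
    raters = np.empty((5, n))
    sigma = config.rater_noise_smooth_s * config.eacl_fs
    for k in range(5):
        if config.rater_noise_sd == 0:
            raters[k] = base
            continue
        noise = rng.standard_normal(n)
        noise = gaussian_filter1d(noise, sigma=sigma, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= config.rater_noise_sd / sd
        raters[k] = np.clip(base + noise, 0.0, 100.0)
    return EACLTrace(times_s=times, score=raters.mean(axis=0), per_rater_scores=raters)


def rr_model_ms(t, state: str, config: SimConfig, rng=None):
    """Instantaneous RR (ms) at time t in a given state, noise optional."""
    rr = (
        config.mean_rr_ms[state]
        + config.lf_amp_ms[state] * np.sin(2 * np.pi * config.lf_hz * t)
        + config.hf_amp_ms[state] * np.sin(2 * np.pi * config.hf_hz * t)
    )
    if rng is not None and config.rr_noise_sd_ms > 0:
        rr = rr + rng.normal(0.0, config.rr_noise_sd_ms)
    return rr


def simulate_rr(
    timeline: AnaesthesiaTimeline, config: SimConfig, case_index: int = 0
) -> RRSeries:
    """Generate beat times whose consecutive intervals follow the RR model.

    Beats are placed iteratively: the interval starting at beat time ``t_k``
    equals the model RR evaluated at ``t_k``. An interval at or below 250 ms is
    treated as a non-physiological configuration and rejected outright.
    """
    rng = _rng(config, case_index, 2)
    t_m = timeline.time_of("maintenance_start")
    t_r = timeline.time_of("recovery_start")
    end = timeline.end_s
    beats = [0.0]
    t = 0.0
    while True:
        state = "I" if t < t_m else ("II" if t < t_r else "III")
        rr = float(rr_model_ms(t, state, config, rng))
        if rr <= 250.0:
            raise ConfigurationError(
                f"simulated RR {rr:.0f} ms <= 250 ms at t={t:.1f}s (phase {state})"
            )
        t = t + rr / 1000.0
        if t > end:
            break
        beats.append(t)
    beats = np.asarray(beats)
    if beats.size < 2:
        raise DataError("timeline too short to fit two beats")
    return RRSeries(
        interval_ms=np.diff(beats) * 1000.0,
        onset_time_s=beats[:-1],
    )


def beat_times(rr: RRSeries) -> np.ndarray:
    """Recover the full beat-time vector (onsets plus the final beat)."""
    last = rr.onset_time_s[-1] + rr.interval_ms[-1] / 1000.0
    return np.append(rr.onset_time_s, last)


def render_ecg(
    rr: RRSeries, config: SimConfig, case_index: int = 0, case_id: str = "case"
) -> ECGRecord:
    """Render a 500 Hz PQRST waveform from a beat sequence.

    Each beat contributes five Gaussian bumps (P, Q, R, S, T) with the R apex
    at the true beat time. Additive components: sinusoidal baseline wander,
    mains-frequency interference, white measurement noise, and Poisson-timed
    high-amplitude noise bursts at ``artifact_rate_per_min``.
    """
    if len(rr) == 0:
        raise DataError("cannot render ECG from empty RR series")
    rng = _rng(config, case_index, 3)
    fs = config.ecg_fs
    bt = beat_times(rr)
    start = bt[0] - 0.5  # lead-in so the first PQRST is not clipped
    duration = bt[-1] + 0.5 - start
    n = int(round(duration * fs))
    sig = np.zeros(n)
    t_half = 0.45  # template support half-width, s
    for b in bt:
        i0 = max(int((b - start - t_half) * fs), 0)
        i1 = min(int((b - start + t_half) * fs) + 1, n)
        tt = start + np.arange(i0, i1) / fs - b
        for _, off, width, amp in _PQRST:
            sig[i0:i1] += amp * np.exp(-0.5 * ((tt - off) / width) ** 2)
    t = start + np.arange(n) / fs
    if config.baseline_wander_mv > 0:
        sig += config.baseline_wander_mv * np.sin(2 * np.pi * config.baseline_wander_hz * t)
    if config.mains_amp_mv > 0:
        sig += config.mains_amp_mv * np.sin(2 * np.pi * config.mains_hz * t)
    if config.ecg_noise_mv > 0:
        sig += rng.normal(0.0, config.ecg_noise_mv, n)
    if config.artifact_rate_per_min > 0:
        n_art = rng.poisson(config.artifact_rate_per_min * duration / 60.0)
        for _ in range(n_art):
            s0 = int(rng.uniform(0, max(n - config.artifact_burst_s * fs, 1)))
            s1 = min(s0 + int(config.artifact_burst_s * fs), n)
            sig[s0:s1] += rng.normal(0.0, config.artifact_amp_mv, s1 - s0)
    return ECGRecord(samples=sig, fs=fs, case_id=case_id, start_time_s=start)


def simulate_case(
    config: SimConfig, case_index: int, with_ecg: bool = False
) -> SimulatedCase:
    """Generate one complete case (timeline, EACL, RR, optional ECG)."""
    timeline = simulate_timeline(config, case_index)
    eacl = simulate_eacl(timeline, config, case_index)
    rr = simulate_rr(timeline, config, case_index)
    ecg = (
        render_ecg(rr, config, case_index, case_id=timeline.case_id)
        if with_ecg
        else None
    )
    return SimulatedCase(
        case_id=timeline.case_id,
        timeline=timeline,
        eacl=eacl,
        rr=rr,
        beat_times_s=beat_times(rr),
        ecg=ecg,
    )


def simulate_cohort(config: SimConfig, with_ecg: bool = False) -> list:
    """Generate the full cohort (default: 23 cases)."""
    return [simulate_case(config, i, with_ecg=with_ecg) for i in range(config.n_cases)]
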