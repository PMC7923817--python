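import numpy as np
import pytest

import hrvdoa as h


def short_sim_config(**overrides) -> h.SimConfig:
    """A fast three-phase case (~11 min) for end-to-end tests."""
    defaults = dict(
        n_cases=3,
        phase_mean_s={"I": 120.0, "II": 400.0, "III": 120.0},
        phase_sd_frac=0.1,
        seed=11,
    )
    defaults.update(overrides)
    return h.SimConfig(**defaults)


def clean_sim_config(**overrides) -> h.SimConfig:
    """Short cases with every ECG noise source disabled."""
    return short_sim_config(
        ecg_noise_mv=0.0,
        baseline_wander_mv=0.0,
        mains_amp_mv=0.0,
        artifact_rate_per_min=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def short_case() -> h.SimulatedCase:
    return h.simulate_case(short_sim_config(), 0, with_ecg=True)


@pytest.fixture(scope="session")
def clean_case() -> h.SimulatedCase:
    return h.simulate_case(clean_sim_config(), 0, with_ecg=True)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table for 3 short cases, built from the true RR series."""
    import pandas as pd

    config = short_sim_config()
    tables = []
    for i in range(config.n_cases):
        case = h.simulate_case(config, i)
        tables.append(
            h.extract_features(case.rr, case.eacl, case.timeline, case_id=case.case_id)
        )
    return pd.concat(tables, ignore_index=True)


def separable_clusters(n_per: int = 200, sep: float = 10.0, seed: int = 0) -> h.Dataset:
    """Three Gaussian clusters separated by ``sep`` standard deviations."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, state in enumerate(h.STATES):
        centre = np.full(4, i * sep)
        X.append(rng.normal(centre, 1.0, size=(n_per, 4)))
        y.extend([state] * n_per)
    return h.Dataset(
        features=np.vstack(X),
        labels=np.array(y),
        eacl=np.linspace(20, 80, 3 * n_per),
        case_ids=np.array(["c%d" % (i % 5) for i in range(3 * n_per)]),
    )


def welch_band_oracle(x, fs: float):
    """Band-integrated periodogram of the mirror-extended window: LF and HF
    power (ms²) by brick-wall integration over the dyadic band unions
    (0.039-0.156 Hz and 0.156-0.625 Hz at a 2.5 Hz resample rate)."""
    import numpy as np
    from scipy.signal import welch

    y = np.concatenate([x, x[::-1]])
    y = y - y.mean()
    f, p = welch(y, fs=fs, nperseg=len(y), window="boxcar", detrend=False)
    df = f[1] - f[0]
    lf = p[(f >= fs / 2**6) & (f < fs / 2**4)].sum() * df
    hf = p[(f >= fs / 2**4) & (f < fs / 2**2)].sum() * df
    return lf, hf


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Independent O(N²) template-counting SampEn (Chebyshev distance,
    self-matches excluded, N - m templates for both lengths)."""
    import math

    x = list(map(float, x))
    n = len(x)
    nt = n - m
    b_count = a_count = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b_count += 1
            d_m1 = max(abs(x[i + k] - x[j + k]) for k in range(m + 1))
            if d_m1 <= r:
                a_count += 1
    if a_count == 0 or b_count == 0:
        return float("nan")
    return -math.log(a_count / b_count)
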