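"""File formats: plain CSV and JSON, documented schemas, round-trip safe.

CSV dialect is fixed: comma-separated, header row, '.' decimal, UTF-8, no
index column. Schemas:

* ECG CSV: columns ``time_s, mv``.
* RR CSV: columns ``onset_time_s, interval_ms, accepted`` (accepted in {0,1}).
* feature CSV: ``case_id, window_start_s, window_end_s, hf_ms2, lf_ms2,
  hf_lf_ratio, sampen, eacl, state``.
* timeline JSON: ``{"case_id": ..., "events": [[name, time_s], ...]}``.
* EACL JSON: ``{"times_s": [...], "per_rater_scores": [[...] x5]}`` (the mean
  score is recomputed on read, keeping the mean-of-raters invariant intact).
* cohort manifest CSV: ``case_id, timeline_json, eacl_json, rr_csv, ecg_csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .types import AnaesthesiaTimeline, EACLTrace, ECGRecord, RRSeries


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def write_ecg_csv(ecg: ECGRecord, path) -> None:
    pd.DataFrame({"time_s": ecg.times_s, "mv": ecg.samples}).to_csv(path, index=False)


def read_ecg_csv(path, fs: float | None = None, case_id: str | None = None) -> ECGRecord:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "mv"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: ECG needs at least 2 samples")
    dt = np.diff(t)
    if fs is None:
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise DataError(f"{path}: sample times not uniform; pass fs explicitly")
        fs = 1.0 / dt[0]
    return ECGRecord(
        samples=df["mv"].to_numpy(dtype=float), fs=float(fs),
        case_id=case_id or Path(path).stem, start_time_s=float(t[0]),
    )


def write_rr_csv(rr: RRSeries, path) -> None:
    pd.DataFrame(
        {
            "onset_time_s": rr.onset_time_s,
            "interval_ms": rr.interval_ms,
            "accepted": rr.accepted.astype(int),
        }
    ).to_csv(path, index=False)


def read_rr_csv(path) -> RRSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["onset_time_s", "interval_ms", "accepted"], path)
    return RRSeries(
        interval_ms=df["interval_ms"].to_numpy(dtype=float),
        onset_time_s=df["onset_time_s"].to_numpy(dtype=float),
        accepted=df["accepted"].to_numpy(dtype=bool),
    )


def write_timeline_json(timeline: AnaesthesiaTimeline, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"case_id": timeline.case_id,
             "events": [[name, float(t)] for name, t in timeline.events]},
            fh, indent=1,
        )


def read_timeline_json(path) -> AnaesthesiaTimeline:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("case_id", "events"):
        if key not in d:
            raise DataError(f"{path}: timeline JSON missing field '{key}'")
    return AnaesthesiaTimeline(
        case_id=d["case_id"], events=[(name, float(t)) for name, t in d["events"]]
    )


def write_eacl_json(eacl: EACLTrace, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"times_s": eacl.times_s.tolist(),
             "per_rater_scores": eacl.per_rater_scores.tolist()},
            fh,
        )


def read_eacl_json(path) -> EACLTrace:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("times_s", "per_rater_scores"):
        if key not in d:
            raise DataError(f"{path}: EACL JSON missing field '{key}'")
    raters = np.asarray(d["per_rater_scores"], dtype=float)
    return EACLTrace(
        times_s=np.asarray(d["times_s"], dtype=float),
        score=raters.mean(axis=0),
        per_rater_scores=raters,
    )


FEATURE_CSV_COLUMNS = [
    "case_id", "window_start_s", "window_end_s",
    "hf_ms2", "lf_ms2", "hf_lf_ratio", "sampen", "eacl", "state",
]


def write_features_csv(df: pd.DataFrame, path) -> None:
    df[FEATURE_CSV_COLUMNS].to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"state": str, "case_id": str})
    _require_columns(df, FEATURE_CSV_COLUMNS, path)
    return df


def write_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_default)


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest_csv(rows: list, path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["case_id"], path)
    return df
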