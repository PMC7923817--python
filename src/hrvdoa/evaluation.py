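"""Performance metrics, feature-EACL correlations, and model comparisons.

Per-state precision (column-wise), recall (row-wise) and overall accuracy
(trace-wise) come from the 3x3 confusion matrix over states I/II/III.
Classifiers are compared pairwise with a 2x2 chi-square on correct/incorrect
counts over a shared test set; feature relevance is summarised by Pearson
correlation with the EACL and by per-state quartile tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .types import STATES


@dataclass
class ConfusionMatrix:
    """3x3 counts indexed (true state, predicted state) in order I, II, III."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise DataError(f"confusion matrix must be 3x3, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    precision: dict  # state -> float or NaN when the state is never predicted
    recall: dict
    accuracy: float
    n: int
    model_kind: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "accuracy": self.accuracy,
            "n": self.n,
            **{f"precision_{s}": self.precision[s] for s in STATES},
            **{f"recall_{s}": self.recall[s] for s in STATES},
        }


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape or true_labels.size == 0:
        raise DataError("label vectors must be equal-length and non-empty")
    index = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix, model_kind: str = "") -> EvalReport:
    """Precision/recall per state and trace accuracy.

    A state that is never predicted (zero column) has undefined precision; a
    state that never occurs (zero row) has undefined recall. Both are reported
    as NaN with a warning rather than forced to 0.
    """
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    c = cm.counts
    precision, recall = {}, {}
    for i, s in enumerate(STATES):
        col, row = c[:, i].sum(), c[i, :].sum()
        if col == 0:
            warnings.warn(f"state {s} never predicted; precision undefined", stacklevel=2)
            precision[s] = float("nan")
        else:
            precision[s] = float(c[i, i] / col)
        if row == 0:
            warnings.warn(f"state {s} never occurs; recall undefined", stacklevel=2)
            recall[s] = float("nan")
        else:
            recall[s] = float(c[i, i] / row)
    return EvalReport(
        precision=precision,
        recall=recall,
        accuracy=float(np.trace(c) / cm.total),
        n=cm.total,
        model_kind=model_kind,
    )


def pearson(feature_values, eacl_values):
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(eacl_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("correlation inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_models_chisq(
    correct_counts: dict, n_test: int, yates: bool = False, bonferroni: bool = False
) -> pd.DataFrame:
    """Pairwise 2x2 chi-square tests on correct/incorrect counts.

    ``correct_counts`` maps model name -> number of correct classifications on
    a shared test set of size ``n_test``. Each pair forms the contingency
    table [[c1, n-c1], [c2, n-c2]]; identical counts give statistic 0, p = 1.
    No continuity correction by default; an expected cell below 5 is annotated
    rather than rejected. Optional Bonferroni adjustment over the pairs.
    """
    if n_test <= 0:
        raise DataError("n_test must be positive")
    for name, c in correct_counts.items():
        if not 0 <= c <= n_test:
            raise DataError(f"correct count for {name} outside [0, {n_test}]")
    names = list(correct_counts)
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in pairs:
        table = np.array(
            [
                [correct_counts[a], n_test - correct_counts[a]],
                [correct_counts[b], n_test - correct_counts[b]],
            ]
        )
        if correct_counts[a] == correct_counts[b]:
            stat, p = 0.0, 1.0
            low_expected = False
        else:
            stat, p, _, expected = stats.chi2_contingency(table, correction=yates)
            low_expected = bool((expected < 5).any())
        if bonferroni:
            p = min(p * len(pairs), 1.0)
        rows.append(
            {"model_a": a, "model_b": b, "statistic": float(stat), "p": float(p),
             "low_expected_cell": low_expected}
        )
    return pd.DataFrame(rows)


def state_feature_summary(features: pd.DataFrame, rank_tests: bool = False) -> pd.DataFrame:
    """Median/Q1/Q3/whiskers of each feature per state (box-plot summary).

    Whiskers follow the Tukey convention: most extreme points within 1.5 IQR
    of the quartiles. Optionally appends pairwise Mann-Whitney p-values.
    """
    feature_cols = ["hf_ms2", "lf_ms2", "hf_lf_ratio", "sampen"]
    present = set(features["state"].unique())
    missing = set(STATES) - present
    if missing:
        warnings.warn(f"states missing from feature table: {missing}", stacklevel=2)
    rows = []
    for s in STATES:
        sub = features.loc[features["state"] == s]
        for col in feature_cols:
            vals = sub[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append(
                {"state": s, "feature": col, "median": med, "q1": q1, "q3": q3,
                 "whisker_low": lo, "whisker_high": hi, "n": vals.size}
            )
    table = pd.DataFrame(rows)
    if rank_tests and not table.empty:
        tests = []
        for col in feature_cols:
            for i, a in enumerate(STATES):
                for b in STATES[i + 1 :]:
                    va = features.loc[features["state"] == a, col].dropna()
                    vb = features.loc[features["state"] == b, col].dropna()
                    if len(va) and len(vb):
                        _, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
                        tests.append({"feature": col, "pair": f"{a}-{b}", "p": float(p)})
        table.attrs["rank_tests"] = pd.DataFrame(tests)
    return table


def correlation_table(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and p) of each of the four features against the EACL."""
    rows = []
    for col in ["hf_ms2", "lf_ms2", "hf_lf_ratio", "sampen"]:
        sub = features[[col, "eacl"]].dropna()
        r, p = pearson(sub[col], sub["eacl"])
        rows.append({"feature": col, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
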