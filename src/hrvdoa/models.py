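"""State classifiers: logistic regression, SVM, decision tree, and the
4-10-17-1 deep network.

The ternary target (I = induction, II = maintenance, III = recovery) is
derived from the event timeline. Three reference classifiers are standard
scikit-learn fits; the deep network is a fully connected 4-10-17-1 multilayer
perceptron with a single output node, implemented here directly: ReLU hidden
activations, linear output, mean-squared-error loss against ordinal class
codes {0, 0.5, 1}, Adam updates with a fixed seed. Its scalar output is
decoded to the nearest class code (ties toward the lower state).

An alternative head trains the same network on EACL/100 as a regression
target and decodes through the per-state mean scores seen in training; the
primary mode is ordinal class coding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataError
from .types import STATES, AnaesthesiaTimeline

#: Ordinal code for each state, in state order.
CLASS_CODES = {"I": 0.0, "II": 0.5, "III": 1.0}

DNN_LAYERS = (4, 10, 17, 1)


@dataclass
class ModelSpec:
    """Which classifier to fit, with its (documented-default) hyperparameters."""

    kind: str = "dnn"  # lr | svm | dt | dnn
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)
    dnn_layers: tuple = DNN_LAYERS
    target: str = "state"  # state (ordinal codes) | eacl (EACL/100 regression)

    def __post_init__(self):
        self.kind = self.kind.lower()
        if self.kind not in ("lr", "svm", "dt", "dnn"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.target not in ("state", "eacl"):
            raise ConfigurationError(f"unknown target {self.target!r}")


@dataclass
class SplitPlan:
    train_frac: float = 0.8
    seed: int = 0
    stratify_by: str = "state"  # state | none
    grouping: str = "record"  # record | case

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ConfigurationError("train_frac must be in (0, 1)")
        if self.stratify_by not in ("state", "none"):
            raise ConfigurationError("stratify_by must be 'state' or 'none'")
        if self.grouping not in ("record", "case"):
            raise ConfigurationError("grouping must be 'record' or 'case'")


@dataclass
class Dataset:
    """Feature matrix (n x 4: hf, lf, hf_lf, sampen) with labels and metadata."""

    features: np.ndarray
    labels: np.ndarray
    eacl: np.ndarray
    case_ids: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.eacl = np.asarray(self.eacl, dtype=float)
        self.case_ids = np.asarray(self.case_ids)
        n = self.features.shape[0]
        if self.features.ndim != 2 or self.features.shape[1] != 4:
            raise DataError(f"features must be n x 4, got {self.features.shape}")
        if not (len(self.labels) == len(self.eacl) == len(self.case_ids) == n):
            raise DataError("all dataset columns must share length")
        if not np.all(np.isfinite(self.features)):
            raise DataError("dataset contains non-finite features; drop them first")

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.features[idx], self.labels[idx], self.eacl[idx], self.case_ids[idx])


def dataset_from_features(df: pd.DataFrame) -> Dataset:
    """Build a Dataset from a feature table, dropping non-finite rows."""
    cols = ["hf_ms2", "lf_ms2", "hf_lf_ratio", "sampen"]
    missing = [c for c in cols + ["state", "case_id"] if c not in df.columns]
    if missing:
        raise DataError(f"feature table missing columns: {missing}")
    X = df[cols].to_numpy(dtype=float)
    ok = np.all(np.isfinite(X), axis=1)
    if "eacl" in df.columns:
        eacl = df["eacl"].to_numpy(dtype=float)
    else:
        eacl = np.full(len(df), np.nan)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} rows with missing features", stacklevel=2)
    return Dataset(X[ok], df["state"].to_numpy()[ok], eacl[ok], df["case_id"].to_numpy()[ok])


def derive_labels(timeline: AnaesthesiaTimeline, window_centres) -> np.ndarray:
    """State label at each window centre; boundaries are half-open (later state)."""
    centres = np.asarray(window_centres, dtype=float)
    return np.array([timeline.state_at(t) for t in centres])


def split_dataset(data: Dataset, plan: SplitPlan):
    """Deterministic train/test split; |train| = round(train_frac * n)."""
    n = len(data)
    if n < 10:
        raise DataError("need at least 10 records to split")
    n_train = int(round(plan.train_frac * n))
    if plan.grouping == "case":
        rng = np.random.default_rng(plan.seed)
        cases = np.unique(data.case_ids)
        rng.shuffle(cases)
        n_train_cases = max(int(round(plan.train_frac * cases.size)), 1)
        train_cases = set(cases[:n_train_cases])
        mask = np.array([c in train_cases for c in data.case_ids])
        train, test = data.subset(mask), data.subset(~mask)
    else:
        idx = np.arange(n)
        stratify = data.labels if plan.stratify_by == "state" else None
        tr, te = train_test_split(
            idx, train_size=n_train, random_state=plan.seed, stratify=stratify
        )
        train, test = data.subset(np.sort(tr)), data.subset(np.sort(te))
    for part, name in ((train, "train"), (test, "test")):
        present = set(np.unique(part.labels))
        if not set(STATES) <= present:
            warnings.warn(f"{name} partition missing states {set(STATES) - present}", stacklevel=2)
    return train, test


class MLPNetwork:
    """Fully connected network with ReLU hidden layers and one linear output.

    Trained by mini-batch Adam on mean-squared error. The default 4-10-17-1
    architecture has 4·10+10 + 10·17+17 + 17·1+1 = 245 trainable parameters.
    """

    def __init__(self, layers=DNN_LAYERS, seed=0, lr=0.01, epochs=200, batch_size=256):
        self.layers = tuple(int(w) for w in layers)
        self.seed = seed
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        rng = np.random.default_rng(seed)
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(self.layers[:-1], self.layers[1:]):
            # He initialisation for the ReLU stack
            self.weights.append(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.loss_history = []

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def _forward(self, X):
        acts = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.weights) - 1 else z
            acts.append(a)
        return acts

    def predict_raw(self, X) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1].ravel()

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        n = X.shape[0]
        rng = np.random.default_rng(self.seed + 1)
        mw = [np.zeros_like(w) for w in self.weights]
        vw = [np.zeros_like(w) for w in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s0 in range(0, n, self.batch_size):
                idx = order[s0 : s0 + self.batch_size]
                xb, yb = X[idx], y[idx]
                acts = self._forward(xb)
                out = acts[-1]
                err = out - yb
                epoch_loss += float(np.sum(err**2))
                # backprop: MSE loss, linear output layer
                delta = 2.0 * err / xb.shape[0]
                grads_w, grads_b = [None] * len(self.weights), [None] * len(self.biases)
                for i in reversed(range(len(self.weights))):
                    grads_w[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.weights[i].T) * (acts[i] > 0)
                step += 1
                for i in range(len(self.weights)):
                    for g, m, v, p in (
                        (grads_w[i], mw, vw, self.weights),
                        (grads_b[i], mb, vb, self.biases),
                    ):
                        m[i] = beta1 * m[i] + (1 - beta1) * g
                        v[i] = beta2 * v[i] + (1 - beta2) * g**2
                        mhat = m[i] / (1 - beta1**step)
                        vhat = v[i] / (1 - beta2**step)
                        p[i] = p[i] - self.lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(epoch_loss / n)
        return self


@dataclass
class FittedModel:
    """A trained classifier plus the training-partition standardization."""

    spec: ModelSpec
    estimator: object
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    decode_codes: dict | None = None  # state -> score code (DNN only)

    def standardize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise DataError(f"expected n x 4 feature matrix, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite features passed to predict")
        return (X - self.feat_mean) / self.feat_scale


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "lr":
        return LogisticRegression(max_iter=hp.pop("max_iter", 2000), C=hp.pop("C", 1.0),
                                  random_state=spec.seed)
    if spec.kind == "svm":
        return OneVsRestClassifier(
            SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"),
                cache_size=500, random_state=spec.seed)
        )
    if spec.kind == "dt":
        return DecisionTreeClassifier(
            max_depth=hp.pop("max_depth", 8), criterion=hp.pop("criterion", "gini"),
            random_state=spec.seed,
        )
    return MLPNetwork(
        layers=spec.dnn_layers, seed=spec.seed,
        lr=hp.pop("lr", 0.01), epochs=hp.pop("epochs", 200),
        batch_size=hp.pop("batch_size", 256),
    )


def train(spec: ModelSpec, data: Dataset) -> FittedModel:
    """Fit one classifier on a training partition.

    Features are z-scored with training statistics (stored on the fitted
    model). All three states must be present; a zero-variance feature column
    is a validation error.
    """
    if len(data) == 0:
        raise DataError("empty training set")
    present = set(np.unique(data.labels))
    if not set(STATES) <= present:
        raise DataError(f"training set missing states {set(STATES) - present}")
    mean = data.features.mean(axis=0)
    scale = data.features.std(axis=0)
    if np.any(scale == 0):
        raise DataError("a feature column is constant; cannot standardize")
    X = (data.features - mean) / scale
    est = _build_estimator(spec)
    decode = None
    if spec.kind == "dnn":
        if spec.target == "eacl":
            if np.any(~np.isfinite(data.eacl)):
                raise DataError("EACL target mode requires finite EACL values")
            y = data.eacl / 100.0
            est.fit(X, y)
            raw = est.predict_raw(X)
            decode = {s: float(np.mean(raw[data.labels == s])) for s in STATES}
        else:
            y = np.array([CLASS_CODES[s] for s in data.labels])
            est.fit(X, y)
            decode = dict(CLASS_CODES)
    else:
        est.fit(X, data.labels)
    return FittedModel(spec=spec, estimator=est, feat_mean=mean, feat_scale=scale,
                       decode_codes=decode)


def decode_scores(raw: np.ndarray, codes: dict) -> np.ndarray:
    """Map scalar network outputs to states by nearest code, ties to lower state."""
    states = list(STATES)
    code_vec = np.array([codes[s] for s in states])
    dists = np.abs(raw[:, None] - code_vec[None, :])
    # ties: argmin takes the first (lower state index) minimum
    return np.array([states[i] for i in np.argmin(dists, axis=1)])


def predict(model: FittedModel, features) -> tuple:
    """Predict state labels; returns (labels, raw_scores) — scores None unless DNN."""
    X = model.standardize(features)
    if model.spec.kind == "dnn":
        raw = model.estimator.predict_raw(X)
        return decode_scores(raw, model.decode_codes), raw
    return model.estimator.predict(X), None


def cross_validate(data: Dataset, specs: list, k: int = 5, seed: int = 0) -> list:
    """Paired stratified k-fold: every model sees identical fold splits.

    Returns a list of per-fold dicts ``{model_kind: EvalReport}``.
    """
    from .evaluation import confusion, metrics

    if k < 2:
        raise ConfigurationError("k must be >= 2")
    _, counts = np.unique(data.labels, return_counts=True)
    if k > counts.min():
        raise ConfigurationError(f"k={k} exceeds smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(data.features, data.labels))
    reports = []
    for tr, te in folds:
        fold_report = {}
        train_part, test_part = data.subset(tr), data.subset(te)
        for spec in specs:
            model = train(spec, train_part)
            pred, _ = predict(model, test_part.features)
            fold_report[spec.kind] = metrics(confusion(test_part.labels, pred),
                                             model_kind=spec.kind)
        reports.append(fold_report)
    return reports


def save_model(model: FittedModel, path):
    """Serialize a fitted model. The DNN goes to pure JSON; scikit-learn
    estimators are stored via joblib next to the JSON manifest."""
    import joblib

    path = str(path)
    manifest = {
        "kind": model.spec.kind,
        "seed": model.spec.seed,
        "target": model.spec.target,
        "dnn_layers": list(model.spec.dnn_layers),
        "hyperparameters": model.spec.hyperparameters,
        "feat_mean": model.feat_mean.tolist(),
        "feat_scale": model.feat_scale.tolist(),
        "decode_codes": model.decode_codes,
    }
    if model.spec.kind == "dnn":
        manifest["weights"] = [w.tolist() for w in model.estimator.weights]
        manifest["biases"] = [b.tolist() for b in model.estimator.biases]
        manifest["dnn_config"] = {
            "lr": model.estimator.lr,
            "epochs": model.estimator.epochs,
            "batch_size": model.estimator.batch_size,
        }
    else:
        manifest["estimator_file"] = path + ".joblib"
        joblib.dump(model.estimator, manifest["estimator_file"])
    with open(path, "w") as fh:
        json.dump(manifest, fh)


def load_model(path) -> FittedModel:
    import joblib

    with open(path) as fh:
        manifest = json.load(fh)
    spec = ModelSpec(
        kind=manifest["kind"], seed=manifest["seed"], target=manifest["target"],
        dnn_layers=tuple(manifest["dnn_layers"]),
        hyperparameters=manifest.get("hyperparameters", {}),
    )
    if spec.kind == "dnn":
        cfg = manifest["dnn_config"]
        est = MLPNetwork(layers=spec.dnn_layers, seed=spec.seed, **cfg)
        est.weights = [np.array(w) for w in manifest["weights"]]
        est.biases = [np.array(b) for b in manifest["biases"]]
    else:
        est = joblib.load(manifest["estimator_file"])
    return FittedModel(
        spec=spec, estimator=est,
        feat_mean=np.array(manifest["feat_mean"]),
        feat_scale=np.array(manifest["feat_scale"]),
        decode_codes=manifest.get("decode_codes"),
    )
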