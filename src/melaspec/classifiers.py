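"""From-scratch binary classifiers: Gaussian naive Bayes, k-NN and a small
back-propagation network.

All three share one contract: :func:`train` consumes a labelled feature table
and a :class:`ClassifierSpec` and returns a :class:`TrainedModel`;
:func:`predict` maps a feature table to labels in {+1 melanoma, -1 benign}
plus per-class scores.  Everything is bit-deterministic given (data, spec).

Configurations mirror the classic defaults of desktop machine-learning
toolkits of the era this pipeline targets:

* **naive Bayes** — one Gaussian per feature per class (population SD), class
  priors equal to class frequencies.  Each feature's SD is floored at
  ``precision / 6`` where *precision* is the mean gap between consecutive
  distinct sorted training values of that feature, so a feature that is
  constant within a class cannot collapse the likelihood.
* **k-NN** — brute-force Euclidean search, majority vote among the k nearest
  (default k = 3), distance ties broken by training order.  Features are
  min-max scaled to [0, 1] using training ranges.
* **MLP** — fully connected 10 -> hidden (default 6) -> 2 network, sigmoid
  units throughout, inputs min-max scaled to [0, 1], one-hot targets, weights
  initialized uniformly in [-0.5, 0.5] from the seed, trained by per-sample
  (online) back-propagation with momentum for a fixed number of epochs
  (default learning rate 0.3, momentum 0.2, 500 epochs), samples visited in
  table order.

Prediction ties (exactly equal scores) resolve to benign: the clinically
conservative default is handled explicitly rather than left to argmax order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scan_io import (BENIGN, FEATURE_COLUMNS, LABEL_TO_CODE, MELANOMA,
                      read_model_file, write_model_file)

__all__ = ["ClassifierSpec", "TrainedModel", "train", "predict",
           "save_model", "load_model"]

#: Fixed class order: positive (melanoma) first.
CLASSES = (MELANOMA, BENIGN)

#: Fallback numeric precision when a feature has < 2 distinct values.
_DEFAULT_PRECISION = 0.01


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus its hyperparameters.

    ``scale_features`` defaults to on for knn and mlp (both are sensitive to
    feature ranges) and off for nb (per-feature Gaussians are scale-free).
    """

    kind: str = "nb"                 # nb | knn | mlp
    knn_k: int = 3
    mlp_hidden: int = 6
    mlp_learning_rate: float = 0.3
    mlp_momentum: float = 0.2
    mlp_epochs: int = 500
    seed: int = 0
    scale_features: bool | None = None   # None -> kind-dependent default
    nb_sd_floor_divisor: float = 6.0     # sd floor = precision / divisor

    def __post_init__(self) -> None:
        if self.kind not in ("nb", "knn", "mlp"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValidationError(f"knn_k must be odd and >= 1, got {self.knn_k}")
        if self.mlp_hidden < 1 or self.mlp_epochs < 0:
            raise ValidationError("mlp_hidden must be >= 1 and mlp_epochs >= 0")
        if self.mlp_learning_rate < 0 or self.mlp_momentum < 0:
            raise ValidationError("mlp learning rate and momentum must be >= 0")

    @property
    def scaling(self) -> bool:
        if self.scale_features is None:
            return self.kind in ("knn", "mlp")
        return self.scale_features


@dataclass
class TrainedModel:
    """A fitted classifier: the spec plus kind-specific parameter arrays."""

    spec: ClassifierSpec
    n_features: int
    parameters: dict = field(default_factory=dict)
    classes: tuple[int, int] = CLASSES


# ---------------------------------------------------------------------------
# feature-table plumbing

def _extract_xy(features: pd.DataFrame | np.ndarray,
                labels: Sequence[int] | None = None,
                require_labels: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c in FEATURE_COLUMNS]
        if not cols:  # arbitrary numeric table: use all non-meta columns
            cols = [c for c in features.columns if c not in ("sample_id", "label")]
        X = features[cols].to_numpy(dtype=float)
        if labels is None and "label" in features.columns:
            labels = [LABEL_TO_CODE.get(v, v) for v in features["label"]]
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"feature matrix must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    y = None
    if labels is not None:
        y = np.asarray(list(labels), dtype=int)
        if len(y) != len(X):
            raise ValidationError(
                f"{len(y)} labels for {len(X)} feature rows")
    elif require_labels:
        raise ValidationError("training requires labels (a 'label' column or "
                              "an explicit labels argument)")
    return X, y


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = X.min(axis=0), X.max(axis=0)
    return lo, hi


def _apply_scaler(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(X, dtype=float)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out  # constant training features map to 0


# ---------------------------------------------------------------------------
# naive Bayes

def _feature_precision(values: np.ndarray) -> float:
    """Mean gap between consecutive distinct sorted values of one feature."""
    distinct = np.unique(values)
    if len(distinct) < 2:
        return _DEFAULT_PRECISION
    return float((distinct[-1] - distinct[0]) / (len(distinct) - 1))


def _train_nb(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> dict:
    n, d = X.shape
    precision = np.array([_feature_precision(X[:, j]) for j in range(d)])
    sd_floor = precision / spec.nb_sd_floor_divisor
    priors, means, sds = [], [], []
    for cls in CLASSES:
        Xc = X[y == cls]
        priors.append(len(Xc) / n)
        mu = Xc.mean(axis=0)
        sd = np.sqrt(np.mean((Xc - mu) ** 2, axis=0))
        means.append(mu)
        sds.append(np.maximum(sd, sd_floor))
    return {
        "priors": np.array(priors),          # order: (+1, -1)
        "means": np.array(means),            # (2, d)
        "sds": np.array(sds),                # (2, d), floored
        "precision": precision,              # (d,)
    }


def _nb_log_joint(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    p = model.parameters
    means, sds, priors = p["means"], p["sds"], p["priors"]
    out = np.empty((len(X), 2))
    for c in range(2):
        z = (X - means[c]) / sds[c]
        log_dens = -0.5 * z * z - np.log(sds[c] * np.sqrt(2 * np.pi))
        out[:, c] = np.log(priors[c]) + log_dens.sum(axis=1)
    return out


def _predict_nb(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    log_joint = _nb_log_joint(model, X)
    shifted = log_joint - log_joint.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.where(post[:, 0] > post[:, 1], MELANOMA, BENIGN)
    return labels, post


# ---------------------------------------------------------------------------
# k nearest neighbours

def _train_knn(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> dict:
    if spec.knn_k > len(X):
        raise ValidationError(
            f"knn_k={spec.knn_k} exceeds training-set size {len(X)}")
    return {"X": X, "y": y}


def _predict_knn(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    train_X, train_y = model.parameters["X"], model.parameters["y"]
    k = model.spec.knn_k
    labels = np.empty(len(X), dtype=int)
    scores = np.empty((len(X), 2))
    for i, q in enumerate(X):
        dist = np.sqrt(((train_X - q) ** 2).sum(axis=1))
        order = np.argsort(dist, kind="stable")  # distance ties: training order
        votes = train_y[order[:k]]
        frac_pos = np.mean(votes == MELANOMA)
        scores[i] = (frac_pos, 1.0 - frac_pos)
        labels[i] = MELANOMA if frac_pos > 0.5 else BENIGN
    return labels, scores


# ---------------------------------------------------------------------------
# multilayer perceptron

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _train_mlp(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> dict:
    n, d = X.shape
    h = spec.mlp_hidden
    rng = np.random.default_rng(spec.seed)
    # Weight layout: W1 (h, d) + b1 (h,); W2 (2, h) + b2 (2,)
    W1 = rng.uniform(-0.5, 0.5, size=(h, d))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    W2 = rng.uniform(-0.5, 0.5, size=(2, h))
    b2 = rng.uniform(-0.5, 0.5, size=2)
    dW1 = np.zeros_like(W1); db1 = np.zeros_like(b1)
    dW2 = np.zeros_like(W2); db2 = np.zeros_like(b2)

    # one-hot targets in class order (+1, -1)
    T = np.stack([(y == MELANOMA).astype(float), (y == BENIGN).astype(float)], axis=1)
    lr, mom = spec.mlp_learning_rate, spec.mlp_momentum

    for _ in range(spec.mlp_epochs):
        for x, t in zip(X, T):          # online updates, table order
            hid = _sigmoid(W1 @ x + b1)
            out = _sigmoid(W2 @ hid + b2)
            # squared-error deltas for sigmoid units
            delta_out = (t - out) * out * (1.0 - out)
            delta_hid = hid * (1.0 - hid) * (W2.T @ delta_out)
            dW2 = lr * np.outer(delta_out, hid) + mom * dW2
            db2 = lr * delta_out + mom * db2
            dW1 = lr * np.outer(delta_hid, x) + mom * dW1
            db1 = lr * delta_hid + mom * db1
            W2 += dW2; b2 += db2; W1 += dW1; b1 += db1
    return {"W1": W1, "b1": b1, "W2": W2, "b2": b2}


def _predict_mlp(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = model.parameters
    hid = _sigmoid(X @ p["W1"].T + p["b1"])
    out = _sigmoid(hid @ p["W2"].T + p["b2"])
    labels = np.where(out[:, 0] > out[:, 1], MELANOMA, BENIGN)
    return labels, out


# ---------------------------------------------------------------------------
# public contract

_TRAINERS = {"nb": _train_nb, "knn": _train_knn, "mlp": _train_mlp}
_PREDICTORS = {"nb": _predict_nb, "knn": _predict_knn, "mlp": _predict_mlp}


def train(features: pd.DataFrame | np.ndarray, spec: ClassifierSpec,
          labels: Sequence[int] | None = None) -> TrainedModel:
    """Fit a classifier on a labelled feature table.

    ``features`` is either the feature-table DataFrame (with a ``label``
    column) or a plain (n, d) array with ``labels`` given separately.  Both
    classes must be present.
    """
    X, y = _extract_xy(features, labels)
    present = set(np.unique(y))
    if not {MELANOMA, BENIGN} <= present:
        raise ValidationError(
            f"training set must contain both classes (+1 and -1), got {sorted(present)}")
    if present - {MELANOMA, BENIGN}:
        raise ValidationError(f"unknown label(s) in training set: "
                              f"{sorted(present - {MELANOMA, BENIGN})}")

    params: dict = {}
    if spec.scaling:
        lo, hi = _fit_scaler(X)
        params["scale_lo"], params["scale_hi"] = lo, hi
        X = _apply_scaler(X, lo, hi)
    params.update(_TRAINERS[spec.kind](X, y, spec))
    return TrainedModel(spec=spec, n_features=X.shape[1], parameters=params)


def predict(model: TrainedModel, features: pd.DataFrame | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels for a feature table.

    Returns ``(labels, scores)`` where labels are in {+1, -1} and scores is
    an (n, 2) array of per-class scores in class order (melanoma, benign):
    posterior probabilities for nb, vote fractions for knn, output
    activations for mlp.  Exact score ties resolve to benign.
    """
    X, _ = _extract_xy(features, require_labels=False)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"model expects {model.n_features} features, got {X.shape[1]}")
    if model.spec.scaling:
        X = _apply_scaler(X, model.parameters["scale_lo"],
                          model.parameters["scale_hi"])
    return _PREDICTORS[model.spec.kind](model, X)


# ---------------------------------------------------------------------------
# model files

def save_model(model: TrainedModel, path) -> None:
    """Serialize a model to the self-describing text format."""
    params = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
              for k, v in model.parameters.items()}
    payload = {
        "format": "melaspec-model/1",
        "kind": model.spec.kind,
        "classes": list(model.classes),
        "n_features": model.n_features,
        "spec": asdict(model.spec),
        "parameters": params,
    }
    write_model_file(payload, path)


def load_model(path) -> TrainedModel:
    payload = read_model_file(path)
    spec = ClassifierSpec(**payload["spec"])
    params = {k: (np.array(v) if isinstance(v, list) else v)
              for k, v in payload["parameters"].items()}
    if "y" in params:
        params["y"] = params["y"].astype(int)
    return TrainedModel(spec=spec, n_features=payload["n_features"],
                        parameters=params, classes=tuple(payload["classes"]))
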