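"""Repeated random-split evaluation: splits, confusion metrics, aggregation.

The evaluation protocol draws a train/test partition of the cohort by random
sampling without replacement (default: stratified so that class proportions
are preserved in the training set), trains a classifier on the training
rows, predicts the test rows and records sensitivity / specificity /
accuracy; this is repeated (default 25 times) and the per-run metrics are
averaged.  Melanoma (+1) is the positive class throughout:

    sensitivity = 100 * tp / (tp + fn)      (true-positive rate, melanoma)
    specificity = 100 * tn / (tn + fp)      (true-negative rate, benign)
    accuracy    = 100 * (tp + tn) / total

Under stratification of a 19:168 cohort with 60 training cases, every test
set contains exactly 13 melanoma cases, so every achievable sensitivity is an
integer multiple of 100/13.

Feature ablation: an experiment can use the 5 P-scan columns alone (``p``),
the 5 V-scan columns alone (``v``) or all 10 (``pv``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, predict, train
from .exceptions import ValidationError
from .scan_io import BENIGN, FEATURE_COLUMNS, LABEL_TO_CODE, MELANOMA

__all__ = ["SplitSpec", "Metrics", "EvalReport", "split", "compute_metrics",
           "aggregate", "run_experiment", "round1", "FEATURE_SETS"]

FEATURE_SETS = {
    "p": [c for c in FEATURE_COLUMNS if c.startswith("p_")],
    "v": [c for c in FEATURE_COLUMNS if c.startswith("v_")],
    "pv": list(FEATURE_COLUMNS),
}


def round1(x: float) -> float:
    """Round half-up to one decimal, the rendering used in report tables."""
    if math.isnan(x):
        return x
    return math.floor(x * 10 + 0.5) / 10


@dataclass(frozen=True)
class SplitSpec:
    """Repeated random-split protocol parameters."""

    n_train: int
    repetitions: int = 25
    seed: int = 0
    stratified: bool = True
    feature_set: str = "pv"

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValidationError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.feature_set not in FEATURE_SETS:
            raise ValidationError(
                f"feature_set must be one of {sorted(FEATURE_SETS)}, "
                f"got {self.feature_set!r}")


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived rates for one evaluation run.

    Rates are percentages; a rate whose denominator class is absent from the
    truth is NaN (flagged, never silently 0).
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    error_rate: float

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "Metrics":
        pos, neg = tp + fn, tn + fp
        if pos + neg < 1:
            raise ValidationError("empty confusion table")
        sens = 100.0 * tp / pos if pos else float("nan")
        spec = 100.0 * tn / neg if neg else float("nan")
        acc = 100.0 * (tp + tn) / (pos + neg)
        return cls(tp=tp, fn=fn, tn=tn, fp=fp, sensitivity=sens,
                   specificity=spec, accuracy=acc, error_rate=1.0 - acc / 100.0)

    @property
    def undefined(self) -> list[str]:
        """Names of metrics undefined because a class is absent from truth."""
        out = []
        if self.tp + self.fn == 0:
            out.append("sensitivity")
        if self.tn + self.fp == 0:
            out.append("specificity")
        return out


def compute_metrics(predicted, truth) -> Metrics:
    """Confusion metrics of predicted vs. true labels; melanoma is positive."""
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValidationError(
            f"predicted and truth must be equal-length 1-D label arrays "
            f"of length >= 1, got {pred.shape} and {true.shape}")
    bad = set(np.unique(np.concatenate([pred, true]))) - {MELANOMA, BENIGN}
    if bad:
        raise ValidationError(f"labels must be +1 or -1, found {sorted(bad)}")
    tp = int(np.sum((pred == MELANOMA) & (true == MELANOMA)))
    fn = int(np.sum((pred == BENIGN) & (true == MELANOMA)))
    tn = int(np.sum((pred == BENIGN) & (true == BENIGN)))
    fp = int(np.sum((pred == MELANOMA) & (true == BENIGN)))
    return Metrics.from_counts(tp, fn, tn, fp)


def split(sample_ids: list, spec: SplitSpec, run_index: int,
          labels: list | None = None) -> tuple[list, list]:
    """Partition sample ids into disjoint, exhaustive train and test sets.

    Randomness comes from an independent substream derived from
    ``(spec.seed, run_index)`` so each repetition is individually
    reproducible.  Stratified mode draws per-class training counts that
    preserve the cohort's class proportions (rounded to integers); it
    requires ``labels`` aligned with ``sample_ids``.
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("sample ids must be unique")
    n = len(ids)
    if not 1 <= spec.n_train < n:
        raise ValidationError(
            f"n_train must be in [1, {n - 1}] for a cohort of {n}, "
            f"got {spec.n_train}")
    rng = np.random.default_rng([spec.seed, run_index])
    if not spec.stratified:
        perm = rng.permutation(n)
        train_ids = [ids[i] for i in perm[:spec.n_train]]
        test_ids = [ids[i] for i in perm[spec.n_train:]]
        return train_ids, test_ids

    if labels is None:
        raise ValidationError("stratified split requires labels")
    y = np.asarray(list(labels))
    if len(y) != n:
        raise ValidationError(f"{len(y)} labels for {n} sample ids")
    # training count per class: proportional, rounded half-up; the remainder
    # goes to the other class so the total is exact
    classes = sorted(set(y.tolist()), reverse=True)  # (+1, -1) order
    n_first = int(math.floor(spec.n_train * np.sum(y == classes[0]) / n + 0.5))
    counts = {classes[0]: n_first}
    if len(classes) > 1:
        counts[classes[1]] = spec.n_train - n_first
    train_ids = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        take = counts[cls]
        if not 0 <= take <= len(idx):
            raise ValidationError(
                f"stratified split needs {take} training samples of class "
                f"{cls} but the cohort has {len(idx)}")
        chosen = idx[rng.permutation(len(idx))[:take]]
        train_ids.extend(ids[i] for i in chosen)
    train_set = set(train_ids)
    test_ids = [i for i in ids if i not in train_set]
    return train_ids, test_ids


def aggregate(per_run: list[Metrics] | pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean of sensitivity / specificity / accuracy over runs.

    Accepts a list of :class:`Metrics` or a DataFrame with columns
    ``sensitivity, specificity, accuracy`` (e.g. a published per-run table).
    Means are returned at full precision; use :func:`round1` to render them
    at the one-decimal table precision.
    """
    if isinstance(per_run, pd.DataFrame):
        df = per_run
    else:
        if len(per_run) == 0:
            raise ValidationError("cannot aggregate an empty run list")
        df = pd.DataFrame([{"sensitivity": m.sensitivity,
                            "specificity": m.specificity,
                            "accuracy": m.accuracy} for m in per_run])
    if len(df) == 0:
        raise ValidationError("cannot aggregate an empty run list")
    return {col: float(df[col].mean())
            for col in ("sensitivity", "specificity", "accuracy")}


@dataclass
class EvalReport:
    """Per-run metrics, their averages, and the configuration that made them."""

    per_run: list[Metrics]
    averages: dict[str, float]
    split_spec: SplitSpec
    classifier_spec: ClassifierSpec
    notes: dict = field(default_factory=dict)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Report table: one row per run plus an Average row, rendered at one
        decimal (half-up) like the published tables unless ``rounded=False``."""
        rows = []
        fmt = round1 if rounded else (lambda x: x)
        for i, m in enumerate(self.per_run, start=1):
            rows.append({"run": f"Run #{i}", "sensitivity": fmt(m.sensitivity),
                         "specificity": fmt(m.specificity),
                         "accuracy": fmt(m.accuracy)})
        rows.append({"run": "Average",
                     "sensitivity": fmt(self.averages["sensitivity"]),
                     "specificity": fmt(self.averages["specificity"]),
                     "accuracy": fmt(self.averages["accuracy"])})
        return pd.DataFrame(rows)


def run_experiment(features: pd.DataFrame, classifier_spec: ClassifierSpec,
                   split_spec: SplitSpec) -> EvalReport:
    """Repeated random-split evaluation of one classifier on a feature table.

    ``features`` is the labelled feature table produced by
    :func:`melaspec.features.featurize_cohort`.  For each repetition the
    cohort is split, the classifier is trained on the training rows
    (restricted to the configured feature set) and evaluated on the test
    rows.  Fully reproducible from (data, specs, seed).
    """
    df = features.reset_index(drop=True)
    if "label" not in df.columns or "sample_id" not in df.columns:
        raise ValidationError("feature table must have sample_id and label columns")
    y = np.array([LABEL_TO_CODE.get(v, v) for v in df["label"]], dtype=int)
    if not {MELANOMA, BENIGN} <= set(y.tolist()):
        raise ValidationError("experiment requires a labelled cohort with both classes")
    cols = FEATURE_SETS[split_spec.feature_set]
    ids = df["sample_id"].tolist()
    pos = {sid: i for i, sid in enumerate(ids)}

    per_run = []
    for rep in range(split_spec.repetitions):
        try:
            train_ids, test_ids = split(ids, split_spec, rep, labels=y)
            tr = [pos[s] for s in train_ids]
            te = [pos[s] for s in test_ids]
            model = train(df.loc[tr, cols].to_numpy(dtype=float),
                          classifier_spec, labels=y[tr])
            pred, _ = predict(model, df.loc[te, cols].to_numpy(dtype=float))
            per_run.append(compute_metrics(pred, y[te]))
        except Exception as exc:
            raise type(exc)(f"repetition {rep + 1} failed: {exc}") from exc
    return EvalReport(per_run=per_run, averages=aggregate(per_run),
                      split_spec=split_spec, classifier_spec=classifier_spec)
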