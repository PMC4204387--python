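"""End-to-end workflows: single-subject diagnosis and the full simulated study.

:func:`diagnose` mirrors the clinical desktop workflow: load a subject's six
scans (p1, p2, p3, v1, v2, v3), run preprocessing and feature extraction,
classify with a trained model (naive Bayes on the combined P+V features by
default) and return a benign/melanoma call with per-class scores.  It adds
no computation beyond ``predict(model, build_feature_vector(sample))``.

:func:`run_full_pipeline` executes the whole simulated study from one YAML
config: simulate a cohort, featurize it, train a classifier and evaluate it
with repeated random splits, writing every artifact plus a config snapshot
into a run directory.  Re-running the same config reproduces report and
model byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .classifiers import ClassifierSpec, TrainedModel, predict, save_model, train
from .cohort import CohortSpec, generate_cohort, write_cohort
from .evaluation import SplitSpec, run_experiment
from .exceptions import FormatError, MelaspecError
from .features import build_feature_vector, featurize_cohort
from .scan_io import (CODE_TO_LABEL, MELANOMA, SCAN_SLOTS, SampleRecord,
                      read_scan, _SLOT_META, _layout_for)

logger = logging.getLogger("melaspec")

__all__ = ["Diagnosis", "diagnose", "run_full_pipeline", "DEFAULT_CONFIG"]


@dataclass
class Diagnosis:
    """The outcome of one diagnostic run on a subject's six scans."""

    sample_id: str
    call: str                      # "melanoma" | "benign"
    scores: dict[str, float]       # per-class scores, classifier-specific
    model_id: str
    comment: str = ""


def diagnose(scan_paths: dict[str, str | Path], model: TrainedModel,
             window=3, sample_id: str = "subject", comment: str = "",
             n_rows: int = 32, n_cols: int = 512) -> Diagnosis:
    """Classify one subject from the six scan files.

    ``scan_paths`` must map every slot in ``p1, p2, p3, v1, v2, v3`` to a
    readable scan file; a missing or unreadable slot raises an error naming
    it.  The model must have been trained on the combined 10-feature (P+V)
    vector.
    """
    scans = {}
    for slot in SCAN_SLOTS:
        if slot not in scan_paths or not scan_paths[slot]:
            raise FormatError(f"no scan provided for slot {slot}")
        path = Path(scan_paths[slot])
        pol, role = _SLOT_META[slot]
        try:
            scans[slot] = read_scan(path, layout=_layout_for(path),
                                    n_rows=n_rows, n_cols=n_cols,
                                    polarization=pol, spot_role=role)
        except MelaspecError as exc:
            raise type(exc)(f"slot {slot}: {exc}") from exc
        logger.info("loaded %s scan for slot %s from %s", pol, slot, path)

    sample = SampleRecord(sample_id=sample_id, scans=scans)
    fv = build_feature_vector(sample, window)
    logger.info("extracted 10-feature vector for %s", sample_id)
    import numpy as np
    labels, scores = predict(model, np.array([fv.values]))
    call = "melanoma" if labels[0] == MELANOMA else "benign"
    logger.info("classification for %s: %s (scores %s)", sample_id, call, scores[0])
    return Diagnosis(sample_id=sample_id, call=call,
                     scores={"melanoma": float(scores[0][0]),
                             "benign": float(scores[0][1])},
                     model_id=f"{model.spec.kind}-pv", comment=comment)


DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_melanoma": 19, "n_benign": 168, "n_rows": 32, "n_cols": 512,
        "peak_row": 15, "effect_size": 1.0, "noise_rate": 0.002,
        "subject_shift_sd": 0.15, "seed": 0,
    },
    "preprocess": {"window": 3},
    "train": {"classifier": "nb", "seed": 0},
    "evaluate": {"n_train": 60, "repetitions": 25, "seed": 0,
                 "stratified": True, "feature_set": "pv"},
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for section, values in (override or {}).items():
        if section not in out:
            raise MelaspecError(f"unknown config section {section!r}")
        unknown = set(values) - set(out[section])
        if unknown:
            raise MelaspecError(
                f"unknown key(s) {sorted(unknown)} in config section {section!r}")
        out[section].update(values)
    return out


def run_full_pipeline(config: str | Path | dict, out_dir: str | Path,
                      write_scans: bool = True) -> dict[str, Path]:
    """Simulate -> featurize -> train -> evaluate, all artifacts in one place.

    ``config`` is a YAML file path or an equivalent dict with sections
    ``simulate``, ``preprocess``, ``train`` and ``evaluate``; omitted keys
    take the documented defaults.  Returns a dict of artifact paths
    (manifest, features, model, report, config).
    """
    if isinstance(config, (str, Path)):
        loaded = yaml.safe_load(Path(config).read_text()) or {}
    else:
        loaded = config or {}
    cfg = _merge(DEFAULT_CONFIG, loaded)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        spec = CohortSpec(**cfg["simulate"])
        cohort = generate_cohort(spec)
        if write_scans:
            write_cohort(cohort, out_dir / "cohort")
            artifacts["manifest"] = out_dir / "cohort" / "manifest.csv"
    except Exception as exc:
        raise MelaspecError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("features")
        table = featurize_cohort(cohort, window=cfg["preprocess"]["window"])
        artifacts["features"] = out_dir / "features.csv"
        table.to_csv(artifacts["features"], index=False)
    except Exception as exc:
        raise MelaspecError(f"stage 'features' failed: {exc}") from exc

    try:
        stage("train")
        cspec = ClassifierSpec(kind=cfg["train"]["classifier"],
                               seed=cfg["train"]["seed"])
        model = train(table, cspec)
        artifacts["model"] = out_dir / f"model_{cspec.kind}.yaml"
        save_model(model, artifacts["model"])
    except Exception as exc:
        raise MelaspecError(f"stage 'train' failed: {exc}") from exc

    try:
        stage("evaluate")
        sspec = SplitSpec(**cfg["evaluate"])
        report = run_experiment(table, cspec, sspec)
        artifacts["report"] = out_dir / f"report_{cspec.kind}.csv"
        report.to_frame().to_csv(artifacts["report"], index=False)
    except Exception as exc:
        raise MelaspecError(f"stage 'evaluate' failed: {exc}") from exc

    artifacts["config"] = out_dir / "config_snapshot.yaml"
    artifacts["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    logger.info("pipeline complete; artifacts in %s", out_dir)
    return artifacts
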