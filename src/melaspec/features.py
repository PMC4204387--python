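"""Statistical features of corrected intensity images.

Each corrected image (one polarization of one sample) is summarised by five
statistics of its pixel values x over the m x n matrix (m*n = N pixels):

* mean           mu     = (1/N) * sum(x)
* standard dev.  sigma  = sqrt((1/N) * sum((x - mu)^2))   (population form)
* mean abs. dev. MAD    = (1/N) * sum(|x - mu|)
* L1 norm               = sum(|x|)
* L2 norm               = sqrt(sum(x^2))

The P-scan and V-scan statistics are concatenated into a 10-dimensional
feature vector in the fixed order
(p_mean, p_sd, p_mad, p_l1, p_l2, v_mean, v_sd, v_mad, v_l1, v_l2).
Statistics are computed on the signed corrected image — no clipping; the
absolute values and squares inside MAD and the norms handle the sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .preprocess import CorrectedImage, preprocess_sample
from .scan_io import CODE_TO_LABEL, FEATURE_COLUMNS, SampleRecord

__all__ = ["ScanStats", "FeatureVector", "scan_stats",
           "build_feature_vector", "featurize_cohort", "FEATURE_COLUMNS"]


@dataclass(frozen=True)
class ScanStats:
    """The five pixel statistics of one corrected image."""

    mean: float
    sd: float
    mad: float
    l1: float
    l2: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.mean, self.sd, self.mad, self.l1, self.l2)


@dataclass(frozen=True)
class FeatureVector:
    """The 10 statistics of one sample (5 per polarization) plus its label."""

    sample_id: str
    values: tuple[float, ...]
    label: int

    def __post_init__(self) -> None:
        if len(self.values) != 10 or not all(np.isfinite(self.values)):
            raise ValidationError(
                f"sample {self.sample_id}: feature vector must hold 10 finite "
                f"values, got {self.values!r}")


def scan_stats(corr: CorrectedImage | np.ndarray) -> ScanStats:
    """Compute mean, population SD, MAD, L1 and L2 of a corrected image."""
    x = corr.values if isinstance(corr, CorrectedImage) else np.asarray(corr, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute statistics of an empty matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("matrix contains non-finite values")
    mu = float(x.mean())
    dev = x - mu
    return ScanStats(
        mean=mu,
        sd=float(np.sqrt(np.mean(dev * dev))),
        mad=float(np.mean(np.abs(dev))),
        l1=float(np.sum(np.abs(x))),
        l2=float(np.sqrt(np.sum(x * x))),
    )


def build_feature_vector(sample: SampleRecord, window=3) -> FeatureVector:
    """Preprocess a six-scan sample and assemble its 10-feature vector."""
    corr_p, corr_v = preprocess_sample(sample, window)
    return FeatureVector(
        sample_id=sample.sample_id,
        values=scan_stats(corr_p).as_tuple() + scan_stats(corr_v).as_tuple(),
        label=sample.label,
    )


def featurize_cohort(cohort: list[SampleRecord], window=3) -> pd.DataFrame:
    """Feature table for a cohort, one row per sample in cohort order.

    Columns: ``sample_id, label`` (label as ``melanoma``/``benign``/
    ``unknown``) followed by the 10 feature columns.  Any per-sample failure
    is re-raised annotated with the sample_id.
    """
    rows = []
    for sample in cohort:
        try:
            fv = build_feature_vector(sample, window)
        except Exception as exc:
            raise type(exc)(f"featurization failed for sample "
                            f"{sample.sample_id}: {exc}") from exc
        rows.append([fv.sample_id, CODE_TO_LABEL[fv.label], *fv.values])
    return pd.DataFrame(rows, columns=["sample_id", "label", *FEATURE_COLUMNS])
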