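"""Published reference metrics from the original clinical evaluation.

The pipeline was originally evaluated on a clinical cohort of 187 samples
(19 melanoma, 168 benign) that is not publicly deposited.  What survives of
that evaluation are its summary tables; this module transcribes the per-run
naive-Bayes results (combined P+V features, 60 training / 127 test cases,
25 repetitions) so the aggregation arithmetic can be checked against them
and reports can be compared side by side.

Every sensitivity below is an integer multiple of 100/13 at one-decimal
rounding, the fingerprint of a constant 13 melanoma cases per test set —
i.e. of stratified splitting of the 19:168 cohort.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["clinical_nb_pv_runs", "RUN1_CONFUSION",
           "CLINICAL_N_MELANOMA", "CLINICAL_N_BENIGN"]

CLINICAL_N_MELANOMA = 19
CLINICAL_N_BENIGN = 168

#: (sensitivity, specificity, accuracy) per run, NB on P+V, 60/127 splits.
_NB_PV_RUNS = [
    (100.0, 86.0, 87.4),
    (76.9, 92.1, 90.6),
    (100.0, 91.2, 92.1),
    (84.6, 91.2, 90.6),
    (76.9, 88.6, 87.4),
    (92.3, 87.7, 88.2),
    (100.0, 87.7, 89.0),
    (100.0, 88.6, 89.8),
    (100.0, 87.7, 89.0),
    (100.0, 89.5, 90.6),
    (69.2, 89.5, 87.4),
    (76.9, 90.4, 89.0),
    (92.3, 89.5, 89.8),
    (92.3, 90.4, 90.6),
    (76.9, 88.6, 87.4),
    (76.9, 94.7, 92.9),
    (84.6, 89.5, 89.0),
    (100.0, 87.7, 89.0),
    (92.3, 87.7, 88.2),
    (84.6, 87.7, 87.4),
    (92.3, 90.4, 90.6),
    (100.0, 91.2, 92.1),
    (100.0, 85.1, 86.6),
    (100.0, 86.8, 88.2),
    (46.2, 93.0, 88.2),
]

#: Confusion counts (tp, fn, tn, fp) consistent with the first published run:
#: 13 melanoma test cases all detected, 16 of 114 benign misclassified.
RUN1_CONFUSION = (13, 0, 98, 16)


def clinical_nb_pv_runs() -> pd.DataFrame:
    """The 25 published per-run metrics as a DataFrame with columns
    ``run, sensitivity, specificity, accuracy`` (percentages, one-decimal
    precision as printed)."""
    df = pd.DataFrame(_NB_PV_RUNS,
                      columns=["sensitivity", "specificity", "accuracy"])
    df.insert(0, "run", [f"Run #{i}" for i in range(1, len(df) + 1)])
    return df
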