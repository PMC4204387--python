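"""The diagnostic workflow: six scan files in, a benign/melanoma call out.

This mirrors the desktop application the pipeline was built for: a clinician
loads a subject's six scans, the back end runs preprocessing + feature
extraction + classification, and a diagnosis message comes back.
"""

import tempfile
from pathlib import Path

from melaspec import (ClassifierSpec, CohortSpec, diagnose, featurize_cohort,
                      generate_cohort, train, write_cohort)
from melaspec.scan_io import SCAN_SLOTS

# train a naive-Bayes model on a simulated cohort
print("training the bundled-model analogue (NB on P+V features) ...")
model = train(featurize_cohort(generate_cohort(CohortSpec(seed=0))),
              ClassifierSpec(kind="nb"))

# write a new subject's six scans to disk, as the device would
subject = generate_cohort(CohortSpec(n_melanoma=1, n_benign=0, seed=123))[0]
with tempfile.TemporaryDirectory() as tmp:
    write_cohort([subject], tmp)
    paths = {slot: Path(tmp) / f"{subject.sample_id}_{slot}.f32"
             for slot in SCAN_SLOTS}
    result = diagnose(paths, model, sample_id="subject-001",
                      comment="pigmented lesion, left forearm")

print(f"\ndiagnosis for {result.sample_id}: {result.call.upper()}")
print(f"  melanoma score: {result.scores['melanoma']:.4f}")
print(f"  benign score:   {result.scores['benign']:.4f}")
print(f"  model: {result.model_id}   comment: {result.comment}")
print("\nThe scores are the naive-Bayes posterior probabilities; the call is")
print("their argmax (ties resolve to benign).")
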