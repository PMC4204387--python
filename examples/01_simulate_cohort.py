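"""Generate a synthetic six-scan cohort and look at its intensity structure.

Each sample holds six 32x512 spectral scans: P- and V-polarized scans of two
lesion spots (p1, p2 / v1, v2) and one nearby normal-skin spot (p3 / v3).
After per-image min-max normalization, benign lesion pixels concentrate in
the 0.2-0.4 band while melanoma lesions spread over [0, 1] with most pixels
bright — the class-conditional contrast the downstream features exploit.
"""

import numpy as np

from melaspec import CohortSpec, generate_cohort, minmax_normalize

spec = CohortSpec(n_melanoma=3, n_benign=3, seed=42)
cohort = generate_cohort(spec)
print(f"generated {len(cohort)} samples "
      f"({spec.n_melanoma} melanoma, {spec.n_benign} benign)\n")

print(f"{'sample':10s} {'label':9s} {'median':>7s} {'in [0.2,0.4]':>13s} {'> 0.5':>7s}")
for rec in cohort:
    norm = minmax_normalize(rec.scans["p1"]).intensities
    label = "melanoma" if rec.label == 1 else "benign"
    in_band = np.mean((norm >= 0.2) & (norm <= 0.4))
    bright = np.mean(norm > 0.5)
    print(f"{rec.sample_id:10s} {label:9s} {np.median(norm):7.3f} "
          f"{in_band:12.1%} {bright:6.1%}")

print("\nBenign scans keep most normalized pixels in the 0.2-0.4 band;")
print("melanoma scans are dominated by bright pixels (> 0.5).")
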