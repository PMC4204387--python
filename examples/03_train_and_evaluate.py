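"""Repeated random-split evaluation of the three classifiers.

Mirrors the clinical evaluation protocol: a 187-sample cohort (19 melanoma,
168 benign) is split into 60 training and 127 test cases by stratified
random sampling without replacement, 25 times; sensitivity, specificity and
accuracy are averaged over the repetitions.  Stratification fixes 13
melanoma cases per test set, so per-run sensitivities move on a 100/13 grid.
"""

from melaspec import (ClassifierSpec, CohortSpec, SplitSpec, featurize_cohort,
                      generate_cohort, run_experiment)

print("simulating and featurizing the 187-sample cohort ...")
table = featurize_cohort(generate_cohort(CohortSpec(seed=0)))

split_spec = SplitSpec(n_train=60, repetitions=25, seed=0)
print(f"\n{'classifier':12s} {'sensitivity':>12s} {'specificity':>12s} {'accuracy':>9s}")
for kind in ("nb", "knn", "mlp"):
    report = run_experiment(table, ClassifierSpec(kind=kind, seed=0), split_spec)
    avg = report.averages
    print(f"{kind:12s} {avg['sensitivity']:12.1f} {avg['specificity']:12.1f} "
          f"{avg['accuracy']:9.1f}")

print("\nAt the generator's nominal effect size the classes are well")
print("separated, so all three classifiers sit near the ceiling; the")
print("clinical data this emulates was noisier (published NB average:")
print("88.6 / 89.3 / 89.2).")
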