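"""Shared fixtures: small synthetic cohorts and featurized tables.

Everything is generated at test time from fixed seeds; the heavier
full-size (187-sample) tables are session-scoped so the evaluation and
acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from melaspec import CohortSpec, featurize_cohort, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort: 3 melanoma + 5 benign, reduced spectral axis."""
    spec = CohortSpec(n_melanoma=3, n_benign=5, n_cols=96, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return featurize_cohort(tiny_cohort)


def _full_table(effect_size: float):
    spec = CohortSpec(effect_size=effect_size, seed=7)  # 19 mel / 168 benign
    return featurize_cohort(generate_cohort(spec))


@pytest.fixture(scope="session")
def full_table_effect1():
    """Featurized full-size cohort at the nominal effect size."""
    return _full_table(1.0)


@pytest.fixture(scope="session")
def full_table_effect03():
    return _full_table(0.3)


@pytest.fixture(scope="session")
def full_table_null():
    """Featurized full-size cohort with zero class signal."""
    return _full_table(0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
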