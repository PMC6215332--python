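import numpy as np
import pytest

import dmnstab as d


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort with session posteriors."""
    spec = d.CohortSpec(n_subjects=6, sessions_per_subject=5, seed=11)
    truth = d.sample_cohort(spec)
    posteriors = d.emit_session_posteriors(truth)
    return truth, posteriors


@pytest.fixture(scope="session")
def sessions_by_subject(small_cohort):
    _, posteriors = small_cohort
    by = {}
    for p in posteriors:
        by.setdefault(p.subject_id, []).append(p)
    return by


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
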