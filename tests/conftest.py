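"""Shared fixtures: small synthetic instances and their feature caches.

The expensive artifacts (feature caches) are session-scoped; every test that
needs epoch data derives it from these generators rather than from stored
files.
"""

from collections import namedtuple

import pytest

from eegselect import (
    EvaluationConfig,
    SubjectSplit,
    apply_car,
    compute_feature_cache,
    generate_epochset,
    make_benchmark_instance,
    make_evaluator,
)
from eegselect.synthetic import SyntheticSpec

Bench = namedtuple("Bench", "epochset split informative cache")
Oracle = namedtuple("Oracle", "cache split evaluator tail")


@pytest.fixture(scope="session")
def tiny_epochset():
    """4 subjects x 2 sessions x 6 epochs x 6 channels; fast to regenerate."""
    spec = SyntheticSpec(n_subjects=4, n_sessions=2, epochs_per_session=6,
                         n_channels=6, informative_channels=(0, 1, 2), seed=3)
    return generate_epochset(spec)


@pytest.fixture(scope="session")
def tiny_cache(tiny_epochset):
    return compute_feature_cache(apply_car(tiny_epochset))


@pytest.fixture(scope="session")
def easy_bench() -> Bench:
    """The 'easy' benchmark with its common-average-referenced feature cache."""
    epochset, split, informative = make_benchmark_instance("easy", seed=1)
    referenced = apply_car(epochset)
    cache = compute_feature_cache(referenced)
    return Bench(referenced, split, informative, cache)


@pytest.fixture(scope="session")
def oracle_instance() -> Oracle:
    """Middling-separation 8-channel instance small enough to enumerate.

    The nu/gamma tail is frozen at nu=0.01, gamma=0.1 so that the candidate
    space is exactly the 255 non-empty channel masks.
    """
    spec = SyntheticSpec(n_subjects=6, n_sessions=2, epochs_per_session=12,
                         n_channels=8, informative_channels=(0, 1, 2),
                         signature_amplitude=4.0, erp_amplitude=3.0,
                         noise_level=2.0, session_jitter=0.15, seed=11)
    epochset = apply_car(generate_epochset(spec))
    subjects = epochset.subjects
    split = SubjectSplit(subjects[:3], subjects[3:])
    cache = compute_feature_cache(epochset)
    evaluator = make_evaluator(cache, split, EvaluationConfig(cv_folds=10))
    tail = (0, 1, 0, 1, 0, 1, 1, 0)
    return Oracle(cache, split, evaluator, tail)
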