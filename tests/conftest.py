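"""Shared fixtures: small synthetic cohorts and (expensive) fitted models.

Fits are session-scoped so model-dependent tests share one posterior.
"""

import warnings

import numpy as np
import pytest

from frailtydynamics import (
    GroundTruth,
    HumanGroundTruth,
    MouseJointModel,
    HumanSplineModel,
    count_transitions,
    simulate_cohort,
    simulate_human_cohort,
)

warnings.filterwarnings("ignore", message=".*divergent.*")
warnings.filterwarnings("ignore", message=".*quantile knot rule.*")
warnings.filterwarnings("ignore", message=".*survival records without.*")


@pytest.fixture(scope="session")
def mouse_truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def mouse_cohort(mouse_truth):
    return simulate_cohort(mouse_truth, 40, seed=202)


@pytest.fixture(scope="session")
def mouse_counts(mouse_cohort):
    return count_transitions(mouse_cohort.panel)


@pytest.fixture(scope="session")
def mouse_fit(mouse_cohort, mouse_counts):
    model = MouseJointModel(mouse_counts, mouse_cohort.panel.survival)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(n_warmup=300, n_samples=300, n_chains=2, seed=7,
                         on_bad_convergence="warn")


@pytest.fixture(scope="session")
def human_truth():
    return HumanGroundTruth()


@pytest.fixture(scope="session")
def human_cohort(human_truth):
    return simulate_human_cohort(human_truth, 70, seed=303)


@pytest.fixture(scope="session")
def human_fit(human_cohort):
    counts = count_transitions(human_cohort.panel)
    model = HumanSplineModel(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(n_warmup=800, n_samples=800, n_chains=2, seed=11,
                         on_bad_convergence="warn")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
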