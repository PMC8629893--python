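import numpy as np
import pytest

from revlearn3.cohort import CohortSpec, generate_cohort
from revlearn3.task import Session, TaskConfig


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, paper-scale drug effect; shared across read-only tests."""
    spec = CohortSpec(n_subjects=12)
    return generate_cohort(spec, seed=101)


@pytest.fixture(scope="session")
def null_cohort_20():
    """20 subjects, no drug effect at all (shared-parameter sessions)."""
    spec = CohortSpec(n_subjects=20, drug_slope=0.0, drug_noise_sd=0.0,
                      include_rt=False)
    return generate_cohort(spec, seed=202)


def make_session(choices, outcomes, drug="placebo", config=None, **kw):
    config = config or TaskConfig(n_trials=len(choices), reversal_trial=len(choices) // 2 + 1)
    return Session(subject_id=kw.pop("subject_id", "s1"), drug_label=drug,
                   choices=np.asarray(choices), outcomes=np.asarray(outcomes, float),
                   config=config, **kw)


@pytest.fixture
def session_factory():
    return make_session


def random_sessions(rng, n_trials=80, both_drugs=True, config=None):
    """Arbitrary (model-free) choice/outcome sequences for likelihood tests."""
    config = config or TaskConfig()
    labels = ("placebo", "MPH") if both_drugs else ("placebo",)
    out = []
    for drug in labels:
        ch = rng.integers(0, 3, n_trials)
        ch[0] = 0
        oc = rng.choice([-1.0, 1.0], n_trials)
        out.append(Session(subject_id="r", drug_label=drug, choices=ch,
                           outcomes=oc, config=config))
    return out
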