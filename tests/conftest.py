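import pytest

from brainstates.io import collapse_replicates
from brainstates.multistate import GmmPrior, classify_dataset, determine_prior
from brainstates.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_prior():
    """Weakly informative prior with mean precision 25 (error variance 0.04)."""
    return GmmPrior(alpha0=1.0, m0=8.0, beta0=0.01, a0=2.0, b0=0.08)


@pytest.fixture(scope="session")
def small_spec():
    """A fast, fully featured dataset spec for unit tests."""
    return SyntheticSpec(
        class_counts={
            "one_state_stable": 40,
            "one_state_variable": 20,
            "k2": 25,
            "k3": 15,
            "k4": 10,
            "k5": 8,
            "k6": 6,
        },
        n_pathways=12,
        n_controls=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    return collapse_replicates(small_dataset.expression.drop_controls())


@pytest.fixture(scope="session")
def small_table(small_dataset, small_profile):
    prior = determine_prior(small_profile)
    return classify_dataset(
        small_profile, prior, annotation=small_dataset.annotation, seed=7
    )


# ---------------------------------------------------------------------------
# Full-scale run shared by the acceptance tests (fit once, score many ways).
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_spec():
    """Default study conditions at full scale: 5,000 spec-class probes."""
    return SyntheticSpec(seed=1).scaled(5.0)


@pytest.fixture(scope="session")
def study_dataset(study_spec):
    return generate_dataset(study_spec)


@pytest.fixture(scope="session")
def study_profile(study_dataset):
    return collapse_replicates(study_dataset.expression.drop_controls())


@pytest.fixture(scope="session")
def study_table(study_dataset, study_profile):
    prior = determine_prior(study_profile)
    return classify_dataset(
        study_profile, prior, annotation=study_dataset.annotation, seed=1
    )
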