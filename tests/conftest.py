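import numpy as np
import pytest

from poppred import (
    Dataset,
    LearningParams,
    ManifestCovariates,
    OutcomeRecord,
    Participant,
    SimConfig,
    StructuralCoefficients,
    SubjectTimeSeries,
    generate_dataset,
)


def make_coeffs(**overrides) -> StructuralCoefficients:
    base = dict(
        beta0=0.0, beta_a=0.0, beta_g=0.0, beta_r=0.0, beta_eps=0.0,
        beta_age=0.0, beta_sex=0.0, beta_edu=0.0, beta_rac=0.0, beta_eth=0.0,
    )
    base.update(overrides)
    return StructuralCoefficients(**base)


def make_covariates(**overrides) -> ManifestCovariates:
    base = dict(age_std=0.0, sex_male=0, edu_std=0.0, race_black=0, eth_hispanic=0)
    base.update(overrides)
    return ManifestCovariates(**base)


def make_participant(pid, times, values, mci=0, cov=None) -> Participant:
    return Participant(
        SubjectTimeSeries(pid, np.asarray(times, float), np.asarray(values, float)),
        cov if cov is not None else make_covariates(),
        OutcomeRecord(mci),
    )


@pytest.fixture(scope="session")
def toy_dataset() -> Dataset:
    """Two participants, three daily means each, one outcome observed."""
    return Dataset(
        [
            make_participant("s1", [0, 1, 2], [3.5, 3.0, 2.8], mci=1,
                             cov=make_covariates(age_std=0.5, race_black=1)),
            make_participant("s2", [0, 1, 2], [4.1, 3.2, 3.0], mci=0,
                             cov=make_covariates(age_std=-0.3, sex_male=1)),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by fit smoke tests."""
    return generate_dataset(SimConfig(n_participants=40, n_days=12, seed=9))
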