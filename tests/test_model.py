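"""Unit and property tests of the core model mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import log_ndtr
from scipy.stats import norm

from poppred import (
    EAS_COEFFS,
    EAS_HYPERS,
    Dataset,
    GroupHyperParams,
    LearningParams,
    OutcomeRecord,
    Participant,
    SubjectTimeSeries,
    hier_logprior,
    hyper_logprior,
    joint_log_posterior,
    learning_mean,
    linear_predictor,
    mci_risk,
    process_loglik,
)
from conftest import make_coeffs, make_covariates, make_participant

finite = st.floats(-5, 5, allow_nan=False)
positive = st.floats(0.05, 5, allow_nan=False)


# ---------------------------------------------------------------------------
# learning curve
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params, m, expected",
    [
        (LearningParams(2, 1, 0.5, 1), 0.0, 3.0),  # e^0 = 1 so mean = a + g
        (LearningParams(2, 0, 0.7, 1), 13.7, 2.0),  # zero gain: asymptote only
        (LearningParams(3, 2, 0.5, 1), 2.0, 3 + 2 * np.exp(-1.0)),
    ],
)
def test_learning_mean_known_values(params, m, expected):
    assert learning_mean(params, m) == pytest.approx(expected, rel=1e-12)


def test_learning_mean_vectorizes():
    p = LearningParams(2, 1, 0.3, 1)
    m = np.array([0.0, 1.0, 5.0])
    out = learning_mean(p, m)
    assert out.shape == (3,)
    assert out[0] == pytest.approx(3.0)


@given(a=finite, g=positive, r=positive)
@settings(max_examples=50, derandomize=True)
def test_learning_curve_decreases_and_converges(a, g, r):
    """With positive gain and learning rate the expected RT falls with
    practice and approaches the asymptote."""
    p = LearningParams(a, g, r, 1.0)
    m = np.linspace(0, 5, 50)  # grid where the decrement stays above float eps
    vals = learning_mean(p, m)
    assert np.all(np.diff(vals) < 0)
    assert learning_mean(p, 1e6) == pytest.approx(a, abs=1e-9)


# ---------------------------------------------------------------------------
# process likelihood
# ---------------------------------------------------------------------------


def test_process_loglik_standard_normal_at_mean():
    p = LearningParams(2, 1, 0.5, 1)
    series = SubjectTimeSeries("x", [0.0], [3.0])  # y equals the curve mean
    assert process_loglik(series, p) == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_process_loglik_shift_invariance():
    times = [0, 1, 2, 3]
    y = np.array([4.0, 3.4, 3.1, 3.05])
    c = 1.7
    base = process_loglik(SubjectTimeSeries("x", times, y), LearningParams(3, 1, 0.8, 0.4))
    shifted = process_loglik(
        SubjectTimeSeries("x", times, y + c), LearningParams(3 + c, 1, 0.8, 0.4)
    )
    assert shifted == pytest.approx(base, rel=1e-12)


def test_process_loglik_matches_per_term_sum():
    p = LearningParams(2.5, 1.5, 0.6, 0.3)
    times = np.array([0.0, 1.0, 2.0])
    y = np.array([4.2, 3.1, 2.9])
    expected = sum(
        norm.logpdf(yi, loc=p.a + p.g * np.exp(-p.r * t), scale=p.eps)
        for yi, t in zip(y, times)
    )
    assert process_loglik(SubjectTimeSeries("x", times, y), p) == pytest.approx(
        expected, rel=1e-12
    )


def test_non_positive_eps_rejected():
    with pytest.raises(ValueError):
        LearningParams(2, 1, 0.5, 0.0)
    with pytest.raises(ValueError):
        LearningParams(2, 1, 0.5, -1.0)


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------


def test_linear_predictor_zero_coefficients():
    assert linear_predictor(make_coeffs(), LearningParams(1, 1, 1, 1), make_covariates()) == 0.0


def test_linear_predictor_at_group_means():
    """Published coefficients with the latent markers at their group means
    and reference covariates give a linear predictor of about -1.100."""
    eta = linear_predictor(EAS_COEFFS, EAS_HYPERS.latent_means(), make_covariates())
    assert eta == pytest.approx(-1.10009064, abs=1e-6)


def test_linear_predictor_additivity():
    lat = LearningParams(2.0, 1.5, 0.4, 0.7)
    lat2 = LearningParams(2.0 + 0.25, 1.5, 0.4, 0.7)
    cov = make_covariates(edu_std=1.2)
    d = linear_predictor(EAS_COEFFS, lat2, cov) - linear_predictor(EAS_COEFFS, lat, cov)
    assert d == pytest.approx(EAS_COEFFS.beta_a * 0.25, rel=1e-10)


def test_mci_risk_at_zero_is_half():
    assert mci_risk(make_coeffs(), LearningParams(0, 0, 0, 1e-9), make_covariates()) == pytest.approx(0.5)


def test_mci_risk_reproduces_published_profiles():
    """Average person: risk .25; one group SD slower asymptote: .37."""
    base = mci_risk(EAS_COEFFS, EAS_HYPERS.latent_means(), make_covariates())
    assert round(base, 2) == 0.25
    shifted = LearningParams(
        EAS_HYPERS.mu_a + EAS_HYPERS.sigma_a, EAS_HYPERS.mu_g, EAS_HYPERS.mu_r, EAS_HYPERS.mu_eps
    )
    assert round(mci_risk(EAS_COEFFS, shifted, make_covariates()), 2) == 0.37


@given(a=finite, g=finite, r=finite, eps=positive)
@settings(max_examples=50, derandomize=True)
def test_logistic_symmetry(a, g, r, eps):
    """Negating every coefficient flips the risk around 1/2."""
    lat = LearningParams(a, g, r, eps)
    cov = make_covariates(age_std=0.4, race_black=1)
    pos = mci_risk(EAS_COEFFS, lat, cov)
    neg_coeffs = type(EAS_COEFFS).from_array(-EAS_COEFFS.as_array())
    assert mci_risk(neg_coeffs, lat, cov) == pytest.approx(1 - pos, rel=1e-9)


def test_risk_monotone_in_markers():
    """Risk rises with the asymptote (beta_a > 0) and falls with the
    learning rate (beta_r < 0), matching the published signs."""
    h = EAS_HYPERS
    grid = np.linspace(-1, 1, 7)
    risks_a = [
        mci_risk(EAS_COEFFS, LearningParams(h.mu_a + d, h.mu_g, h.mu_r, h.mu_eps), make_covariates())
        for d in grid
    ]
    risks_r = [
        mci_risk(EAS_COEFFS, LearningParams(h.mu_a, h.mu_g, h.mu_r + d, h.mu_eps), make_covariates())
        for d in grid
    ]
    assert np.all(np.diff(risks_a) > 0)
    assert np.all(np.diff(risks_r) < 0)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def test_hier_logprior_at_the_mode():
    """One person at the group means with unit SDs: four standard-normal
    peaks plus the truncation renormalization of the residual-SD marker."""
    h = GroupHyperParams(0.3, 1, 1.2, 1, 0.5, 1, 0.8, 1)
    val = hier_logprior([LearningParams(0.3, 1.2, 0.5, 0.8)], h)
    expected = 4 * (-0.5 * np.log(2 * np.pi)) - log_ndtr(0.8 / 1.0)
    assert val == pytest.approx(expected, rel=1e-12)


def test_hier_logprior_additive_over_persons():
    h = GroupHyperParams(0.3, 1, 1.2, 1, 0.5, 1, 0.8, 1)
    p = LearningParams(0.1, 1.0, 0.4, 0.9)
    assert hier_logprior([p, p], h) == pytest.approx(2 * hier_logprior([p], h), rel=1e-12)


def test_hier_logprior_matches_brute_force():
    rng = np.random.default_rng(5)
    h = GroupHyperParams(2.9, 0.9, 1.8, 1.1, 0.55, 0.3, 0.77, 0.44)
    persons = [
        LearningParams(*rng.normal([2.9, 1.8, 0.55, 0.77], 0.3, size=4).clip(0.05))
        for _ in range(4)
    ]
    mus = [h.mu_a, h.mu_g, h.mu_r, h.mu_eps]
    sds = [h.sigma_a, h.sigma_g, h.sigma_r, h.sigma_eps]
    expected = 0.0
    for p in persons:
        for x, m, s in zip(p.as_array(), mus, sds):
            expected += norm.logpdf(x, m, s)
        expected -= log_ndtr(h.mu_eps / h.sigma_eps)
    assert hier_logprior(persons, h) == pytest.approx(expected, rel=1e-12)


def test_hyper_logprior_matches_brute_force():
    h = GroupHyperParams(2.9, 0.9, 1.8, 1.1, 0.55, 0.3, 0.77, 0.44)
    expected = sum(norm.logpdf(m) for m in h.mus())
    expected += sum(norm.logpdf(b) for b in EAS_COEFFS.as_array())
    # half-normal(0,1) log-density = standard-normal log-density + log 2
    expected += sum(norm.logpdf(s) + np.log(2) for s in h.sigmas())
    assert hyper_logprior(h, EAS_COEFFS) == pytest.approx(expected, rel=1e-12)


def test_invalid_sigma_rejected():
    with pytest.raises(ValueError):
        GroupHyperParams(0, -1, 0, 1, 0, 1, 0, 1)
    degenerate = GroupHyperParams(0, 0, 0, 1, 0, 1, 0, 1)
    with pytest.raises(ValueError):
        hyper_logprior(degenerate, EAS_COEFFS)


# ---------------------------------------------------------------------------
# joint posterior
# ---------------------------------------------------------------------------


def _brute_force_joint(data, latents, hypers, coeffs):
    total = hier_logprior(latents, hypers) + hyper_logprior(hypers, coeffs)
    for p, lat in zip(data, latents):
        total += process_loglik(p.series, lat)
        if p.outcome.observed:
            pi = mci_risk(coeffs, lat, p.covariates)
            total += np.log(pi) if p.outcome.mci == 1 else np.log1p(-pi)
    return total


def test_joint_log_posterior_decomposition(toy_dataset):
    latents = [LearningParams(3.0, 1.0, 0.5, 0.4), LearningParams(3.2, 1.1, 0.6, 0.5)]
    val = joint_log_posterior(toy_dataset, latents, EAS_HYPERS, EAS_COEFFS)
    assert val == pytest.approx(
        _brute_force_joint(toy_dataset, latents, EAS_HYPERS, EAS_COEFFS), rel=1e-12
    )


def test_missing_outcome_drops_exactly_the_bernoulli_term(toy_dataset):
    latents = [LearningParams(3.0, 1.0, 0.5, 0.4), LearningParams(3.2, 1.1, 0.6, 0.5)]
    full = joint_log_posterior(toy_dataset, latents, EAS_HYPERS, EAS_COEFFS)
    first = toy_dataset.participants[0]
    masked = toy_dataset.with_outcomes_masked({"s1"})
    reduced = joint_log_posterior(masked, latents, EAS_HYPERS, EAS_COEFFS)
    pi = mci_risk(EAS_COEFFS, latents[0], first.covariates)
    bern = np.log(pi) if first.outcome.mci == 1 else np.log1p(-pi)
    assert full - reduced == pytest.approx(bern, rel=1e-10)


def test_bernoulli_contribution_at_even_odds():
    """With all coefficients zero the risk is 1/2, so one observed outcome
    contributes log(1/2)."""
    p1 = make_participant("s1", [0, 1], [3.0, 2.5], mci=1)
    data_obs = Dataset([p1])
    data_missing = Dataset(
        [Participant(p1.series, p1.covariates, OutcomeRecord(None))]
    )
    lat = [LearningParams(2.5, 0.5, 0.5, 0.5)]
    h = GroupHyperParams(2.5, 1, 0.5, 1, 0.5, 1, 0.5, 1)
    c = make_coeffs()
    diff = joint_log_posterior(data_obs, lat, h, c) - joint_log_posterior(
        data_missing, lat, h, c
    )
    assert diff == pytest.approx(np.log(0.5), rel=1e-12)


def test_dataset_invariants():
    p = make_participant("dup", [0, 1], [3, 2.5])
    with pytest.raises(ValueError):
        Dataset([p, p])
    with pytest.raises(ValueError):
        SubjectTimeSeries("x", [1, 0], [3, 2])  # decreasing times
    with pytest.raises(ValueError):
        SubjectTimeSeries("x", [0, 1], [3, -2])  # non-positive RT
    with pytest.raises(ValueError):
        OutcomeRecord(2)
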