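"""Core mathematics of the partially observable predictor (POP) model.

A POP model couples two submodels:

* a *process model* for repeated behavioral observations — here the
  exponential model of practice, in which person ``i``'s daily mean
  response time on day ``m`` is normal with mean ``a_i + g_i * exp(-r_i m)``
  and standard deviation ``eps_i``; and
* a *structural model* — a logistic regression in which the person-level
  process parameters (latent cognitive markers) and manifest demographic
  covariates jointly predict a binary clinical outcome (mild cognitive
  impairment, MCI).

Everything in this module is a pure function of its arguments: the mean
function, the process likelihood, the structural linear predictor and risk,
the hierarchical and hyper priors, and the joint log posterior that the
sampler in :mod:`poppred.inference` targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, log_ndtr

__all__ = [
    "SubjectTimeSeries",
    "LearningParams",
    "ManifestCovariates",
    "OutcomeRecord",
    "StructuralCoefficients",
    "GroupHyperParams",
    "Participant",
    "Dataset",
    "EAS_COEFFS",
    "EAS_HYPERS",
    "learning_mean",
    "process_loglik",
    "linear_predictor",
    "mci_risk",
    "hier_logprior",
    "hyper_logprior",
    "joint_log_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

COVARIATE_NAMES = ("age_std", "sex_male", "edu_std", "race_black", "eth_hispanic")
LATENT_NAMES = ("a", "g", "r", "eps")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One participant's repeated daily mean response times.

    ``times`` are measurement times in days since the participant's first
    assessment (non-decreasing, starting at 0 by convention); ``values``
    are daily mean response times in seconds (strictly positive).
    """

    participant_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-d")
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValueError("times and values must have equal length >= 1")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if not np.all(self.values > 0):
            raise ValueError("response times must be positive")


@dataclass(frozen=True)
class LearningParams:
    """Person-level markers of the exponential model of practice.

    ``a``: asymptote (peak sustainable response time, seconds);
    ``g``: gain (total practice-related improvement, seconds);
    ``r``: learning rate (per day); ``eps``: intra-individual variability
    (residual SD of daily means around the curve, seconds).

    ``a``, ``g`` and ``r`` are unconstrained (a negative ``r`` models
    worsening performance); ``eps`` must be positive for the Gaussian
    likelihood to exist.
    """

    a: float
    g: float
    r: float
    eps: float

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps (residual SD) must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.g, self.r, self.eps], dtype=float)


@dataclass(frozen=True)
class ManifestCovariates:
    """Demographic predictors: standardized age and education, plus
    male / Black / Hispanic dummy codes (reference: female, White,
    non-Hispanic)."""

    age_std: float
    sex_male: int
    edu_std: float
    race_black: int
    eth_hispanic: int

    def __post_init__(self) -> None:
        for name in ("sex_male", "race_black", "eth_hispanic"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if not (np.isfinite(self.age_std) and np.isfinite(self.edu_std)):
            raise ValueError("standardized covariates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.age_std, self.sex_male, self.edu_std, self.race_black, self.eth_hispanic],
            dtype=float,
        )


@dataclass(frozen=True)
class OutcomeRecord:
    """Binary MCI status; ``None`` marks a missing / held-out outcome."""

    mci: int | None

    def __post_init__(self) -> None:
        if self.mci is not None and self.mci not in (0, 1):
            raise ValueError("mci must be 0, 1 or None")

    @property
    def observed(self) -> bool:
        return self.mci is not None


@dataclass(frozen=True)
class StructuralCoefficients:
    """All regression weights of the structural logistic model: intercept,
    weights on the four latent markers, weights on the five manifest
    covariates."""

    beta0: float
    beta_a: float
    beta_g: float
    beta_r: float
    beta_eps: float
    beta_age: float
    beta_sex: float
    beta_edu: float
    beta_rac: float
    beta_eth: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.beta0,
                self.beta_a,
                self.beta_g,
                self.beta_r,
                self.beta_eps,
                self.beta_age,
                self.beta_sex,
                self.beta_edu,
                self.beta_rac,
                self.beta_eth,
            ],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StructuralCoefficients":
        return cls(*map(float, arr))


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level means and SDs of the four latent markers.

    A zero SD is tolerated at construction (the synthetic generator treats
    it as a degenerate point mass) but rejected by the prior densities,
    which require strictly positive SDs.
    """

    mu_a: float
    sigma_a: float
    mu_g: float
    sigma_g: float
    mu_r: float
    sigma_r: float
    mu_eps: float
    sigma_eps: float

    def __post_init__(self) -> None:
        for name in ("sigma_a", "sigma_g", "sigma_r", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def mus(self) -> np.ndarray:
        return np.array([self.mu_a, self.mu_g, self.mu_r, self.mu_eps], dtype=float)

    def sigmas(self) -> np.ndarray:
        return np.array(
            [self.sigma_a, self.sigma_g, self.sigma_r, self.sigma_eps], dtype=float
        )

    def latent_means(self) -> LearningParams:
        return LearningParams(self.mu_a, self.mu_g, self.mu_r, self.mu_eps)


@dataclass(frozen=True)
class Participant:
    series: SubjectTimeSeries
    covariates: ManifestCovariates
    outcome: OutcomeRecord

    @property
    def participant_id(self) -> str:
        return self.series.participant_id


@dataclass
class Dataset:
    """The triples (time series, covariates, outcome) for a cohort, with
    unique participant ids."""

    participants: list[Participant] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    @property
    def ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def covariate_matrix(self) -> np.ndarray:
        return np.array([p.covariates.as_array() for p in self.participants])

    def outcomes(self) -> list[OutcomeRecord]:
        return [p.outcome for p in self.participants]

    def with_outcomes_masked(self, ids_to_mask: set[str]) -> "Dataset":
        """Copy of the dataset with the listed participants' MCI status set
        missing (their time series and covariates are retained)."""
        missing = set(ids_to_mask) - set(self.ids)
        if missing:
            raise ValueError(f"unknown participant ids: {sorted(missing)}")
        out = []
        for p in self.participants:
            if p.participant_id in ids_to_mask:
                p = Participant(p.series, p.covariates, OutcomeRecord(None))
            out.append(p)
        return Dataset(out)


# Posterior means reported for the Einstein Aging Study Symbol Search
# analysis (structural coefficients, and group-level means/SDs of the
# latent markers).  They serve as the default generating values of the
# synthetic cohorts and as the reference point of the counterfactual
# risk profiles.
EAS_COEFFS = StructuralCoefficients(
    beta0=-2.8047,
    beta_a=0.6362,
    beta_g=-0.0339,
    beta_r=-1.4253,
    beta_eps=0.8513,
    beta_age=0.1929,
    beta_sex=-0.1975,
    beta_edu=0.1907,
    beta_rac=0.4855,
    beta_eth=0.3031,
)

EAS_HYPERS = GroupHyperParams(
    mu_a=2.9533,
    sigma_a=0.9053,
    mu_g=1.8067,
    sigma_g=1.1512,
    mu_r=0.5367,
    sigma_r=0.2989,
    mu_eps=0.7658,
    sigma_eps=0.4436,
)


# ---------------------------------------------------------------------------
# Process model
# ---------------------------------------------------------------------------


def learning_mean(params: LearningParams, m):
    """Expected response time ``a + g * exp(-r m)`` at day(s) ``m``.

    Vectorizes over ``m``; returns a scalar for scalar input.
    """
    m = np.asarray(m, dtype=float)
    out = params.a + params.g * np.exp(-params.r * m)
    return float(out) if out.ndim == 0 else out


def process_loglik(series: SubjectTimeSeries, params: LearningParams) -> float:
    """Gaussian log-likelihood of one participant's daily means under the
    exponential learning curve with residual SD ``eps``."""
    if not params.eps > 0:
        raise ValueError("eps must be positive")
    mu = learning_mean(params, series.times)
    resid = (series.values - mu) / params.eps
    n = len(series.values)
    return float(-0.5 * np.sum(resid**2) - n * (np.log(params.eps) + 0.5 * _LOG_2PI))


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------


def linear_predictor(
    coeffs: StructuralCoefficients, lat: LearningParams, cov: ManifestCovariates
) -> float:
    """Structural linear predictor: intercept + latent weights applied to the
    raw-scale markers + manifest weights applied to the covariates."""
    return float(
        coeffs.beta0
        + coeffs.beta_a * lat.a
        + coeffs.beta_g * lat.g
        + coeffs.beta_r * lat.r
        + coeffs.beta_eps * lat.eps
        + coeffs.beta_age * cov.age_std
        + coeffs.beta_sex * cov.sex_male
        + coeffs.beta_edu * cov.edu_std
        + coeffs.beta_rac * cov.race_black
        + coeffs.beta_eth * cov.eth_hispanic
    )


def mci_risk(
    coeffs: StructuralCoefficients, lat: LearningParams, cov: ManifestCovariates
) -> float:
    """Model-implied probability of MCI: logistic(linear predictor)."""
    return float(expit(linear_predictor(coeffs, lat, cov)))


# ---------------------------------------------------------------------------
# Priors and joint posterior
# ---------------------------------------------------------------------------


def _norm_logpdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * z**2 - np.log(sigma) - 0.5 * _LOG_2PI


def hier_logprior(
    all_latents: Sequence[LearningParams], hypers: GroupHyperParams
) -> float:
    """Hierarchical log-prior of the person-level markers: independent
    normals around the group means.

    The ``eps`` term is the normal density restricted to ``eps > 0`` and
    properly renormalized: each person contributes an extra
    ``-log Phi(mu_eps / sigma_eps)``.  The normalization cannot be dropped
    as a constant — it depends on the hyperparameters, and omitting it
    would bias their posterior whenever the truncation mass is
    non-negligible.
    """
    if not np.all(hypers.sigmas() > 0):
        raise ValueError("group SDs must be positive")
    lam = np.array([p.as_array() for p in all_latents])  # (n, 4)
    total = _norm_logpdf(lam, hypers.mus(), hypers.sigmas()).sum()
    total -= len(all_latents) * log_ndtr(hypers.mu_eps / hypers.sigma_eps)
    return float(total)


def hyper_logprior(hypers: GroupHyperParams, coeffs: StructuralCoefficients) -> float:
    """Log-density of the weakly informative hyperpriors: standard normal on
    the 4 group means and all 10 regression coefficients, half-normal(0,1)
    on the 4 group SDs."""
    sig = hypers.sigmas()
    if not np.all(sig > 0):
        raise ValueError("group SDs must be positive")
    total = _norm_logpdf(hypers.mus(), 0.0, 1.0).sum()
    total += _norm_logpdf(coeffs.as_array(), 0.0, 1.0).sum()
    # half-normal(0,1) on sigma: normal kernel + log 2 per term
    total += (_norm_logpdf(sig, 0.0, 1.0) + np.log(2.0)).sum()
    return float(total)


def bernoulli_loglik(z: int, pi: float) -> float:
    """log p(z | pi) for a single Bernoulli outcome."""
    return float(np.log(pi) if z == 1 else np.log1p(-pi))


def joint_log_posterior(
    data: Dataset,
    all_latents: Sequence[LearningParams],
    hypers: GroupHyperParams,
    coeffs: StructuralCoefficients,
) -> float:
    """Unnormalized log posterior of the joint POP model.

    Sums, over participants, the process likelihood of their time series
    and (when their outcome is observed) the Bernoulli likelihood of their
    MCI status at the model-implied risk, plus the hierarchical prior of
    the latent markers and the hyperpriors.  Participants with a missing
    outcome contribute no Bernoulli term: their markers are informed by
    the behavioral data alone.
    """
    if len(all_latents) != len(data):
        raise ValueError("one LearningParams per participant required")
    total = 0.0
    for p, lat in zip(data, all_latents):
        total += process_loglik(p.series, lat)
        if p.outcome.observed:
            total += bernoulli_loglik(
                p.outcome.mci, mci_risk(coeffs, lat, p.covariates)
            )
    total += hier_logprior(all_latents, hypers)
    total += hyper_logprior(hypers, coeffs)
    return float(total)
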