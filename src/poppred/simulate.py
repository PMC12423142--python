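"""Synthetic measurement-burst cohorts with known ground truth.

The generator emulates the structure of an Einstein Aging Study-like
measurement burst: a cohort of older adults (default 316 participants),
each completing brief cognitive testing over a 16-day burst aggregated to
one daily mean response time, with demographics (standardized age and
education; sex, race, ethnicity dummies) and a binary MCI outcome drawn
from the structural logistic model.  Defaults reproduce the reported
group-level posterior means/SDs and coefficient estimates, so that data
generated here carry roughly the cohort's outcome prevalence (~29%) and
the latent markers' separation between MCI-positive and -negative groups.

Everything is a deterministic function of the configuration's seed; the
ground truth (per-person markers, true risks) is returned alongside the
dataset for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import (
    EAS_COEFFS,
    EAS_HYPERS,
    Dataset,
    GroupHyperParams,
    LearningParams,
    ManifestCovariates,
    OutcomeRecord,
    Participant,
    StructuralCoefficients,
    SubjectTimeSeries,
    linear_predictor,
)
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "generate_covariates", "generate_latents",
           "generate_outcomes", "generate_timeseries", "generate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    Covariate distributions follow the EAS sample margins: age 77.54 (SD
    4.98) years, 67% female, 15.09 (SD 3.55) years of education, ~43%
    Black, ~13% Hispanic.  Age and education are standardized
    within-sample after drawing.
    """

    n_participants: int = 316
    n_days: int = 16
    hypers: GroupHyperParams = EAS_HYPERS
    coeffs: StructuralCoefficients = EAS_COEFFS
    age_mean: float = 77.54
    age_sd: float = 4.98
    p_female: float = 0.67
    edu_mean: float = 15.09
    edu_sd: float = 3.55
    p_black: float = 0.43
    p_hispanic: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants to standardize covariates")
        if self.n_days < 2:
            raise ValueError("need at least 2 measurement days")
        for name in ("p_female", "p_black", "p_hispanic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort: the per-person generating
    parameters and true risks, plus the generating hypers/coeffs."""

    latents: list[LearningParams]
    covariates: list[ManifestCovariates]
    pi: np.ndarray
    z: np.ndarray
    hypers: GroupHyperParams
    coeffs: StructuralCoefficients
    seed: int


def _rng(config_or_seed) -> np.random.Generator:
    seed = getattr(config_or_seed, "seed", config_or_seed)
    return np.random.default_rng(seed)


def generate_covariates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[ManifestCovariates]:
    """Draw demographics; age and education are standardized within-sample
    (mean 0, SD 1), dummies are Bernoulli draws."""
    rng = rng if rng is not None else _rng(config)
    n = config.n_participants
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    edu = rng.normal(config.edu_mean, config.edu_sd, size=n)
    age_std = (age - age.mean()) / age.std()
    edu_std = (edu - edu.mean()) / edu.std()
    sex_male = rng.binomial(1, 1.0 - config.p_female, size=n)
    race_black = rng.binomial(1, config.p_black, size=n)
    eth_hispanic = rng.binomial(1, config.p_hispanic, size=n)
    return [
        ManifestCovariates(
            age_std=float(age_std[i]),
            sex_male=int(sex_male[i]),
            edu_std=float(edu_std[i]),
            race_black=int(race_black[i]),
            eth_hispanic=int(eth_hispanic[i]),
        )
        for i in range(n)
    ]


def _draw_truncated_positive(
    rng: np.random.Generator, mu: float, sigma: float, size: int
) -> tuple[np.ndarray, int]:
    """Normal draws redrawn until positive; returns draws and the number of
    rejected proposals.  sigma == 0 degenerates to the constant mean."""
    if sigma == 0:
        if mu <= 0:
            raise ValueError("degenerate truncated draw with non-positive mean")
        return np.full(size, mu), 0
    out = rng.normal(mu, sigma, size=size)
    rejections = 0
    while True:
        bad = out <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out, rejections
        rejections += n_bad
        out[bad] = rng.normal(mu, sigma, size=n_bad)


def generate_latents(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[LearningParams]:
    """Draw person-level markers from the group-level normals.

    ``eps`` and ``r`` are redrawn until positive (rejection sampling) so
    that every generated learning curve is a valid, improving one; the
    rejection counts are logged.  Degenerate ``sigma = 0`` collapses every
    person to the group mean (warned)."""
    rng = rng if rng is not None else _rng(config)
    h = config.hypers
    n = config.n_participants
    if np.any(h.sigmas() == 0):
        logger.warning("degenerate group SD of 0: latent draws collapse to the mean")
    a = rng.normal(h.mu_a, h.sigma_a, size=n) if h.sigma_a > 0 else np.full(n, h.mu_a)
    g = rng.normal(h.mu_g, h.sigma_g, size=n) if h.sigma_g > 0 else np.full(n, h.mu_g)
    r, rej_r = _draw_truncated_positive(rng, h.mu_r, h.sigma_r, n)
    eps, rej_eps = _draw_truncated_positive(rng, h.mu_eps, h.sigma_eps, n)
    if rej_r or rej_eps:
        logger.info("rejection redraws: r=%d, eps=%d", rej_r, rej_eps)
    return [LearningParams(float(a[i]), float(g[i]), float(r[i]), float(eps[i])) for i in range(n)]


def generate_outcomes(
    coeffs: StructuralCoefficients,
    latents: list[LearningParams],
    covariates: list[ManifestCovariates],
    seed: int | np.random.Generator = 0,
) -> tuple[list[OutcomeRecord], np.ndarray]:
    """Draw MCI outcomes from the structural model: z_i ~ Bernoulli(pi_i)
    with pi_i = logistic(linear predictor).  Returns outcomes and true pi."""
    if len(latents) != len(covariates):
        raise ValueError("latents and covariates must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = np.array(
        [linear_predictor(coeffs, lat, cov) for lat, cov in zip(latents, covariates)]
    )
    pi = expit(eta)
    z = rng.binomial(1, pi)
    return [OutcomeRecord(int(zi)) for zi in z], pi


def generate_timeseries(
    latents: list[LearningParams],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SubjectTimeSeries]:
    """Generate daily mean RT series: days 0..n_days-1, Gaussian noise with
    each person's eps around their learning curve; non-positive values are
    redrawn (logged) since response times are positive."""
    rng = rng if rng is not None else _rng(config)
    times = np.arange(config.n_days, dtype=float)
    out = []
    redraws = 0
    for i, lat in enumerate(latents):
        mu = lat.a + lat.g * np.exp(-lat.r * times)
        y = rng.normal(mu, lat.eps)
        while np.any(y <= 0):
            bad = y <= 0
            redraws += int(bad.sum())
            y[bad] = rng.normal(mu[bad], lat.eps)
        out.append(SubjectTimeSeries(f"p{i:04d}", times.copy(), y))
    if redraws:
        logger.info("redrew %d non-positive response times", redraws)
    return out


def generate_dataset(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[Dataset, SimTruth]:
    """Compose covariates -> latents -> outcomes -> time series into a full
    synthetic cohort; optionally write the CSV/JSON artifacts."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    covariates = generate_covariates(config, rngs[0])
    latents = generate_latents(config, rngs[1])
    outcomes, pi = generate_outcomes(config.coeffs, latents, covariates, rngs[2])
    series = generate_timeseries(latents, config, rngs[3])
    data = Dataset(
        [Participant(s, c, o) for s, c, o in zip(series, covariates, outcomes)]
    )
    truth = SimTruth(
        latents=latents,
        covariates=covariates,
        pi=pi,
        z=np.array([o.mci for o in outcomes]),
        hypers=config.hypers,
        coeffs=config.coeffs,
        seed=config.seed,
    )
    if out_dir is not None:
        from .io import write_dataset  # deferred: io imports model, not simulate

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dataset(data, out_dir)
        truth_doc = {
            "seed": config.seed,
            "config": {
                k: v for k, v in asdict(config).items() if not isinstance(v, dict)
            },
            "hypers": asdict(config.hypers),
            "coeffs": asdict(config.coeffs),
            "participants": [
                {
                    "participant_id": p.participant_id,
                    "a": lat.a,
                    "g": lat.g,
                    "r": lat.r,
                    "eps": lat.eps,
                    "pi": float(pi_i),
                    "z": int(z_i),
                }
                for p, lat, pi_i, z_i in zip(data, latents, pi, truth.z)
            ],
        }
        (out_dir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return data, truth
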