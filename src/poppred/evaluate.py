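"""Predictive evaluation of POP models.

Implements the counterfactual risk profiles (how the model-implied MCI
probability moves as latent markers or demographic dummies are shifted
from a baseline profile), stratified k-fold cross-validation in which each
fold's MCI status is held out while the behavioral data are retained, ROC
curves and AUC with a stratified bootstrap confidence interval, and the
two comparator model variants ("manifest only" and "manifest + latent
descriptors").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .inference import (
    McmcConfig,
    fit_joint_model,
    fit_manifest_logistic,
    posterior_risk,
)
from .model import (
    Dataset,
    GroupHyperParams,
    LearningParams,
    ManifestCovariates,
    OutcomeRecord,
    StructuralCoefficients,
    mci_risk,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "counterfactual_risk_chain",
    "stratified_folds",
    "cv_predict_risk",
    "auc",
    "roc_points",
    "RocResult",
    "bootstrap_auc_ci",
]

VARIANTS = ("full_pop", "manifest_only", "latent_descriptors")

_LATENT_ALIASES = {
    "asymptote": ("a", "sigma_a", "mu_a"),
    "gain": ("g", "sigma_g", "mu_g"),
    "learning_rate": ("r", "sigma_r", "mu_r"),
    "variability": ("eps", "sigma_eps", "mu_eps"),
}

_SHIFT_RE = re.compile(
    r"^\s*(?P<name>[a-z_]+)\s*(?:(?P<sd>[+-]\s*[\d.]+)\s*sd|=\s*(?P<val>[+-]?[\d.]+))\s*$"
)


def counterfactual_risk_chain(
    coeffs: StructuralCoefficients,
    hypers: GroupHyperParams,
    shifts: list[str],
) -> list[float]:
    """MCI risk at a baseline profile and after each cumulative shift.

    The baseline profile fixes the latent markers at their group-level
    means, the standardized covariates at the sample average (0), and the
    dummies at their reference categories (0).  Shifts are strings,
    applied cumulatively:

    * ``"asymptote +1sd"`` / ``"learning_rate -1sd"`` — move a latent
      marker by a multiple of its group-level SD (aliases: asymptote,
      gain, learning_rate, variability);
    * ``"race_black = 1"`` — set a dummy covariate;
    * ``"age_std = 0.5"`` — set a standardized covariate.

    Returns the risk after the baseline and after each shift, in order.
    """
    lat = {"a": hypers.mu_a, "g": hypers.mu_g, "r": hypers.mu_r, "eps": hypers.mu_eps}
    cov = {"age_std": 0.0, "sex_male": 0, "edu_std": 0.0, "race_black": 0, "eth_hispanic": 0}
    sds = {"a": hypers.sigma_a, "g": hypers.sigma_g, "r": hypers.sigma_r, "eps": hypers.sigma_eps}

    def risk() -> float:
        return mci_risk(coeffs, LearningParams(**lat), ManifestCovariates(**cov))

    out = [risk()]
    for shift in shifts:
        m = _SHIFT_RE.match(shift.lower())
        if m is None:
            raise ValueError(f"cannot parse shift {shift!r}")
        name = m.group("name")
        if m.group("sd") is not None:
            if name not in _LATENT_ALIASES:
                raise ValueError(f"unknown latent marker in shift {shift!r}")
            key = _LATENT_ALIASES[name][0]
            lat[key] += float(m.group("sd").replace(" ", "")) * sds[key]
        else:
            if name not in cov:
                raise ValueError(f"unknown covariate in shift {shift!r}")
            val = float(m.group("val"))
            cov[name] = int(val) if name in ("sex_male", "race_black", "eth_hispanic") else val
        out.append(risk())
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(
    outcomes: list[OutcomeRecord] | list[int],
    k: int,
    seed: int = 0,
    ids: list[str] | None = None,
) -> dict[str, int]:
    """Outcome-stratified fold assignment.

    Participants are permuted within outcome class and dealt round-robin
    into ``k`` folds, the negatives continuing where the positives left
    off so fold sizes differ by at most one and every fold's positive
    count differs by at most one.
    """
    z = np.array([o.mci if isinstance(o, OutcomeRecord) else o for o in outcomes])
    if any(v is None for v in z):
        raise ValueError("fold stratification requires observed outcomes")
    z = z.astype(int)
    n = len(z)
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of participants")
    if ids is None:
        ids = [f"p{i:04d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(z == 1))
    neg = rng.permutation(np.flatnonzero(z == 0))
    if min(len(pos), len(neg)) < k:
        logger.warning("an outcome class has fewer members than folds")
    assignment: dict[str, int] = {}
    slot = 0
    for idx in np.concatenate([pos, neg]):
        assignment[ids[int(idx)]] = slot % k
        slot += 1
    return assignment


def cv_predict_risk(
    data: Dataset,
    folds: dict[str, int],
    variant: str,
    mcmc: McmcConfig,
) -> pd.DataFrame:
    """Cross-validated held-out risk predictions.

    For each fold, the fold members' MCI status is set missing (their time
    series and covariates are retained for the joint variants), the model
    is refitted from scratch, and each held-out participant's predicted
    risk is the posterior mean of logistic(eta) over the refit's draws.
    Returns one prediction per participant with columns
    ``participant_id, variant, pi_pred, z_true, fold``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if set(folds) != set(data.ids):
        raise ValueError("fold assignment must cover exactly the dataset's participants")
    z_true = {p.participant_id: p.outcome.mci for p in data}
    if any(v is None for v in z_true.values()):
        raise ValueError("cross-validation requires observed outcomes for all participants")
    rows = []
    for fold in sorted(set(folds.values())):
        held = {pid for pid, f in folds.items() if f == fold}
        masked = data.with_outcomes_masked(held)
        fold_mcmc = replace(mcmc, seed=int(np.random.SeedSequence([mcmc.seed, fold]).generate_state(1)[0] % (2**31)))
        try:
            if variant == "manifest_only":
                draws = fit_manifest_logistic(masked, fold_mcmc)
            else:
                process = "exponential" if variant == "full_pop" else "descriptors"
                draws = fit_joint_model(masked, fold_mcmc, process=process)
        except Exception as err:  # pragma: no cover - defensive
            raise RuntimeError(f"fit failed in fold {fold}") from err
        preds = posterior_risk(draws, masked).set_index("participant_id")
        for pid in sorted(held):
            rows.append(
                {
                    "participant_id": pid,
                    "variant": variant,
                    "pi_pred": float(preds.loc[pid, "pi_pred"]),
                    "z_true": int(z_true[pid]),
                    "fold": fold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both outcome classes must be present")


def auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative, ties
    counted half (Mann-Whitney convention; equals the trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    return float(roc_auc_score(labels, scores))


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None


def roc_points(scores, labels) -> RocResult:
    """ROC curve at every distinct score threshold, endpoints included; the
    trapezoidal area under the returned points equals :func:`auc` exactly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc(scores, labels))


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling participants within
    outcome class (stratified), so every replicate keeps both classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        sp = rng.choice(pos, size=len(pos), replace=True)
        sn = rng.choice(neg, size=len(neg), replace=True)
        stats[b] = roc_auc_score(
            np.concatenate([np.ones(len(sp), dtype=int), np.zeros(len(sn), dtype=int)]),
            np.concatenate([sp, sn]),
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
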