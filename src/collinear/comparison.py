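"""Predictive-accuracy scoring and group-level model selection.

Per subject, models are scored by PSIS-LOO: leave-one-out predictive
density estimated from full-posterior draws with Pareto-smoothed importance
weights.  AIC is provided as a cheap cross-check (reported as -AIC/2 so it
lives on the same scale as LOO).  At the group level a Dirichlet
random-effects model over model frequencies is fitted by the standard
variational iteration, yielding expected posterior frequencies, exceedance
probabilities and their "protected" version that blends with chance via the
Bayes omnibus risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "LooResult",
    "GroupComparison",
    "psis_loo",
    "aic",
    "aic_loo_scale",
    "group_bms",
]

PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO score with per-trial terms and Pareto shape diagnostics."""

    loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_draws: int

    @property
    def n_trials(self) -> int:
        return len(self.pointwise)

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def _gpd_fit(exceedances: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to sorted exceedances.

    Zhang & Stephens (2009) profile posterior-mean estimator with the weak
    regularizing prior used by standard PSIS implementations.  Returns
    (k, sigma).
    """
    x = np.asarray(exceedances, dtype=float)
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    log_lik = n * (np.log(-(b / k)) - k - 1.0)
    weights = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    weights /= weights.sum()
    b_post = float(np.sum(b * weights))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post  # scale uses the unregularized shape
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantiles(probs: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        q = -np.log1p(-probs)
    else:
        q = np.expm1(-k * np.log1p(-probs)) / k
    return sigma * q


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws x trials) matrix of pointwise log-likelihoods.

    For each trial, the raw importance log-ratios are the negated pointwise
    log-likelihoods; the ``M = min(S/5, 3 sqrt(S))`` largest ratios are
    replaced by generalized-Pareto order statistics and truncated at the raw
    maximum.  Degenerate (constant) columns are passed through unsmoothed
    with a Pareto shape of 0.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be 2-D (draws x trials)")
    n_draws, n_trials = ll.shape
    if n_draws < 100:
        raise ValueError("psis_loo requires at least 100 posterior draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik must be finite")

    m_tail = int(np.ceil(min(n_draws / 5.0, 3.0 * np.sqrt(n_draws))))
    pointwise = np.empty(n_trials)
    pareto_k = np.empty(n_trials)
    for i in range(n_trials):
        log_ratio = -ll[:, i]
        log_ratio = log_ratio - log_ratio.max()
        if np.ptp(log_ratio) == 0.0:
            pareto_k[i] = 0.0  # constant weights: importance sampling is exact
            pointwise[i] = ll[0, i]
            continue
        order = np.argsort(log_ratio)
        cutoff = max(log_ratio[order[-m_tail - 1]], np.log(np.finfo(float).tiny))
        (tail_idx,) = np.where(log_ratio > cutoff)
        khat = np.inf
        if len(tail_idx) > 4:
            exceed = np.exp(log_ratio[tail_idx]) - np.exp(cutoff)
            ranks = np.argsort(exceed)
            khat, sigma = _gpd_fit(exceed[ranks])
            if np.isfinite(khat) and sigma > 0:
                probs = (np.arange(0.5, len(tail_idx))) / len(tail_idx)
                smoothed = np.log(_gpd_quantiles(probs, khat, sigma) + np.exp(cutoff))
                log_ratio = log_ratio.copy()
                log_ratio[tail_idx[ranks]] = smoothed
                log_ratio = np.minimum(log_ratio, 0.0)  # truncate at raw max
        pareto_k[i] = khat
        # log( sum_s w_s p_is / sum_s w_s )
        pointwise[i] = logsumexp(log_ratio + ll[:, i]) - logsumexp(log_ratio)

    loo = float(np.sum(pointwise))
    se = float(np.sqrt(n_trials * np.var(pointwise, ddof=0)))
    return LooResult(loo=loo, se=se, pointwise=pointwise, pareto_k=pareto_k, n_draws=n_draws)


def aic(max_loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``-2 max_loglik + 2 n_params``."""
    return -2.0 * float(max_loglik) + 2.0 * int(n_params)


def aic_loo_scale(max_loglik: float, n_params: int) -> float:
    """AIC on the LOO (predictive log-density) scale, ``-AIC / 2``."""
    return -0.5 * aic(max_loglik, n_params)


@dataclass(frozen=True)
class GroupComparison:
    """Group-level random-effects model selection summary."""

    evidence: np.ndarray
    alpha: np.ndarray
    frequency_mean: np.ndarray
    frequency_sd: np.ndarray
    responsibilities: np.ndarray
    exceedance_prob: np.ndarray
    protected_exceedance_prob: np.ndarray
    bayes_omnibus_risk: float


def group_bms(
    evidence: np.ndarray,
    *,
    alpha0: float = 1.0,
    n_mc: int = 100_000,
    rng_seed=0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> GroupComparison:
    """Hierarchical Bayesian model selection across subjects.

    ``evidence`` is a (subjects x models) matrix of log model evidences
    (here: LOO scores).  A Dirichlet random-effects model with symmetric
    prior ``alpha0`` is fitted by the standard variational iteration;
    exceedance probabilities are computed by Monte-Carlo sampling of the
    posterior Dirichlet, and protected against the "all models equal"
    hypothesis via the Bayes omnibus risk.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be (subjects x models) with at least 2 of each")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence must be finite")
    n_subj, n_models = lme.shape
    lme = lme - lme.max(axis=1, keepdims=True)

    alpha_prior = np.full(n_models, float(alpha0))
    alpha = alpha_prior.copy()
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        log_u = log_u - logsumexp(log_u, axis=1, keepdims=True)
        g = np.exp(log_u)
        alpha_new = alpha_prior + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    g = np.exp(lme + digamma(alpha) - digamma(alpha.sum()))
    g /= g.sum(axis=1, keepdims=True)

    a_sum = alpha.sum()
    freq_mean = alpha / a_sum
    freq_sd = np.sqrt(alpha * (a_sum - alpha) / (a_sum**2 * (a_sum + 1.0)))

    rng = np.random.default_rng(rng_seed)
    draws = rng.dirichlet(alpha, size=int(n_mc))
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_models) / len(winners)

    # Free energy of the random-effects model (ELBO at convergence).
    psi_term = digamma(alpha) - digamma(a_sum)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = np.where(g > 0, g * np.log(g), 0.0).sum()
    kl_dirichlet = (
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(alpha_prior.sum())
        + gammaln(alpha_prior).sum()
        + np.sum((alpha - alpha_prior) * psi_term)
    )
    f1 = np.sum(g * (lme + psi_term)) - entropy_g - kl_dirichlet
    # Null hypothesis: all models equally frequent.
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(n_models)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = xp * (1.0 - bor) + bor / n_models

    return GroupComparison(
        evidence=np.asarray(evidence, dtype=float),
        alpha=alpha,
        frequency_mean=freq_mean,
        frequency_sd=freq_sd,
        responsibilities=g,
        exceedance_prob=xp,
        protected_exceedance_prob=pxp,
        bayes_omnibus_risk=bor,
    )
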