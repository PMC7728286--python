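"""Observer decision models for the collinearity and height judgment tasks.

Ten model variants are implemented.  All share eccentricity-dependent
Gaussian measurement noise ``sigma_x(y)`` and a lapse rate ``lambda``; they
differ in the mapping from measurements ``(x_L, x_R)`` to a binary report.

Threshold family (criterion on the measured offset ``|x_L - x_R|``):

* ``Fixed`` -- a single criterion ``kappa``;
* ``Lin`` -- uncertainty-dependent criterion ``kappa0 + kappa1 sigma_x(y)``;
* ``History`` -- Lin extended with weighted noise terms from up to four
  preceding trials of the same session;
* ``Nonparametric`` -- one free criterion per eccentricity level.

Bayesian family (posterior ratio of the two causal categories):

* ``Bayes`` -- exact posterior ratio with free category prior ``p_common``;
* ``NoiseMismatch`` -- the observer's assumed noise is an affine function
  of the true noise (``p_common`` fixed at 0.5);
* ``WidthMismatch`` -- the observer assumes an incorrect stimulus
  distribution width ``sigma_y_assumed``;
* ``BayesDN`` -- Gaussian decision noise ``sigma_d`` on the decision
  variable before thresholding;
* ``HybridDNWidth`` -- width mismatch and decision noise combined.

``HeightJudgment`` responds to the sign of the measured offset and is used
to estimate the noise profile independently of any criterion.

Response probabilities are exact: closed form for the threshold family,
Gauss-Hermite quadrature over the measurement distribution for the Bayesian
family.  The lapse enters as a symmetric mixture ``lambda/2 + (1-lambda) p``.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

from .synthetic import (
    COLLINEAR,
    COLLINEARITY,
    HEIGHT,
    LEFT_HIGHER,
    NONCOLLINEAR,
    RIGHT_HIGHER,
    TrialRecord,
    trials_to_frame,
)

__all__ = [
    "NoiseProfile",
    "ObserverParams",
    "ParamEntry",
    "ParamSpace",
    "MODEL_IDS",
    "bayes_log_posterior_ratio",
    "bayes_accept_halfwidth",
    "p_collinear_response",
    "p_right_higher",
    "response_log_probs",
    "dataset_log_likelihood",
    "history_criterion",
    "effective_criterion",
    "decide_collinear",
    "param_space",
    "free_parameter_count",
    "write_params",
    "read_params",
]

FIXED = "Fixed"
BAYES = "Bayes"
LIN = "Lin"
HISTORY = "History"
NOISE_MISMATCH = "NoiseMismatch"
WIDTH_MISMATCH = "WidthMismatch"
BAYES_DN = "BayesDN"
HYBRID_DN_WIDTH = "HybridDNWidth"
NONPARAMETRIC = "Nonparametric"
HEIGHT_JUDGMENT = "HeightJudgment"

MODEL_IDS = (
    FIXED,
    BAYES,
    LIN,
    HISTORY,
    NOISE_MISMATCH,
    WIDTH_MISMATCH,
    BAYES_DN,
    HYBRID_DN_WIDTH,
    NONPARAMETRIC,
    HEIGHT_JUDGMENT,
)

THRESHOLD_MODELS = (FIXED, LIN, HISTORY, NONPARAMETRIC)
BAYES_QUAD_MODELS = (BAYES, NOISE_MISMATCH, WIDTH_MISMATCH)
DECISION_NOISE_MODELS = (BAYES_DN, HYBRID_DN_WIDTH)

#: Gauss-Hermite nodes per dimension for quadrature-based probabilities.
GH_NODES = 31

#: Number of previous trials feeding the History criterion.
HISTORY_LAGS = 4


@lru_cache(maxsize=8)
def _hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * nodes, weights / np.sqrt(np.pi)


@dataclass(frozen=True)
class NoiseProfile:
    """Measurement-noise SD per eccentricity level, in dva."""

    levels: tuple[float, ...]
    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        sigmas = tuple(float(v) for v in self.sigmas)
        if len(levels) != len(sigmas):
            raise ValueError("levels and sigmas must have equal length")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(not (s > 0) for s in sigmas):
            raise ValueError("all noise SDs must be strictly positive")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "sigmas", sigmas)

    @classmethod
    def from_dict(cls, mapping: Mapping[float, float]) -> "NoiseProfile":
        items = sorted((float(k), float(v)) for k, v in mapping.items())
        return cls(tuple(k for k, _ in items), tuple(v for _, v in items))

    def to_dict(self) -> dict[float, float]:
        return dict(zip(self.levels, self.sigmas))

    def sigma_at(self, eccentricity) -> np.ndarray:
        """Look up sigma_x for each eccentricity (exact level match)."""
        ecc = np.atleast_1d(np.asarray(eccentricity, dtype=float))
        levels = np.asarray(self.levels)
        idx = np.searchsorted(levels, ecc)
        idx_clipped = np.clip(idx, 0, len(levels) - 1)
        ok = np.isclose(levels[idx_clipped], ecc, rtol=0.0, atol=1e-9)
        if not np.all(ok):
            missing = sorted(set(np.asarray(ecc)[~ok].tolist()))
            raise KeyError(f"noise profile has no entry for eccentricity level(s) {missing}")
        return np.asarray(self.sigmas)[idx_clipped]

    def level_index(self, eccentricity) -> np.ndarray:
        ecc = np.atleast_1d(np.asarray(eccentricity, dtype=float))
        levels = np.asarray(self.levels)
        idx = np.clip(np.searchsorted(levels, ecc), 0, len(levels) - 1)
        if not np.all(np.isclose(levels[idx], ecc, rtol=0.0, atol=1e-9)):
            raise KeyError("eccentricity not in noise profile")
        return idx


@dataclass(frozen=True)
class ObserverParams:
    """A model identifier plus that model's parameters.

    Only the fields relevant to ``model_id`` are used; ``sigma_y`` is the
    stimulus-distribution width the Bayesian family assumes it has learned
    (the design's ``offset_sd`` unless overridden by ``sigma_y_assumed``).
    """

    model_id: str
    noise: NoiseProfile
    lapse: float = 0.0
    sigma_y: float = 0.48
    p_common: float = 0.5
    kappa: float | None = None
    kappa0: float | None = None
    kappa1: float | None = None
    history_weights: tuple[float, ...] | None = None
    mm_a: float | None = None
    mm_b: float | None = None
    sigma_y_assumed: float | None = None
    sigma_d: float | None = None
    level_criteria: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")
        if self.model_id == FIXED and (self.kappa is None or self.kappa < 0):
            raise ValueError("Fixed requires kappa >= 0")
        if self.model_id == LIN and (self.kappa0 is None or self.kappa1 is None):
            raise ValueError("Lin requires kappa0 and kappa1")
        if self.model_id == HISTORY:
            if self.kappa0 is None or self.history_weights is None:
                raise ValueError("History requires kappa0 and history_weights")
            if len(self.history_weights) != HISTORY_LAGS + 1:
                raise ValueError(f"History requires {HISTORY_LAGS + 1} weights")
        if self.model_id == NONPARAMETRIC:
            if self.level_criteria is None or len(self.level_criteria) != len(self.noise.levels):
                raise ValueError("Nonparametric requires one criterion per noise level")
        if self.model_id == NOISE_MISMATCH and (self.mm_a is None or self.mm_b is None):
            raise ValueError("NoiseMismatch requires mm_a and mm_b")
        if self.model_id in (WIDTH_MISMATCH, HYBRID_DN_WIDTH) and not (
            self.sigma_y_assumed is not None and self.sigma_y_assumed > 0
        ):
            raise ValueError(f"{self.model_id} requires sigma_y_assumed > 0")
        if self.model_id in DECISION_NOISE_MODELS and not (
            self.sigma_d is not None and self.sigma_d > 0
        ):
            raise ValueError(f"{self.model_id} requires sigma_d > 0")
        if self.model_id in (BAYES, WIDTH_MISMATCH, BAYES_DN, HYBRID_DN_WIDTH, NOISE_MISMATCH):
            if not (0.0 < self.p_common < 1.0):
                raise ValueError("p_common must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Bayesian decision variable


def _log_normpdf(x, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + np.asarray(x) ** 2 / var)


def bayes_log_posterior_ratio(x_left, x_right, eccentricity, sigma_x, sigma_y, p_common):
    """Log posterior ratio ``log p(C=1|x) - log p(C=0|x)``.

    Marginalizing the latent segment positions gives, with
    ``u = x_L - x_R`` and ``v = (x_L + x_R)/2``:

    * same contour:  ``u ~ N(0, 2 sigma_x^2)``, ``v ~ N(y, sigma_y^2 + sigma_x^2/2)``
    * two contours:  ``x_L, x_R`` iid ``N(y, sigma_x^2 + sigma_y^2)``

    ``sigma_y = 0`` is allowed as the degenerate limit where both category
    likelihoods coincide and the ratio reduces to the log prior ratio.
    """
    sigma_x = np.asarray(sigma_x, dtype=float)
    if np.any(sigma_x <= 0):
        raise ValueError("sigma_x must be strictly positive")
    if np.any(np.asarray(sigma_y) < 0):
        raise ValueError("sigma_y must be nonnegative")
    if np.any((np.asarray(p_common) <= 0) | (np.asarray(p_common) >= 1)):
        raise ValueError("p_common must lie in (0, 1)")
    x_left = np.asarray(x_left, dtype=float)
    x_right = np.asarray(x_right, dtype=float)
    y = np.asarray(eccentricity, dtype=float)
    u = x_left - x_right
    v = 0.5 * (x_left + x_right)
    var_x = sigma_x**2
    var_y = np.asarray(sigma_y, dtype=float) ** 2
    s2 = var_x + var_y
    log_prior = np.log(p_common) - np.log1p(-np.asarray(p_common, dtype=float))
    log_c1 = _log_normpdf(u, 2.0 * var_x) + _log_normpdf(v - y, var_y + 0.5 * var_x)
    log_c0 = _log_normpdf(x_left - y, s2) + _log_normpdf(x_right - y, s2)
    return log_prior + log_c1 - log_c0


def _accept_coefficients(sigma_x, sigma_y, p_common):
    """Decompose the decision variable as ``d* = a0 + c_v (v-y)^2 - q u^2``.

    Returns ``(a0, c_v, q)``; ``c_v`` and ``q`` are strictly positive for
    ``sigma_y > 0``.
    """
    sigma_x = np.asarray(sigma_x, dtype=float)
    sigma_y = np.asarray(sigma_y, dtype=float)
    if np.any(sigma_x <= 0) or np.any(sigma_y <= 0):
        raise ValueError("sigma_x and sigma_y must be strictly positive")
    var_x = sigma_x**2
    var_y = sigma_y**2
    s2 = var_x + var_y
    w2 = var_y + 0.5 * var_x
    q = 0.25 / var_x - 0.25 / s2  # curvature in u
    c_v = 1.0 / s2 - 0.5 / w2  # curvature in (v - y)
    log_prior = np.log(p_common) - np.log1p(-np.asarray(p_common, dtype=float))
    a0 = (
        log_prior
        - 0.5 * np.log(2.0 * np.pi * 2.0 * var_x)
        - 0.5 * np.log(2.0 * np.pi * w2)
        + np.log(2.0 * np.pi * s2)
    )
    return a0, c_v, q


def _accept_quadratic(v, eccentricity, sigma_x, sigma_y, p_common):
    """``(A(v), q)`` with ``d* = A(v) - q u^2``."""
    a0, c_v, q = _accept_coefficients(sigma_x, sigma_y, p_common)
    v = np.asarray(v, dtype=float)
    y = np.asarray(eccentricity, dtype=float)
    return a0 + c_v * (v - y) ** 2, q


def bayes_accept_halfwidth(v, eccentricity, sigma_x, sigma_y, p_common):
    """Half-width ``b(v)`` of the accept region ``|u| <= b(v)`` at fixed ``v``.

    The decision variable is quadratic with negative curvature in ``u`` and
    positive curvature in ``v - y``, so the accept region at fixed ``v`` is a
    symmetric interval whose half-width has the closed form
    ``b(v) = sqrt(A(v) / q)``.  Returns NaN where the region is empty
    (``A(v) < 0``).
    """
    a_v, q = _accept_quadratic(v, eccentricity, sigma_x, sigma_y, p_common)
    with np.errstate(invalid="ignore"):
        b = np.sqrt(a_v / q)
    return np.where(a_v >= 0, b, np.nan)


# ---------------------------------------------------------------------------
# Effective criteria for the threshold family


def _trial_arrays(trials):
    if isinstance(trials, TrialRecord):
        trials = [trials]
    trials = list(trials)
    ecc = np.array([t.eccentricity for t in trials])
    y_left = np.array([t.y_left for t in trials])
    y_right = np.array([t.y_right for t in trials])
    return trials, ecc, y_left, y_right


def history_criterion(params: ObserverParams, session_trials: Sequence[TrialRecord], t: int) -> float:
    """History-model criterion for trial index ``t`` of one session sequence.

    ``kappa_t = kappa0 + sum_k w_k sigma_x(y_{t-k})`` for lags ``k = 0..4``;
    indices before the session start contribute the current trial's noise.
    The returned value is not clipped.
    """
    trials = list(session_trials)
    keys = {(tr.subject_id, tr.session) for tr in trials}
    if len(keys) > 1:
        raise ValueError("history_criterion requires trials from a single session")
    if not (0 <= t < len(trials)):
        raise IndexError("trial index out of range")
    sigma = params.noise.sigma_at([tr.eccentricity for tr in trials])
    kappa = float(params.kappa0)
    for k, w in enumerate(params.history_weights):
        j = t - k
        kappa += w * float(sigma[j] if j >= 0 else sigma[t])
    return kappa


def _session_runs(trials: Sequence[TrialRecord]) -> list[tuple[int, int]]:
    """Contiguous runs of identical (subject, session); rejects interleaving."""
    runs: list[tuple[int, int]] = []
    seen: set = set()
    prev_key = None
    start = 0
    for i, t in enumerate(trials):
        key = (t.subject_id, t.session)
        if key != prev_key:
            if key in seen:
                raise ValueError("trials from the same session must be contiguous")
            if prev_key is not None:
                runs.append((start, i))
            seen.add(key)
            prev_key = key
            start = i
    runs.append((start, len(trials)))
    return runs


def effective_criterion(params: ObserverParams, trials) -> np.ndarray:
    """Per-trial criterion (before clipping at zero) for threshold models."""
    trials, ecc, _, _ = _trial_arrays(trials)
    if params.model_id == FIXED:
        return np.full(len(trials), float(params.kappa))
    if params.model_id == LIN:
        return params.kappa0 + params.kappa1 * params.noise.sigma_at(ecc)
    if params.model_id == NONPARAMETRIC:
        crit = np.asarray(params.level_criteria, dtype=float)
        return crit[params.noise.level_index(ecc)]
    if params.model_id == HISTORY:
        sigma = params.noise.sigma_at(ecc)
        weights = np.asarray(params.history_weights, dtype=float)
        kappa = np.full(len(trials), float(params.kappa0))
        for start, stop in _session_runs(trials):
            seg = sigma[start:stop]
            for k, w in enumerate(weights):
                lagged = np.empty_like(seg)
                if k == 0:
                    lagged = seg
                else:
                    lagged[k:] = seg[:-k]
                    lagged[:k] = seg[:k]  # pad with the current trial's noise
                kappa[start:stop] += w * lagged
        return kappa
    raise ValueError(f"{params.model_id} has no offset criterion")


# ---------------------------------------------------------------------------
# Response probabilities


def _p_threshold(kappa_eff, delta, sigma):
    """P(|x_L - x_R| < kappa) with x_L - x_R ~ N(delta, 2 sigma^2)."""
    kappa = np.clip(kappa_eff, 0.0, None)
    scale = np.sqrt(2.0) * sigma
    return ndtr((kappa - delta) / scale) - ndtr((-kappa - delta) / scale)


def _assumed_sigmas(params: ObserverParams, sigma_x: np.ndarray):
    """(sigma_x, sigma_y) the observer plugs into the decision variable."""
    sigma_x_a = sigma_x
    sigma_y_a = params.sigma_y
    if params.model_id == NOISE_MISMATCH:
        sigma_x_a = np.clip(params.mm_a + params.mm_b * sigma_x, 1e-6, None)
    if params.model_id in (WIDTH_MISMATCH, HYBRID_DN_WIDTH):
        sigma_y_a = params.sigma_y_assumed
    return sigma_x_a, sigma_y_a


def _p_bayes_quad(params: ObserverParams, ecc, delta, vbar, sigma, n_nodes=GH_NODES):
    """E_v[P(|u| <= b(v))] over the measurement distribution of ``v``.

    ``v ~ N(vbar, sigma^2/2)`` independently of ``u ~ N(delta, 2 sigma^2)``.
    When the accept region exists for every ``v`` (``a0 >= 0``) plain
    Gauss-Hermite applies; otherwise the region is ``|v - y| >= r`` with a
    square-root kink in ``b`` at ``r``, and each branch is integrated with
    the smoothing substitution ``t = +-(r + w^2)`` (Gauss-Legendre).
    """
    sigma_x_a, sigma_y_a = _assumed_sigmas(params, sigma)
    sigma_x_a = np.broadcast_to(np.asarray(sigma_x_a, dtype=float), sigma.shape)
    a0, c_v, q = _accept_coefficients(sigma_x_a, sigma_y_a, params.p_common)
    a0 = np.broadcast_to(np.asarray(a0), sigma.shape)
    c_v = np.broadcast_to(np.asarray(c_v), sigma.shape)
    q = np.broadcast_to(np.asarray(q), sigma.shape)
    mu = vbar - np.asarray(ecc)  # v - y mean
    sv = sigma / np.sqrt(2.0)
    scale = np.sqrt(2.0) * sigma
    d = np.asarray(delta)

    def mass(b, dd, cc):
        return ndtr((b - dd) / cc) - ndtr((-b - dd) / cc)

    # accept region: |t| >= r, with r = 0 when a0 >= 0 (where b(t) still has
    # a cusp at t = 0 if a0 is small).  Where the kink/cusp sits inside the
    # measurement mass, integrate each side with the smoothing substitution
    # t = +-(r + w^2); where it is far outside, plain Gauss-Hermite centred
    # on the mass is both accurate and better resolved.
    r = np.sqrt(np.clip(-a0, 0.0, None) / c_v)
    kink_dist = np.minimum(np.abs(mu - r), np.abs(mu + r))
    out = np.zeros(len(sigma))

    plain = kink_dist > 7.0 * sv
    if np.any(plain):
        nodes, weights = _hermgauss(n_nodes)
        t = mu[plain, None] + sv[plain, None] * nodes[None, :]
        with np.errstate(invalid="ignore"):
            b = np.sqrt(
                np.clip(a0[plain, None] + c_v[plain, None] * t**2, 0.0, None)
                / q[plain, None]
            )
        b = np.where(a0[plain, None] + c_v[plain, None] * t**2 >= 0, b, 0.0)
        out[plain] = mass(b, d[plain, None], scale[plain, None]) @ weights

    sub = ~plain
    if np.any(sub):
        x, w = _leggauss01(n_nodes)
        acc = np.zeros(int(sub.sum()))
        for side in (+1.0, -1.0):
            reach = side * mu[sub] + 6.5 * sv[sub] - r[sub]  # cover 6.5 SDs
            span = np.sqrt(np.clip(reach, 0.0, None))
            ww = span[:, None] * x[None, :]
            t_abs = r[sub, None] + ww**2
            b = np.sqrt(
                np.clip(a0[sub, None] + c_v[sub, None] * t_abs**2, 0.0, None)
                / q[sub, None]
            )
            density = np.exp(
                -0.5 * ((side * t_abs - mu[sub, None]) / sv[sub, None]) ** 2
            ) / (np.sqrt(2.0 * np.pi) * sv[sub, None])
            integrand = 2.0 * ww * density * mass(b, d[sub, None], scale[sub, None])
            acc += span * (integrand @ w)
        out[sub] = acc
    return out


@lru_cache(maxsize=8)
def _leggauss01(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


_EPS_TAIL = 6.5  # decision-noise draws beyond this many SDs are negligible


def _decision_noise_expectation(a, q, sigma_d, delta, scale, n_nodes):
    """``E_eps[M(b(eps))]`` with ``b = sqrt(max(a + sigma_d eps, 0) / q)``.

    ``M`` is the probability mass of the measured offset inside ``+-b``.
    The integrand has a square-root kink at ``eps0 = -a / sigma_d``; cells
    where the kink falls inside the Gaussian mass are integrated with the
    substitution ``eps = eps0 + t^2`` (Gauss-Legendre), the rest with plain
    Gauss-Hermite.
    """
    a, q, delta, scale = np.broadcast_arrays(a, q, delta, scale)
    flat_a = a.ravel()
    flat_q = q.ravel()
    flat_d = delta.ravel()
    flat_c = scale.ravel()
    out = np.zeros(flat_a.shape)
    eps0 = -flat_a / sigma_d

    def mass(b, d, c):
        return ndtr((b - d) / c) - ndtr((-b - d) / c)

    gh = eps0 <= -_EPS_TAIL  # kink far in the left tail: integrand smooth
    if np.any(gh):
        nodes, weights = _hermgauss(n_nodes)
        shifted = flat_a[gh, None] + sigma_d * nodes[None, :]
        b = np.sqrt(np.clip(shifted, 0.0, None) / flat_q[gh, None])
        out[gh] = mass(b, flat_d[gh, None], flat_c[gh, None]) @ weights

    gl = (~gh) & (eps0 < _EPS_TAIL)  # kink inside the mass: substitute
    if np.any(gl):
        x, w = _leggauss01(n_nodes)
        span = np.sqrt(_EPS_TAIL - eps0[gl])
        t = span[:, None] * x[None, :]
        eps = eps0[gl, None] + t**2
        b = t * np.sqrt(sigma_d / flat_q[gl, None])
        integrand = (
            2.0 * t * np.exp(-0.5 * eps**2) / np.sqrt(2.0 * np.pi)
            * mass(b, flat_d[gl, None], flat_c[gl, None])
        )
        out[gl] = span * (integrand @ w)
    # eps0 >= tail: the accept region is empty with overwhelming probability
    return out.reshape(a.shape)


def _p_decision_noise(params: ObserverParams, ecc, delta, vbar, sigma, n_nodes=GH_NODES,
                      chunk=256):
    """E[P("collinear")] under decision noise on the decision variable.

    Conditioned on the decision-noise draw ``eps``, the rule accepts iff
    ``u^2 <= (A(v) + sigma_d eps) / q``, so the integral over ``u`` is
    analytic and only (v, eps) need quadrature.
    """
    nodes, weights = _hermgauss(n_nodes)
    sigma_x_a, sigma_y_a = _assumed_sigmas(params, sigma)
    out = np.empty(len(ecc))
    for start in range(0, len(ecc), chunk):
        sl = slice(start, start + chunk)
        e, d, vb, s = ecc[sl], delta[sl], vbar[sl], sigma[sl]
        sa = np.broadcast_to(np.asarray(sigma_x_a)[sl], s.shape)
        v = vb[:, None] + (s / np.sqrt(2.0))[:, None] * nodes[None, :]
        a_v, q = _accept_quadratic(
            v, e[:, None], sa[:, None], sigma_y_a, params.p_common
        )
        inner = _decision_noise_expectation(
            a_v,
            np.asarray(q),
            params.sigma_d,
            d[:, None],
            (np.sqrt(2.0) * s)[:, None],
            n_nodes,
        )
        out[sl] = inner @ weights
    return out


def p_collinear_response(params: ObserverParams, trials, n_nodes: int = GH_NODES):
    """Probability of responding "collinear" for each collinearity trial.

    Returns a scalar for a single :class:`TrialRecord`, else an array.
    """
    single = isinstance(trials, TrialRecord)
    prepared = trials if isinstance(trials, PreparedTrials) else prepare_trials(trials)
    if len(prepared.height_pos):
        raise ValueError("p_collinear_response requires collinearity-task trials")
    p = _p_collinear_arrays(
        params, prepared.coll_ecc, prepared.coll_delta, prepared.coll_vbar,
        prepared.lag_pos, n_nodes,
    )
    return float(p[0]) if single else p


def p_right_higher(params: ObserverParams, trials):
    """Probability of responding "right higher" for each height trial."""
    single = isinstance(trials, TrialRecord)
    trials, ecc, y_left, y_right = _trial_arrays(trials)
    for t in trials:
        if t.task != HEIGHT:
            raise ValueError("p_right_higher requires height-task trials")
    sigma = params.noise.sigma_at(ecc)
    p = ndtr((y_right - y_left) / (np.sqrt(2.0) * sigma))
    p = 0.5 * params.lapse + (1.0 - params.lapse) * p
    return float(p[0]) if single else p


def decide_collinear(params: ObserverParams, trials, x_left, x_right, rng=None) -> np.ndarray:
    """Apply the model's deterministic/stochastic rule to given measurements.

    This is the forward-simulation route: threshold models compare
    ``|x_L - x_R|`` to their criterion (strictly), Bayesian models threshold
    the decision variable at zero (ties count as "collinear"), and
    decision-noise models jitter the variable first (requires ``rng``).
    """
    trials, ecc, _, _ = _trial_arrays(trials)
    x_left = np.asarray(x_left, dtype=float)
    x_right = np.asarray(x_right, dtype=float)
    sigma = params.noise.sigma_at(ecc)
    if params.model_id in THRESHOLD_MODELS:
        kappa = np.clip(effective_criterion(params, trials), 0.0, None)
        return np.abs(x_left - x_right) < kappa
    if params.model_id in BAYES_QUAD_MODELS + DECISION_NOISE_MODELS:
        sigma_x_a, sigma_y_a = _assumed_sigmas(params, sigma)
        d_star = bayes_log_posterior_ratio(x_left, x_right, ecc, sigma_x_a, sigma_y_a, params.p_common)
        if params.model_id in DECISION_NOISE_MODELS:
            if rng is None:
                raise ValueError("decision-noise models need an rng for simulation")
            d_star = d_star + params.sigma_d * rng.standard_normal(d_star.shape)
        return d_star >= 0
    raise ValueError(f"model {params.model_id!r} has no collinearity rule")


@dataclass(frozen=True)
class PreparedTrials:
    """Array view of a trial list for fast repeated likelihood evaluation.

    ``lag_pos`` holds, per collinearity trial and history lag, the index of
    the lagged trial within the collinearity block (the current trial's own
    index before the session start), so the History criterion is a pure
    array lookup.
    """

    n: int
    coll_pos: np.ndarray
    coll_ecc: np.ndarray
    coll_delta: np.ndarray
    coll_vbar: np.ndarray
    coll_first: np.ndarray | None
    lag_pos: np.ndarray
    height_pos: np.ndarray
    height_ecc: np.ndarray
    height_dy: np.ndarray
    height_first: np.ndarray | None


def prepare_trials(trials) -> PreparedTrials:
    """Precompute the arrays used by the likelihood for a trial list."""
    if isinstance(trials, TrialRecord):
        trials = [trials]
    trials = list(trials)
    coll = [(i, t) for i, t in enumerate(trials) if t.task == COLLINEARITY]
    height = [(i, t) for i, t in enumerate(trials) if t.task == HEIGHT]
    if len(coll) + len(height) != len(trials):
        bad = {t.task for t in trials} - {COLLINEARITY, HEIGHT}
        raise ValueError(f"unknown task label(s) {sorted(bad)}")

    coll_trials = [t for _, t in coll]
    lag_pos = np.empty((len(coll_trials), HISTORY_LAGS + 1), dtype=int)
    if coll_trials:
        offsets = np.arange(len(coll_trials))
        for start, stop in _session_runs(coll_trials):
            for k in range(HISTORY_LAGS + 1):
                lagged = offsets[start:stop] - k
                below = lagged < start
                lag_pos[start:stop, k] = np.where(below, offsets[start:stop], lagged)

    def first_or_none(sub, label):
        if any(t.response is None for t in sub):
            return None
        return np.array([t.response == label for t in sub])

    return PreparedTrials(
        n=len(trials),
        coll_pos=np.array([i for i, _ in coll], dtype=int),
        coll_ecc=np.array([t.eccentricity for t in coll_trials]),
        coll_delta=np.array([t.y_left - t.y_right for t in coll_trials]),
        coll_vbar=np.array([0.5 * (t.y_left + t.y_right) for t in coll_trials]),
        coll_first=first_or_none(coll_trials, COLLINEAR),
        lag_pos=lag_pos,
        height_pos=np.array([i for i, _ in height], dtype=int),
        height_ecc=np.array([t.eccentricity for _, t in height]),
        height_dy=np.array([t.y_right - t.y_left for _, t in height]),
        height_first=first_or_none([t for _, t in height], RIGHT_HIGHER),
    )


def _criterion_arrays(params: ObserverParams, ecc, sigma, lag_pos) -> np.ndarray:
    if params.model_id == FIXED:
        return np.full(len(ecc), float(params.kappa))
    if params.model_id == LIN:
        return params.kappa0 + params.kappa1 * sigma
    if params.model_id == NONPARAMETRIC:
        crit = np.asarray(params.level_criteria, dtype=float)
        return crit[params.noise.level_index(ecc)]
    if params.model_id == HISTORY:
        weights = np.asarray(params.history_weights, dtype=float)
        return params.kappa0 + sigma[lag_pos] @ weights
    raise ValueError(f"{params.model_id} has no offset criterion")


def _p_collinear_arrays(params, ecc, delta, vbar, lag_pos, n_nodes=GH_NODES):
    sigma = params.noise.sigma_at(ecc)
    if params.model_id in THRESHOLD_MODELS:
        p = _p_threshold(_criterion_arrays(params, ecc, sigma, lag_pos), delta, sigma)
    elif params.model_id in BAYES_QUAD_MODELS:
        p = _p_bayes_quad(params, ecc, delta, vbar, sigma, n_nodes)
    elif params.model_id in DECISION_NOISE_MODELS:
        p = _p_decision_noise(params, ecc, delta, vbar, sigma, n_nodes)
    else:
        raise ValueError(f"model {params.model_id!r} has no collinearity rule")
    if np.any(p < -1e-6) or np.any(p > 1 + 1e-6):
        raise FloatingPointError("quadrature produced probabilities outside [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    return 0.5 * params.lapse + (1.0 - params.lapse) * p


def response_log_probs(params: ObserverParams, trials) -> np.ndarray:
    """Log probability of each trial's recorded response."""
    prepared = trials if isinstance(trials, PreparedTrials) else prepare_trials(trials)
    if (len(prepared.coll_pos) and prepared.coll_first is None) or (
        len(prepared.height_pos) and prepared.height_first is None
    ):
        raise ValueError("all trials must carry responses")
    out = np.empty(prepared.n)
    with np.errstate(divide="ignore"):
        if len(prepared.coll_pos):
            p = _p_collinear_arrays(
                params, prepared.coll_ecc, prepared.coll_delta, prepared.coll_vbar,
                prepared.lag_pos,
            )
            out[prepared.coll_pos] = np.where(
                prepared.coll_first, np.log(p), np.log1p(-p)
            )
        if len(prepared.height_pos):
            sigma = params.noise.sigma_at(prepared.height_ecc)
            p = ndtr(prepared.height_dy / (np.sqrt(2.0) * sigma))
            p = 0.5 * params.lapse + (1.0 - params.lapse) * p
            out[prepared.height_pos] = np.where(
                prepared.height_first, np.log(p), np.log1p(-p)
            )
    return out


def dataset_log_likelihood(params: ObserverParams, trials, pointwise: bool = False):
    """Total log-likelihood of the responses; optionally the per-trial vector.

    A zero-probability response (possible only at ``lapse = 0``) yields
    ``-inf``, which is allowed but flagged with a warning.
    """
    lp = response_log_probs(params, trials)
    total = float(np.sum(lp))
    if not np.isfinite(total):
        warnings.warn(
            "dataset contains zero-probability responses (log-likelihood -inf)",
            RuntimeWarning,
            stacklevel=2,
        )
    if pointwise:
        return total, lp
    return total


# ---------------------------------------------------------------------------
# Parameter spaces (free parameters, bounds, transforms)


@dataclass(frozen=True)
class ParamEntry:
    name: str
    lower: float
    upper: float
    log_scale: bool = False


# Default bounds; the source study states only "reasonably large bounds".
_SIGMA_BOUNDS = (0.05, 10.0, True)
_LAPSE_BOUNDS = (0.0, 0.3, False)
_PCOMMON_BOUNDS = (0.1, 0.9, False)
_KAPPA_POS_BOUNDS = (0.0, 5.0, False)
_KAPPA_BOUNDS = (-5.0, 5.0, False)
_SIGMA_D_BOUNDS = (0.01, 20.0, True)
_SIGMA_YA_BOUNDS = (0.05, 5.0, True)
_MM_BOUNDS = (0.0, 5.0, False)


@dataclass(frozen=True)
class ParamSpace:
    """Mapping between a model's free-parameter vector and ObserverParams."""

    model_id: str
    levels: tuple[float, ...]
    entries: tuple[ParamEntry, ...]
    fixed_noise: NoiseProfile | None = None
    sigma_y: float = 0.48

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def n_params(self) -> int:
        return len(self.entries)

    def to_params(self, theta) -> ObserverParams:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.entries),):
            raise ValueError(f"expected {len(self.entries)} parameters, got {theta.shape}")
        values = dict(zip(self.names, theta))
        if self.fixed_noise is not None:
            noise = self.fixed_noise
        else:
            noise = NoiseProfile(self.levels, tuple(values.pop(f"sigma_{i}") for i in range(len(self.levels))))
        kwargs: dict = {"model_id": self.model_id, "noise": noise, "sigma_y": self.sigma_y}
        m = self.model_id
        kwargs["lapse"] = values.pop("lapse")
        if m == FIXED:
            kwargs["kappa"] = values.pop("kappa")
        elif m == BAYES:
            kwargs["p_common"] = values.pop("p_common")
        elif m == LIN:
            kwargs["kappa0"] = values.pop("kappa0")
            kwargs["kappa1"] = values.pop("kappa1")
        elif m == HISTORY:
            kwargs["kappa0"] = values.pop("kappa0")
            kwargs["history_weights"] = tuple(values.pop(f"w{k}") for k in range(HISTORY_LAGS + 1))
        elif m == NOISE_MISMATCH:
            kwargs["mm_a"] = values.pop("mm_a")
            kwargs["mm_b"] = values.pop("mm_b")
            kwargs["p_common"] = 0.5
        elif m == WIDTH_MISMATCH:
            kwargs["p_common"] = values.pop("p_common")
            kwargs["sigma_y_assumed"] = values.pop("sigma_y_assumed")
        elif m == BAYES_DN:
            kwargs["p_common"] = values.pop("p_common")
            kwargs["sigma_d"] = values.pop("sigma_d")
        elif m == HYBRID_DN_WIDTH:
            kwargs["p_common"] = values.pop("p_common")
            kwargs["sigma_y_assumed"] = values.pop("sigma_y_assumed")
            kwargs["sigma_d"] = values.pop("sigma_d")
        elif m == NONPARAMETRIC:
            kwargs["level_criteria"] = tuple(
                values.pop(f"kappa_at_{i}") for i in range(len(self.levels))
            )
        elif m == HEIGHT_JUDGMENT:
            pass
        if values:
            raise RuntimeError(f"unconsumed parameters: {sorted(values)}")
        return ObserverParams(**kwargs)

    def from_params(self, params: ObserverParams) -> np.ndarray:
        values: dict[str, float] = {}
        if self.fixed_noise is None:
            for i, level in enumerate(self.levels):
                values[f"sigma_{i}"] = params.noise.sigma_at(level)[0]
        values["lapse"] = params.lapse
        m = self.model_id
        if m == FIXED:
            values["kappa"] = params.kappa
        elif m == BAYES:
            values["p_common"] = params.p_common
        elif m == LIN:
            values["kappa0"] = params.kappa0
            values["kappa1"] = params.kappa1
        elif m == HISTORY:
            values["kappa0"] = params.kappa0
            for k, w in enumerate(params.history_weights):
                values[f"w{k}"] = w
        elif m == NOISE_MISMATCH:
            values["mm_a"] = params.mm_a
            values["mm_b"] = params.mm_b
        elif m == WIDTH_MISMATCH:
            values["p_common"] = params.p_common
            values["sigma_y_assumed"] = params.sigma_y_assumed
        elif m == BAYES_DN:
            values["p_common"] = params.p_common
            values["sigma_d"] = params.sigma_d
        elif m == HYBRID_DN_WIDTH:
            values["p_common"] = params.p_common
            values["sigma_y_assumed"] = params.sigma_y_assumed
            values["sigma_d"] = params.sigma_d
        elif m == NONPARAMETRIC:
            for i, c in enumerate(params.level_criteria):
                values[f"kappa_at_{i}"] = c
        return np.array([values[name] for name in self.names])


def param_space(
    model_id: str,
    levels: Sequence[float],
    *,
    fixed_noise: NoiseProfile | None = None,
    sigma_y: float = 0.48,
) -> ParamSpace:
    """Free-parameter space for a model (optionally with an imported,
    fixed noise profile as in the constrained fits)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    levels = tuple(float(v) for v in levels)
    if fixed_noise is not None and tuple(fixed_noise.levels) != levels:
        raise ValueError("fixed noise profile levels must match the requested levels")
    entries: list[ParamEntry] = []
    if fixed_noise is None:
        for i in range(len(levels)):
            entries.append(ParamEntry(f"sigma_{i}", *_SIGMA_BOUNDS))
    entries.append(ParamEntry("lapse", *_LAPSE_BOUNDS))
    if model_id == FIXED:
        entries.append(ParamEntry("kappa", *_KAPPA_POS_BOUNDS))
    elif model_id == BAYES:
        entries.append(ParamEntry("p_common", *_PCOMMON_BOUNDS))
    elif model_id == LIN:
        entries.append(ParamEntry("kappa0", *_KAPPA_BOUNDS))
        entries.append(ParamEntry("kappa1", *_KAPPA_BOUNDS))
    elif model_id == HISTORY:
        entries.append(ParamEntry("kappa0", *_KAPPA_BOUNDS))
        for k in range(HISTORY_LAGS + 1):
            entries.append(ParamEntry(f"w{k}", *_KAPPA_BOUNDS))
    elif model_id == NOISE_MISMATCH:
        entries.append(ParamEntry("mm_a", *_MM_BOUNDS))
        entries.append(ParamEntry("mm_b", *_MM_BOUNDS))
    elif model_id == WIDTH_MISMATCH:
        entries.append(ParamEntry("p_common", *_PCOMMON_BOUNDS))
        entries.append(ParamEntry("sigma_y_assumed", *_SIGMA_YA_BOUNDS))
    elif model_id == BAYES_DN:
        entries.append(ParamEntry("p_common", *_PCOMMON_BOUNDS))
        entries.append(ParamEntry("sigma_d", *_SIGMA_D_BOUNDS))
    elif model_id == HYBRID_DN_WIDTH:
        entries.append(ParamEntry("p_common", *_PCOMMON_BOUNDS))
        entries.append(ParamEntry("sigma_y_assumed", *_SIGMA_YA_BOUNDS))
        entries.append(ParamEntry("sigma_d", *_SIGMA_D_BOUNDS))
    elif model_id == NONPARAMETRIC:
        for i in range(len(levels)):
            entries.append(ParamEntry(f"kappa_at_{i}", *_KAPPA_POS_BOUNDS))
    elif model_id == HEIGHT_JUDGMENT:
        pass
    return ParamSpace(model_id, levels, tuple(entries), fixed_noise=fixed_noise, sigma_y=sigma_y)


def free_parameter_count(model_id: str, n_levels: int = 4, constrained: bool = False) -> int:
    """Number of free parameters of a model (optionally noise-constrained)."""
    levels = tuple(float(i) for i in range(n_levels))
    noise = NoiseProfile(levels, (1.0,) * n_levels) if constrained else None
    return param_space(model_id, levels, fixed_noise=noise).n_params


# ---------------------------------------------------------------------------
# Parameter file round-trip (plain-text key = value)

_SCALAR_FIELDS = (
    "lapse",
    "sigma_y",
    "p_common",
    "kappa",
    "kappa0",
    "kappa1",
    "mm_a",
    "mm_b",
    "sigma_y_assumed",
    "sigma_d",
)


def write_params(path_or_buffer, params: ObserverParams) -> None:
    """Write an ObserverParams to a plain-text key = value file."""
    lines = [f"model_id = {params.model_id}"]
    for name in _SCALAR_FIELDS:
        value = getattr(params, name)
        if value is not None:
            lines.append(f"{name} = {value!r}")
    for level, sigma in zip(params.noise.levels, params.noise.sigmas):
        lines.append(f"noise[{level!r}] = {sigma!r}")
    if params.history_weights is not None:
        lines.append("history_weights = " + " ".join(repr(w) for w in params.history_weights))
    if params.level_criteria is not None:
        lines.append("level_criteria = " + " ".join(repr(c) for c in params.level_criteria))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "w") as fh:
            fh.write(text)


def read_params(path_or_buffer) -> ObserverParams:
    """Read an ObserverParams from a plain-text key = value file."""
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    values: dict[str, float] = {}
    noise: dict[float, float] = {}
    model_id = None
    history_weights = None
    level_criteria = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line {lineno}: {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "model_id":
            model_id = value
        elif key.startswith("noise[") and key.endswith("]"):
            noise[float(key[6:-1])] = float(value)
        elif key == "history_weights":
            history_weights = tuple(float(v) for v in value.split())
        elif key == "level_criteria":
            level_criteria = tuple(float(v) for v in value.split())
        elif key in _SCALAR_FIELDS:
            values[key] = float(value)
        else:
            raise ValueError(f"unknown parameter key {key!r} on line {lineno}")
    if model_id is None:
        raise ValueError("parameter file is missing model_id")
    if not noise:
        raise ValueError("parameter file is missing noise entries")
    kwargs = dict(values)
    if history_weights is not None:
        kwargs["history_weights"] = history_weights
    if level_criteria is not None:
        kwargs["level_criteria"] = level_criteria
    return ObserverParams(model_id=model_id, noise=NoiseProfile.from_dict(noise), **kwargs)
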