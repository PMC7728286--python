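"""Posterior sampling and point estimation for observer models.

Fitting works in a transformed coordinate system where scale parameters
(noise SDs, decision noise, assumed width) are log-transformed; the prior is
uniform in those coordinates within fixed bounds, so the log posterior is
the data log-likelihood plus a constant inside the box.

The sampler is coordinate-wise slice sampling with stepping-out and
shrinkage; chains start from jittered MAP estimates.  Convergence is
monitored with the Gelman-Rubin potential scale reduction statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .models import ObserverParams, ParamSpace, dataset_log_likelihood, prepare_trials

__all__ = [
    "PriorSpec",
    "MapResult",
    "PosteriorSamples",
    "map_fit",
    "sample_posterior",
    "gelman_rubin",
    "slice_sample",
]

_BAD = -1e12  # optimizer-safe stand-in for log posterior -inf


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter uniform prior bounds; scale parameters are uniform in
    log space."""

    space: ParamSpace
    lower: np.ndarray
    upper: np.ndarray
    log_scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower >= self.upper):
            raise ValueError("prior bounds require lower < upper")
        if np.any(self.log_scale & (self.lower <= 0)):
            raise ValueError("log-scale parameters need positive lower bounds")

    @classmethod
    def from_space(cls, space: ParamSpace, overrides: dict | None = None) -> "PriorSpec":
        lower = np.array([e.lower for e in space.entries], dtype=float)
        upper = np.array([e.upper for e in space.entries], dtype=float)
        log_scale = np.array([e.log_scale for e in space.entries], dtype=bool)
        if overrides:
            names = list(space.names)
            for name, bounds in overrides.items():
                i = names.index(name)
                lower[i], upper[i] = bounds
        return cls(space, lower, upper, log_scale)

    @property
    def names(self) -> tuple[str, ...]:
        return self.space.names

    def transform(self, theta: np.ndarray) -> np.ndarray:
        """Natural -> sampling coordinates."""
        theta = np.asarray(theta, dtype=float)
        return np.where(self.log_scale, np.log(np.where(self.log_scale, theta, 1.0)), theta)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        """Sampling -> natural coordinates."""
        z = np.asarray(z, dtype=float)
        return np.where(self.log_scale, np.exp(z), z)

    @property
    def t_lower(self) -> np.ndarray:
        return self.transform(self.lower)

    @property
    def t_upper(self) -> np.ndarray:
        return self.transform(self.upper)

    def in_bounds(self, z: np.ndarray) -> bool:
        return bool(np.all(z >= self.t_lower) and np.all(z <= self.t_upper))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.t_lower, self.t_upper, size=(n, len(self.lower)))


def make_log_posterior(prior: PriorSpec, trials) -> Callable[[np.ndarray], float]:
    """Log posterior (up to a constant) as a function of sampling coordinates."""
    from .models import PreparedTrials

    if not isinstance(trials, PreparedTrials):
        trials = prepare_trials(list(trials))

    def log_post(z: np.ndarray) -> float:
        if not prior.in_bounds(z):
            return -np.inf
        params = prior.space.to_params(prior.inverse(z))
        ll = dataset_log_likelihood(params, trials)
        return ll if np.isfinite(ll) else -np.inf

    return log_post


@dataclass(frozen=True)
class MapResult:
    params: ObserverParams
    theta: np.ndarray
    z: np.ndarray
    log_posterior: float
    n_starts: int


def map_fit(prior: PriorSpec, trials, n_starts: int = 8, rng_seed=0) -> MapResult:
    """Best of ``n_starts`` bounded optimizations of the log posterior.

    Deterministic given the seed.  The first start is the prior midpoint
    (in sampling coordinates), the rest are uniform prior draws.
    """
    rng = np.random.default_rng(rng_seed)
    log_post = make_log_posterior(prior, trials)  # accepts PreparedTrials too

    def objective(z):
        lp = log_post(z)
        return -lp if np.isfinite(lp) else -_BAD

    tl, tu = prior.t_lower, prior.t_upper
    starts = [0.5 * (tl + tu)]
    starts.extend(prior.sample(rng, max(0, n_starts - 1)))
    bounds = list(zip(tl, tu))
    best = None
    for z0 in starts[:n_starts]:
        if not np.isfinite(log_post(z0)):
            continue
        # Powell first: clipped criteria create plateaus where gradient
        # methods stall; its long line searches escape them.
        res = minimize(
            objective, z0, method="Powell", bounds=bounds,
            options={"maxfev": 250 * len(z0)},
        )
        polish = minimize(objective, res.x, method="L-BFGS-B", bounds=bounds)
        if polish.fun < res.fun:
            res = polish
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("map_fit: no start point had a finite posterior")
    z = np.clip(best.x, tl, tu)
    theta = prior.inverse(z)
    return MapResult(
        params=prior.space.to_params(theta),
        theta=theta,
        z=z,
        log_posterior=-float(best.fun),
        n_starts=len(starts),
    )


def _laplace_widths(log_post, z_map, lower, upper, rel_step=1e-3):
    """Per-coordinate slice widths ~ 3 posterior SDs from a diagonal
    Laplace approximation at the MAP; falls back to range/10 where the
    curvature is unusable (flat or boundary-pinned directions)."""
    span = upper - lower
    widths = span / 10.0
    f0 = log_post(z_map)
    for i in range(len(z_map)):
        e = rel_step * span[i]
        zp, zm = z_map.copy(), z_map.copy()
        zp[i] = min(z_map[i] + e, upper[i])
        zm[i] = max(z_map[i] - e, lower[i])
        h = zp[i] - zm[i]
        if h <= 0:
            continue
        curv = (log_post(zp) - 2.0 * f0 + log_post(zm)) / (0.5 * h) ** 2
        if np.isfinite(curv) and curv < 0:
            sd = 1.0 / np.sqrt(-curv)
            # only ever widen: narrow widths stall mixing along ridges,
            # while over-wide ones just cost a few shrinkage steps
            widths[i] = float(np.clip(3.0 * sd, span[i] / 10.0, span[i]))
    return widths


def _slice_update_coord(log_post, z, i, width, lo, hi, log_fz, rng, max_steps=1000):
    """One stepping-out + shrinkage slice-sampling update of coordinate i."""
    log_y = log_fz - rng.exponential()
    x0 = z[i]

    def f_at(x):
        z[i] = x
        return log_post(z)

    u = rng.uniform(0.0, width)
    left = x0 - u
    right = left + width
    steps = 0
    while left > lo and f_at(left) > log_y and steps < max_steps:
        left -= width
        steps += 1
    left = max(left, lo)
    steps = 0
    while right < hi and f_at(right) > log_y and steps < max_steps:
        right += width
        steps += 1
    right = min(right, hi)

    for _ in range(max_steps):
        x1 = rng.uniform(left, right)
        log_f1 = f_at(x1)
        if log_f1 >= log_y:
            z[i] = x1
            return log_f1
        if x1 < x0:
            left = x1
        else:
            right = x1
    z[i] = x0  # shrinkage failed to move; keep the current point
    return log_fz


def _slice_update_line(log_post, z, direction, lower, upper, log_fz, rng, max_steps=1000):
    """Slice update along an arbitrary direction (helps ridge mixing).

    The step scale is baked into ``direction``; the line is clipped to the
    prior box analytically.
    """
    log_y = log_fz - rng.exponential()
    with np.errstate(divide="ignore", invalid="ignore"):
        to_upper = np.where(direction != 0, (upper - z) / direction, np.inf)
        to_lower = np.where(direction != 0, (lower - z) / direction, -np.inf)
    t_hi = float(np.min(np.maximum(to_upper, to_lower)))
    t_lo = float(np.max(np.minimum(to_upper, to_lower)))

    def f_at(t):
        return log_post(z + t * direction)

    u = rng.uniform(0.0, 1.0)
    left, right = -u, 1.0 - u
    steps = 0
    while left > t_lo and f_at(left) > log_y and steps < max_steps:
        left -= 1.0
        steps += 1
    left = max(left, t_lo)
    steps = 0
    while right < t_hi and f_at(right) > log_y and steps < max_steps:
        right += 1.0
        steps += 1
    right = min(right, t_hi)

    for _ in range(max_steps):
        t1 = rng.uniform(left, right)
        log_f1 = f_at(t1)
        if log_f1 >= log_y:
            z += t1 * direction
            return log_f1
        if t1 < 0:
            left = t1
        else:
            right = t1
    return log_fz


def slice_sample(log_post, z0, n_samples, widths, lower, upper, rng, burn_in=0,
                 n_line_updates=2):
    """Coordinate-wise slice sampling of ``log_post`` from ``z0``.

    Each sweep updates every coordinate, then performs ``n_line_updates``
    slice moves along random directions (scaled by the widths), which
    speeds up mixing along correlated parameter ridges.  Returns
    ``(draws, log_posts)`` with post-burn-in draws only.
    """
    z = np.array(z0, dtype=float)
    k = len(z)
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (k,))
    log_fz = log_post(z)
    if not np.isfinite(log_fz):
        raise RuntimeError("slice_sample: non-finite log posterior at initialization")
    draws = np.empty((n_samples, k))
    log_posts = np.empty(n_samples)
    for it in range(burn_in + n_samples):
        for i in range(k):
            log_fz = _slice_update_coord(
                log_post, z, i, widths[i], lower[i], upper[i], log_fz, rng
            )
        for _ in range(n_line_updates):
            direction = rng.standard_normal(k) * widths
            norm = np.linalg.norm(direction / widths)
            if norm > 0:
                log_fz = _slice_update_line(
                    log_post, z, direction / norm, lower, upper, log_fz, rng
                )
        if it >= burn_in:
            draws[it - burn_in] = z
            log_posts[it - burn_in] = log_fz
    return draws, log_posts


@dataclass
class PosteriorSamples:
    """MCMC draws with per-trial pointwise log-likelihoods.

    ``draws`` holds natural-scale parameters with shape
    (chains, samples, params); ``pointwise_loglik`` has shape
    (chains * samples, trials).
    """

    model_id: str
    names: tuple[str, ...]
    draws: np.ndarray
    draws_z: np.ndarray
    log_posterior: np.ndarray
    pointwise_loglik: np.ndarray
    rhat: np.ndarray
    seed: int | None
    prior: PriorSpec

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def merged(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def params_at(self, index: int) -> ObserverParams:
        return self.prior.space.to_params(self.merged[index])

    def posterior_mean_params(self) -> ObserverParams:
        return self.prior.space.to_params(self.merged.mean(axis=0))


def sample_posterior(
    prior: PriorSpec,
    trials,
    *,
    n_chains: int = 3,
    n_samples: int = 2000,
    burn_in: int = 500,
    rng_seed=0,
    map_starts: int = 6,
    init: MapResult | None = None,
    widths=None,
    n_line_updates: int = 2,
) -> PosteriorSamples:
    """Slice-sample the posterior; chains are initialized at jittered MAP
    estimates and merged after computing per-parameter R-hat."""
    trials = list(trials)
    if not trials:
        raise ValueError("sample_posterior requires a nonempty trial list")
    prepared_for_eval = prepare_trials(trials)
    seed_seq = (
        rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    )
    map_seed, *chain_seeds = seed_seq.spawn(n_chains + 1)
    if init is None:
        init = map_fit(
            prior, prepared_for_eval, n_starts=map_starts, rng_seed=np.random.default_rng(map_seed)
        )
    log_post = make_log_posterior(prior, prepared_for_eval)
    tl, tu = prior.t_lower, prior.t_upper
    if widths is None:
        widths = _laplace_widths(log_post, init.z, tl, tu)

    all_draws = np.empty((n_chains, n_samples, len(tl)))
    all_lp = np.empty((n_chains, n_samples))
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        for _ in range(100):
            z0 = np.clip(init.z + 0.02 * widths * rng.standard_normal(len(tl)), tl, tu)
            if np.isfinite(log_post(z0)):
                break
        else:
            raise RuntimeError("could not find a finite-posterior chain start")
        draws, lps = slice_sample(
            log_post, z0, n_samples, widths, tl, tu, rng, burn_in=burn_in,
            n_line_updates=n_line_updates,
        )
        all_draws[c] = draws
        all_lp[c] = lps

    rhat = gelman_rubin(all_draws)
    natural = prior.inverse(all_draws.reshape(-1, len(tl))).reshape(all_draws.shape)

    merged_nat = natural.reshape(-1, len(tl))
    prepared = prepare_trials(trials)
    pointwise = np.empty((merged_nat.shape[0], prepared.n))
    for s in range(merged_nat.shape[0]):
        params = prior.space.to_params(merged_nat[s])
        _, lp = dataset_log_likelihood(params, prepared, pointwise=True)
        pointwise[s] = lp

    return PosteriorSamples(
        model_id=prior.space.model_id,
        names=prior.names,
        draws=natural,
        draws_z=all_draws,
        log_posterior=all_lp,
        pointwise_loglik=pointwise,
        rhat=rhat,
        seed=rng_seed if isinstance(rng_seed, (int, np.integer)) else None,
        prior=prior,
    )


def gelman_rubin(chain_draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction statistic per parameter.

    ``chain_draws`` has shape (chains, samples, params).  Uses the classic
    between/within variance ratio; identical chains give
    ``sqrt((n - 1) / n)``, i.e. 1 up to O(1/n).
    """
    draws = np.asarray(chain_draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[..., None]
    m, n, k = draws.shape
    if m < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("gelman_rubin requires at least 10 draws per chain")
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    if np.any(w == 0):
        bad = np.flatnonzero(w == 0).tolist()
        raise FloatingPointError(f"zero within-chain variance for parameter index(es) {bad}")
    var_plus = (n - 1) / n * w + b / n
    return np.sqrt(var_plus / w)
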