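"""Downstream analyses: psychometric binning, height-task noise import,
suboptimality/efficiency, posterior-predictive curves and recovery
harnesses."""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import comparison as _comparison
from . import inference as _inference
from . import models as _models
from . import synthetic as _synthetic
from .models import HEIGHT_JUDGMENT, BAYES, NoiseProfile, ObserverParams
from .synthetic import COLLINEAR, COLLINEARITY, HEIGHT, RIGHT_HIGHER, TaskDesign

__all__ = [
    "DEFAULT_BIN_EDGES",
    "EfficiencyReport",
    "bin_offsets",
    "bin_psychometric",
    "import_height_noise",
    "optimal_accuracy",
    "efficiency",
    "posterior_predictive_curves",
    "parameter_recovery",
    "model_recovery",
]

#: Inner edges of the offset bins (dva); outer bins are open-ended.  Bins are
#: left-open, right-closed: (-inf, -3.31], (-3.31, -2.08], ..., (3.31, inf).
DEFAULT_BIN_EDGES = (-3.31, -2.08, -1.17, -0.38, 0.38, 1.17, 2.08, 3.31)


def bin_offsets(offsets, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> np.ndarray:
    """Assign each offset (``y_left - y_right``) to its half-open bin.

    Bin ``i`` is ``(edges[i-1], edges[i]]``; an offset equal to an edge falls
    in the bin that edge closes.  Returns indices in ``0..len(edges)``.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return np.searchsorted(edges, np.asarray(offsets, dtype=float), side="left")


def _response_is_first(trials) -> tuple[np.ndarray, str]:
    tasks = {t.task for t in trials}
    if len(tasks) != 1:
        raise ValueError("trials must come from a single task")
    task = tasks.pop()
    target = COLLINEAR if task == COLLINEARITY else RIGHT_HIGHER
    if any(t.response is None for t in trials):
        raise ValueError("trials must carry responses")
    return np.array([t.response == target for t in trials]), task


def bin_psychometric(trials, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Per eccentricity x offset-bin response proportions with binomial SE.

    The tabulated proportion is "collinear" reports for the collinearity
    task and "right higher" reports for the height task.  Empty bins carry
    ``n = 0`` and NaN proportion.
    """
    trials = list(trials)
    hits, _task = _response_is_first(trials)
    edges = tuple(edges)
    offsets = np.array([t.y_left - t.y_right for t in trials])
    ecc = np.array([t.eccentricity for t in trials])
    bins = bin_offsets(offsets, edges)
    levels = sorted(set(ecc.tolist()))
    full_edges = (-np.inf, *edges, np.inf)
    rows = []
    for level in levels:
        for b in range(len(edges) + 1):
            sel = (ecc == level) & (bins == b)
            n = int(sel.sum())
            prop = float(hits[sel].mean()) if n else np.nan
            se = float(np.sqrt(prop * (1 - prop) / n)) if n else np.nan
            rows.append(
                {
                    "eccentricity": level,
                    "bin_index": b,
                    "bin_left": full_edges[b],
                    "bin_right": full_edges[b + 1],
                    "n": n,
                    "proportion": prop,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def import_height_noise(
    trials,
    levels: Sequence[float] | None = None,
    *,
    n_chains: int = 3,
    n_samples: int = 500,
    burn_in: int = 150,
    rng_seed=0,
) -> dict:
    """Estimate a noise profile from height-task data.

    Fits the HeightJudgment observer by MCMC and returns both the
    posterior-mean and the MAP noise profile (the study ran both imports as
    a sanity check), plus the samples for inspection.
    """
    trials = list(trials)
    if any(t.task != HEIGHT for t in trials):
        raise ValueError("import_height_noise requires height-task trials")
    if levels is None:
        levels = sorted({t.eccentricity for t in trials})
    levels = tuple(float(v) for v in levels)
    present = {t.eccentricity for t in trials}
    missing = [lv for lv in levels if lv not in present]
    if missing:
        raise ValueError(f"height data has no trials at level(s) {missing}")
    space = _models.param_space(HEIGHT_JUDGMENT, levels)
    prior = _inference.PriorSpec.from_space(space)
    samples = _inference.sample_posterior(
        prior, trials, n_chains=n_chains, n_samples=n_samples, burn_in=burn_in, rng_seed=rng_seed
    )
    mean_params = samples.posterior_mean_params()
    best = int(np.argmax(samples.log_posterior.reshape(-1)))
    map_params = samples.params_at(best)
    return {
        "posterior_mean": mean_params.noise,
        "map": map_params.noise,
        "samples": samples,
    }


def optimal_accuracy(
    noise: NoiseProfile,
    design: TaskDesign,
    n_sim: int = 100_000,
    rng_seed=0,
) -> pd.DataFrame:
    """Simulated accuracy of a Bayes-optimal observer per eccentricity.

    The optimal observer uses the true ``p_common = 0.5`` prior, no lapse,
    the design's stimulus-distribution width, and the given noise profile.
    """
    if n_sim < 10_000:
        raise ValueError("n_sim must be at least 10^4 per level")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    rows = []
    for level in design.eccentricity_levels:
        level_design = dc_replace(design, eccentricity_levels=(level,))
        params = ObserverParams(
            model_id=BAYES,
            noise=NoiseProfile((level,), (noise.sigma_at(level)[0],)),
            lapse=0.0,
            p_common=0.5,
            sigma_y=design.offset_sd,
        )
        trials = _synthetic.generate_collinearity_trials(level_design, n_sim, rng)
        responded = _synthetic.simulate_responses(params, trials, rng)
        correct = np.array([t.response == t.category for t in responded])
        acc = float(correct.mean())
        rows.append(
            {
                "eccentricity": level,
                "accuracy": acc,
                "se": float(np.sqrt(acc * (1 - acc) / n_sim)),
                "n": n_sim,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EfficiencyReport:
    """Observed vs simulated-optimal accuracy and their overall ratio."""

    observed: pd.DataFrame
    optimal: pd.DataFrame
    overall_observed: float
    overall_optimal: float
    efficiency: float


def efficiency(trials, optimal: pd.DataFrame) -> EfficiencyReport:
    """Overall observed proportion correct divided by simulated optimal.

    The optimal accuracies are weighted by the observed per-level trial
    counts so both terms describe the same stimulus mix.
    """
    trials = list(trials)
    if any(t.response is None for t in trials):
        raise ValueError("trials must carry responses")
    ecc = np.array([t.eccentricity for t in trials])
    correct = np.array([t.response == t.category for t in trials])
    rows = []
    weights = {}
    for level in sorted(set(ecc.tolist())):
        sel = ecc == level
        rows.append(
            {
                "eccentricity": level,
                "accuracy": float(correct[sel].mean()),
                "n": int(sel.sum()),
            }
        )
        weights[level] = int(sel.sum())
    observed = pd.DataFrame(rows)
    opt = optimal.set_index("eccentricity")["accuracy"]
    missing = [lv for lv in weights if lv not in opt.index]
    if missing:
        raise ValueError(f"optimal accuracies missing level(s) {missing}")
    total = sum(weights.values())
    overall_observed = float(correct.mean())
    overall_optimal = float(sum(opt[lv] * w for lv, w in weights.items()) / total)
    return EfficiencyReport(
        observed=observed,
        optimal=optimal,
        overall_observed=overall_observed,
        overall_optimal=overall_optimal,
        efficiency=overall_observed / overall_optimal,
    )


def posterior_predictive_curves(
    samples: "_inference.PosteriorSamples",
    trials,
    n_draws: int = 60,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Posterior-predictive psychometric curves from equally spaced draws.

    For each selected draw the analytic response probability of every trial
    is computed and averaged within (eccentricity, offset-bin) cells; the
    returned table carries the across-draw mean and SD per cell.
    """
    trials = list(trials)
    tasks = {t.task for t in trials}
    if len(tasks) != 1:
        raise ValueError("trials must come from a single task")
    task = tasks.pop()
    merged = samples.merged
    n_total = merged.shape[0]
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    idx = np.unique(np.linspace(0, n_total - 1, num=min(n_draws, n_total)).astype(int))

    offsets = np.array([t.y_left - t.y_right for t in trials])
    ecc = np.array([t.eccentricity for t in trials])
    bins = bin_offsets(offsets, edges)
    levels = sorted(set(ecc.tolist()))
    n_bins = len(tuple(edges)) + 1

    curves = np.full((len(idx), len(levels), n_bins), np.nan)
    for d, s in enumerate(idx):
        params = samples.params_at(int(s))
        if task == COLLINEARITY:
            p = np.atleast_1d(_models.p_collinear_response(params, trials))
        else:
            p = np.atleast_1d(_models.p_right_higher(params, trials))
        for li, level in enumerate(levels):
            for b in range(n_bins):
                sel = (ecc == level) & (bins == b)
                if sel.any():
                    curves[d, li, b] = p[sel].mean()

    full_edges = (-np.inf, *tuple(edges), np.inf)
    rows = []
    for li, level in enumerate(levels):
        for b in range(n_bins):
            cell = curves[:, li, b]
            has = np.isfinite(cell)
            rows.append(
                {
                    "eccentricity": level,
                    "bin_index": b,
                    "bin_left": full_edges[b],
                    "bin_right": full_edges[b + 1],
                    "n_draws": int(has.sum()),
                    "mean": float(cell[has].mean()) if has.any() else np.nan,
                    "sd": float(cell[has].std(ddof=0)) if has.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _simulate_collinearity_dataset(true_params, design, n_trials, rng):
    trials = _synthetic.generate_collinearity_trials(design, n_trials, rng)
    return _synthetic.simulate_responses(true_params, trials, rng)


def parameter_recovery(
    model_id: str,
    true_params: ObserverParams,
    design: TaskDesign,
    n_replicates: int = 4,
    *,
    n_trials: int = 2400,
    n_chains: int = 3,
    n_samples: int = 400,
    burn_in: int = 100,
    map_starts: int = 4,
    rng_seed=0,
) -> pd.DataFrame:
    """Simulate -> fit -> compare true vs recovered parameters.

    Returns one row per free parameter with posterior-mean bias, RMS error
    and 95% central-interval coverage across replicates.
    """
    space = _models.param_space(model_id, design.eccentricity_levels, sigma_y=design.offset_sd)
    prior = _inference.PriorSpec.from_space(space)
    truth = space.from_params(true_params)
    seed_seq = (
        rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    )
    estimates = np.empty((n_replicates, space.n_params))
    covered = np.zeros((n_replicates, space.n_params), dtype=bool)
    for r, child in enumerate(seed_seq.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        data = _simulate_collinearity_dataset(true_params, design, n_trials, rng)
        samples = _inference.sample_posterior(
            prior,
            data,
            n_chains=n_chains,
            n_samples=n_samples,
            burn_in=burn_in,
            rng_seed=child.spawn(1)[0],
            map_starts=map_starts,
        )
        merged = samples.merged
        estimates[r] = merged.mean(axis=0)
        lo = np.quantile(merged, 0.025, axis=0)
        hi = np.quantile(merged, 0.975, axis=0)
        covered[r] = (truth >= lo) & (truth <= hi)
    rows = []
    for j, name in enumerate(space.names):
        err = estimates[:, j] - truth[j]
        rows.append(
            {
                "parameter": name,
                "true": truth[j],
                "recovered_mean": float(estimates[:, j].mean()),
                "bias": float(err.mean()),
                "rms_error": float(np.sqrt(np.mean(err**2))),
                "coverage_95": float(covered[:, j].mean()),
            }
        )
    return pd.DataFrame(rows)


def model_recovery(
    generating: dict[str, Sequence[ObserverParams]],
    candidate_models: Sequence[str],
    design: TaskDesign,
    *,
    n_trials: int = 600,
    n_chains: int = 3,
    n_samples: int = 150,
    burn_in: int = 50,
    map_starts: int = 4,
    rng_seed=0,
) -> dict:
    """Simulate cohorts per generating model, fit all candidates, score by
    PSIS-LOO.

    ``generating`` maps a generating model id to one ObserverParams per
    synthetic subject.  Returns the per-subject LOO table, the mean-LOO
    matrix (generators x candidates) and the winner-count confusion matrix.
    """
    if len(candidate_models) < 1:
        raise ValueError("need at least one candidate model")
    seed_seq = (
        rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    )
    candidate_models = list(candidate_models)
    spaces = {
        m: _models.param_space(m, design.eccentricity_levels, sigma_y=design.offset_sd)
        for m in candidate_models
    }
    priors = {m: _inference.PriorSpec.from_space(s) for m, s in spaces.items()}
    rows = []
    for gen_model, cohort in generating.items():
        for s_idx, (true_params, child) in enumerate(zip(cohort, seed_seq.spawn(len(cohort)))):
            rng = np.random.default_rng(child)
            data = _simulate_collinearity_dataset(true_params, design, n_trials, rng)
            fit_seeds = child.spawn(len(candidate_models))
            for m, fseed in zip(candidate_models, fit_seeds):
                samples = _inference.sample_posterior(
                    priors[m],
                    data,
                    n_chains=n_chains,
                    n_samples=n_samples,
                    burn_in=burn_in,
                    rng_seed=fseed,
                    map_starts=map_starts,
                )
                loo = _comparison.psis_loo(samples.pointwise_loglik)
                rows.append(
                    {
                        "generator": gen_model,
                        "subject": s_idx,
                        "model": m,
                        "loo": loo.loo,
                        "loo_se": loo.se,
                        "max_rhat": float(np.max(samples.rhat)),
                    }
                )
    table = pd.DataFrame(rows)
    mean_loo = table.pivot_table(index="generator", columns="model", values="loo", aggfunc="mean")
    winners = (
        table.loc[table.groupby(["generator", "subject"])["loo"].idxmax()]
        .groupby(["generator", "model"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=candidate_models, fill_value=0)
    )
    return {"table": table, "mean_loo": mean_loo, "confusion": winners}
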