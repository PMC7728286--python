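"""Synthetic trial generation for the two psychophysical tasks.

The experiment interleaves two tasks at four retinal eccentricity levels:

* *collinearity judgment* -- report whether two horizontal line segments on
  either side of an occluder are collinear (``C = 1``) or not (``C = 0``);
* *height judgment* -- report which segment is higher (a Vernier task used
  to estimate sensory noise independently of any criterion).

On a collinear trial a single vertical position is drawn from a Gaussian
centred on the trial's eccentricity level and assigned to both segments; on
a non-collinear (and every height-task) trial the two positions are drawn
independently from that same Gaussian.  All positions are in degrees of
visual angle (dva).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskDesign",
    "TrialRecord",
    "make_default_design",
    "generate_collinearity_trials",
    "generate_height_trials",
    "generate_session",
    "generate_subject",
    "simulate_responses",
    "trials_to_frame",
    "frame_to_trials",
]

# Task labels
COLLINEARITY = "collinearity"
HEIGHT = "height"

# Category / response labels
COLLINEAR = "collinear"
NONCOLLINEAR = "noncollinear"
LEFT_HIGHER = "left_higher"
RIGHT_HIGHER = "right_higher"

TASKS = (COLLINEARITY, HEIGHT)
COLLINEARITY_LABELS = (COLLINEAR, NONCOLLINEAR)
HEIGHT_LABELS = (LEFT_HIGHER, RIGHT_HIGHER)

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial_index",
    "task",
    "eccentricity",
    "y_left",
    "y_right",
    "category",
    "response",
]


@dataclass(frozen=True)
class TaskDesign:
    """Stimulus statistics and session structure of the experiment.

    Defaults reproduce the study design: four eccentricity levels
    (0, 4.8, 9.6, 16.8 dva), segment positions jittered about the level with
    SD 0.48 dva, a 50/50 collinear / non-collinear mix, 200-trial
    collinearity blocks and 60-trial height blocks (3 + 2 per session,
    4 sessions).
    """

    eccentricity_levels: tuple[float, ...] = (0.0, 4.8, 9.6, 16.8)
    offset_sd: float = 0.48
    prior_collinear: float = 0.5
    collinearity_block_size: int = 200
    height_block_size: int = 60
    collinearity_blocks_per_session: int = 3
    height_blocks_per_session: int = 2
    sessions: int = 4

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.eccentricity_levels)
        object.__setattr__(self, "eccentricity_levels", levels)
        if len(levels) == 0:
            raise ValueError("eccentricity_levels must be non-empty")
        if any(b < a or a < 0 for a, b in zip(levels, levels[1:])) or levels[0] < 0:
            raise ValueError("eccentricity_levels must be nonnegative and strictly increasing")
        if len(set(levels)) != len(levels):
            raise ValueError("eccentricity_levels must be strictly increasing")
        if not (self.offset_sd >= 0):
            raise ValueError("offset_sd must be nonnegative")
        if not (0.0 < self.prior_collinear < 1.0):
            raise ValueError("prior_collinear must lie in (0, 1)")
        for name in (
            "collinearity_block_size",
            "height_block_size",
            "collinearity_blocks_per_session",
            "height_blocks_per_session",
            "sessions",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ValueError(f"{name} must be a positive integer, got {value!r}")


@dataclass
class TrialRecord:
    """One stimulus presentation, optionally with a simulated response."""

    subject_id: str
    session: int
    block: int
    trial_index: int
    task: str
    eccentricity: float
    y_left: float
    y_right: float
    category: str
    response: str | None = None


def make_default_design() -> TaskDesign:
    """Return the experiment's default :class:`TaskDesign`."""
    return TaskDesign()


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    if isinstance(rng_seed, np.random.SeedSequence):
        return np.random.default_rng(rng_seed)
    if isinstance(rng_seed, (int, np.integer)):
        if rng_seed < 0:
            raise ValueError("rng_seed must be nonnegative")
        return np.random.default_rng(int(rng_seed))
    raise TypeError(f"rng_seed must be an int, SeedSequence or Generator, got {type(rng_seed)}")


def _check_n_trials(n_trials) -> int:
    if not isinstance(n_trials, (int, np.integer)) or isinstance(n_trials, bool):
        raise TypeError("n_trials must be an integer")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return int(n_trials)


def generate_collinearity_trials(
    design: TaskDesign,
    n_trials: int,
    rng_seed,
    *,
    subject_id: str = "sim",
    session: int = 1,
    block: int = 1,
) -> list[TrialRecord]:
    """Generate collinearity-task trials with an exactly balanced category mix.

    Exactly ``round(prior_collinear * n_trials)`` trials are collinear; the
    category sequence is shuffled.  Eccentricity levels are assigned
    uniformly and independently per trial.
    """
    n = _check_n_trials(n_trials)
    rng = _as_rng(rng_seed)
    n_coll = int(np.floor(design.prior_collinear * n + 0.5))
    collinear = np.zeros(n, dtype=bool)
    collinear[:n_coll] = True
    collinear = rng.permutation(collinear)
    levels = np.asarray(design.eccentricity_levels)
    ecc = levels[rng.integers(0, len(levels), size=n)]
    y_left = rng.normal(ecc, design.offset_sd)
    y_right_ind = rng.normal(ecc, design.offset_sd)
    y_right = np.where(collinear, y_left, y_right_ind)
    return [
        TrialRecord(
            subject_id=subject_id,
            session=session,
            block=block,
            trial_index=i + 1,
            task=COLLINEARITY,
            eccentricity=float(ecc[i]),
            y_left=float(y_left[i]),
            y_right=float(y_right[i]),
            category=COLLINEAR if collinear[i] else NONCOLLINEAR,
        )
        for i in range(n)
    ]


def generate_height_trials(
    design: TaskDesign,
    n_trials: int,
    rng_seed,
    *,
    subject_id: str = "sim",
    session: int = 1,
    block: int = 1,
) -> list[TrialRecord]:
    """Generate height-task trials (both positions drawn independently).

    The category is ``right_higher`` iff ``y_right > y_left``.  A degenerate
    design with ``offset_sd == 0`` is rejected because ties would make the
    category undefined.
    """
    n = _check_n_trials(n_trials)
    if design.offset_sd == 0:
        raise ValueError("height trials require offset_sd > 0 (ties are undefined)")
    rng = _as_rng(rng_seed)
    levels = np.asarray(design.eccentricity_levels)
    ecc = levels[rng.integers(0, len(levels), size=n)]
    y_left = rng.normal(ecc, design.offset_sd)
    y_right = rng.normal(ecc, design.offset_sd)
    return [
        TrialRecord(
            subject_id=subject_id,
            session=session,
            block=block,
            trial_index=i + 1,
            task=HEIGHT,
            eccentricity=float(ecc[i]),
            y_left=float(y_left[i]),
            y_right=float(y_right[i]),
            category=RIGHT_HIGHER if y_right[i] > y_left[i] else LEFT_HIGHER,
        )
        for i in range(n)
    ]


def generate_session(
    design: TaskDesign,
    rng_seed,
    *,
    subject_id: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Generate one full session: height, collinearity x 3, height blocks.

    Block numbering follows presentation order (1..5 for the default
    design).  Each collinearity block is balanced on its own.
    """
    rng = _as_rng(rng_seed)
    trials: list[TrialRecord] = []
    n_height = design.height_blocks_per_session
    n_coll = design.collinearity_blocks_per_session
    # one height block first, the remaining height blocks at the end
    order = [HEIGHT] * min(1, n_height) + [COLLINEARITY] * n_coll + [HEIGHT] * max(0, n_height - 1)
    for block, task in enumerate(order, start=1):
        if task == HEIGHT:
            trials.extend(
                generate_height_trials(
                    design, design.height_block_size, rng,
                    subject_id=subject_id, session=session, block=block,
                )
            )
        else:
            trials.extend(
                generate_collinearity_trials(
                    design, design.collinearity_block_size, rng,
                    subject_id=subject_id, session=session, block=block,
                )
            )
    return trials


def generate_subject(design: TaskDesign, rng_seed, *, subject_id: str = "sim") -> list[TrialRecord]:
    """Generate all sessions for one subject."""
    rng = _as_rng(rng_seed)
    trials: list[TrialRecord] = []
    for session in range(1, design.sessions + 1):
        trials.extend(generate_session(design, rng, subject_id=subject_id, session=session))
    return trials


def simulate_responses(params, trials: Sequence[TrialRecord], rng_seed) -> list[TrialRecord]:
    """Simulate responses of an observer model on ``trials``.

    Per trial, noisy measurements ``x_L ~ N(y_left, sigma_x(y)^2)`` and
    ``x_R ~ N(y_right, sigma_x(y)^2)`` are drawn; with probability ``lapse``
    the response is uniform over the two labels, otherwise the model's
    decision rule is applied.  Returns new records; the inputs are not
    modified.
    """
    from . import models  # local import to avoid a cycle

    trials = list(trials)
    if not trials:
        return []
    rng = _as_rng(rng_seed)
    tasks = {t.task for t in trials}
    if len(tasks) > 1:
        raise ValueError("simulate_responses requires trials from a single task")
    task = tasks.pop()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")

    ecc = np.array([t.eccentricity for t in trials])
    y_left = np.array([t.y_left for t in trials])
    y_right = np.array([t.y_right for t in trials])
    sigma = params.noise.sigma_at(ecc)
    n = len(trials)

    x_left = rng.normal(y_left, sigma)
    x_right = rng.normal(y_right, sigma)

    if task == COLLINEARITY:
        says_first = models.decide_collinear(params, trials, x_left, x_right, rng=rng)
        labels = COLLINEARITY_LABELS  # (collinear, noncollinear)
    else:
        if params.model_id not in (models.HEIGHT_JUDGMENT,):
            raise ValueError(
                f"model {params.model_id!r} does not apply to the height task"
            )
        says_first = x_left > x_right  # "left higher" whenever x_L > x_R
        labels = HEIGHT_LABELS  # (left_higher, right_higher)

    lapse_mask = rng.random(n) < params.lapse
    lapse_first = rng.integers(0, 2, size=n) == 0
    says_first = np.where(lapse_mask, lapse_first, says_first)

    out = []
    for i, t in enumerate(trials):
        out.append(replace(t, response=labels[0] if says_first[i] else labels[1]))
    return out


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the canonical trial-table DataFrame."""
    rows = [
        {
            "subject_id": t.subject_id,
            "session": t.session,
            "block": t.block,
            "trial_index": t.trial_index,
            "task": t.task,
            "eccentricity": t.eccentricity,
            "y_left": t.y_left,
            "y_right": t.y_right,
            "category": t.category,
            "response": t.response,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Convert a trial-table DataFrame back to records."""
    out = []
    for row in frame.itertuples(index=False):
        response = row.response
        if response is None or (isinstance(response, float) and np.isnan(response)) or response == "":
            response = None
        out.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                session=int(row.session),
                block=int(row.block),
                trial_index=int(row.trial_index),
                task=str(row.task),
                eccentricity=float(row.eccentricity),
                y_left=float(row.y_left),
                y_right=float(row.y_right),
                category=str(row.category),
                response=response,
            )
        )
    return out
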