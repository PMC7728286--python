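"""Plain-text file formats: trial tables, posterior samples, comparison
tables.  Every file starts with '#'-prefixed provenance lines (key = value)
followed by a CSV header row."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    COLLINEARITY_LABELS,
    HEIGHT_LABELS,
    TASKS,
    COLLINEARITY,
    TRIAL_COLUMNS,
    trials_to_frame,
)

__all__ = [
    "config_hash",
    "provenance_header",
    "write_trials",
    "read_trials",
    "write_table",
    "read_table",
    "write_samples",
    "read_samples",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_header(metadata: dict) -> str:
    lines = [f"# {key} = {value}" for key, value in metadata.items()]
    return "\n".join(lines) + ("\n" if lines else "")


def _read_header(path) -> tuple[dict, int]:
    metadata: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
    return metadata, n_header


def write_trials(path, trials, metadata: dict | None = None) -> None:
    """Write a trial table as delimited text with a provenance header."""
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    frame = frame[TRIAL_COLUMNS].copy()
    frame["response"] = frame["response"].fillna("")
    path = Path(path)
    with open(path, "w") as fh:
        if metadata:
            fh.write(provenance_header(metadata))
        frame.to_csv(fh, index=False)


def read_trials(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a trial table; returns (frame, metadata)."""
    metadata, n_header = _read_header(path)
    frame = pd.read_csv(
        path, skiprows=n_header, keep_default_na=False, na_values=[], float_precision="round_trip"
    )
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s) {missing}")
    frame = frame[TRIAL_COLUMNS]
    for row_number, task in enumerate(frame["task"], start=1):
        if task not in TASKS:
            raise ValueError(f"trial table {path} row {row_number}: unknown task {task!r}")
    for row_number, (task, category, response) in enumerate(
        zip(frame["task"], frame["category"], frame["response"]), start=1
    ):
        labels = COLLINEARITY_LABELS if task == COLLINEARITY else HEIGHT_LABELS
        if category not in labels:
            raise ValueError(
                f"trial table {path} row {row_number}: unknown category {category!r}"
            )
        if response not in labels and response != "":
            raise ValueError(
                f"trial table {path} row {row_number}: unknown response {response!r}"
            )
    frame["response"] = frame["response"].where(frame["response"] != "", np.nan)
    for column in ("session", "block", "trial_index"):
        frame[column] = frame[column].astype(int)
    for column in ("eccentricity", "y_left", "y_right"):
        frame[column] = frame[column].astype(float)
    return frame, metadata


def write_table(path, frame: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a generic result table with a provenance header."""
    with open(path, "w") as fh:
        if metadata:
            fh.write(provenance_header(metadata))
        frame.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    metadata, n_header = _read_header(path)
    return pd.read_csv(path, skiprows=n_header, float_precision="round_trip"), metadata


def write_samples(path, samples, metadata: dict | None = None) -> None:
    """Persist posterior draws plus the pointwise log-likelihood matrix.

    Draws go to ``path``; the (draws x trials) pointwise matrix goes to
    ``path`` with an extra ``.pointwise`` suffix before the extension.
    """
    path = Path(path)
    meta = {
        "model_id": samples.model_id,
        "seed": samples.seed,
        "n_chains": samples.n_chains,
        "parameters": " ".join(samples.names),
        "rhat": " ".join(f"{r:.6f}" for r in samples.rhat),
        "bounds": " ".join(
            f"{n}:[{lo:g},{hi:g}]" for n, lo, hi in zip(samples.names, samples.prior.lower, samples.prior.upper)
        ),
    }
    if metadata:
        meta.update(metadata)
    n_chains, n_samples, k = samples.draws.shape
    frame = pd.DataFrame(samples.draws.reshape(-1, k), columns=list(samples.names))
    frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_samples))
    frame["log_posterior"] = samples.log_posterior.reshape(-1)
    with open(path, "w") as fh:
        fh.write(provenance_header(meta))
        frame.to_csv(fh, index=False)
    pw_path = path.with_suffix(".pointwise" + path.suffix)
    with open(pw_path, "w") as fh:
        fh.write(provenance_header({"model_id": samples.model_id, "shape": "draws x trials"}))
        pd.DataFrame(samples.pointwise_loglik).to_csv(fh, index=False)


def read_samples(path) -> dict:
    """Read stored draws and pointwise log-likelihoods.

    Returns a dict with 'draws' (chains, samples, params), 'names',
    'log_posterior', 'pointwise_loglik', and 'metadata'.
    """
    path = Path(path)
    metadata, n_header = _read_header(path)
    frame = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    names = metadata["parameters"].split()
    chains = frame["chain"].to_numpy()
    n_chains = int(chains.max()) + 1
    k = len(names)
    draws = frame[names].to_numpy().reshape(n_chains, -1, k)
    log_posterior = frame["log_posterior"].to_numpy().reshape(n_chains, -1)
    pw_path = path.with_suffix(".pointwise" + path.suffix)
    pointwise = None
    if pw_path.exists():
        _, n_pw_header = _read_header(pw_path)
        pointwise = pd.read_csv(pw_path, skiprows=n_pw_header, float_precision="round_trip").to_numpy()
    return {
        "draws": draws,
        "names": names,
        "log_posterior": log_posterior,
        "pointwise_loglik": pointwise,
        "metadata": metadata,
    }
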