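"""Delimited-text and JSON readers/writers shared by the CLI.

Everything is plain text: CSV matrices with a header row of feature
identifiers, JSON sidecars and results with a schema-version stamp.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SIDECAR_NAME = "config.json"
ATTRIBUTES_NAME = "attributes.csv"
TRUTH_NAME = "truth.json"
SIDECAR_SCHEMA = "experiment-sidecar/1"


def feature_columns(n: int) -> list[str]:
    return [f"f{i:04d}" for i in range(n)]


def write_matrix(path, X: np.ndarray) -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pd.DataFrame(X, columns=feature_columns(X.shape[1])).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def write_experiment(outdir, experiment) -> None:
    """Persist a synthetic experiment: trials, sidecar, attributes, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = experiment.config
    stimuli = [f"stim{i + 1}" for i in range(cfg.n_stimuli)]
    for name, trials in zip(stimuli, experiment.trials):
        write_matrix(outdir / f"trials_{name}.csv", trials)
    sidecar = {
        "schema_version": SIDECAR_SCHEMA,
        "domain": "feature",
        "fs": cfg.fs,
        "pre_stimulus_s": 0.15,
        "n_samples": cfg.n_samples,
        "n_features": cfg.n_features,
        "stimuli": stimuli,
        "seed": cfg.seed,
    }
    with open(outdir / SIDECAR_NAME, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    pd.DataFrame(
        {"stimulus": stimuli, "phi_ms": experiment.phi, "psi": experiment.psi}
    ).to_csv(outdir / ATTRIBUTES_NAME, index=False, float_format="%.17g")
    with open(outdir / TRUTH_NAME, "w") as fh:
        json.dump(experiment.truth_dict(), fh)


def read_experiment(datadir) -> dict:
    """Load a persisted experiment directory.

    Returns a dict with keys sidecar, stimuli, trials (list of matrices),
    phi, psi.
    """
    datadir = Path(datadir)
    with open(datadir / SIDECAR_NAME) as fh:
        sidecar = json.load(fh)
    if sidecar.get("schema_version") != SIDECAR_SCHEMA:
        raise ValueError(
            f"unsupported sidecar schema: {sidecar.get('schema_version')!r}"
        )
    attrs = pd.read_csv(datadir / ATTRIBUTES_NAME)
    stimuli = list(attrs["stimulus"])
    trials = [read_matrix(datadir / f"trials_{s}.csv") for s in stimuli]
    return {
        "sidecar": sidecar,
        "stimuli": stimuli,
        "trials": trials,
        "phi": attrs["phi_ms"].to_numpy(dtype=float),
        "psi": attrs["psi"].to_numpy(dtype=float),
    }


def write_scalogram_csv(path, cells: list[dict]) -> None:
    pd.DataFrame(
        cells,
        columns=["band", "level", "t_start", "t_end", "low_hz", "high_hz", "value"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
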