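"""Delimited-text serialisation for tables, posteriors and experiments.

Everything is plain headered CSV so artefacts can be inspected, versioned
and reloaded without the package.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .population import (
    NOISE_PARAMS,
    REGRESSION_PARAMS,
    NoisePosterior,
    RegressionPosterior,
    compute_diagnostics,
    validate_raw_estimates,
)

__all__ = [
    "read_raw_estimates",
    "write_raw_estimates",
    "write_posterior",
    "read_regression_posterior",
    "read_noise_posterior",
    "write_experiments",
    "write_power_table",
]


def read_raw_estimates(path, require_rmse: bool = True) -> pd.DataFrame:
    """Read a raw-estimates table (columns id, a, b, rmse[, sigma])."""
    raw = pd.read_csv(path)
    return validate_raw_estimates(raw, require_rmse=require_rmse)


def write_raw_estimates(raw: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    raw.to_csv(path, index=False)


def write_posterior(posterior, path) -> None:
    """Write posterior draws (one row per draw, chain id column) as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    posterior.draws.to_csv(path, index=False)


def _read_draws(path, params: list[str]) -> pd.DataFrame:
    draws = pd.read_csv(path)
    missing = [c for c in ["chain", "draw", *params] if c not in draws.columns]
    if missing:
        raise ValueError(f"draws file {path} missing column(s): {missing}")
    return draws


def _diag_from_frame(draws: pd.DataFrame, params: list[str]):
    by_chain = {
        p: draws.pivot(index="chain", columns="draw", values=p).to_numpy()
        for p in params
    }
    return compute_diagnostics(by_chain)


def read_regression_posterior(path) -> RegressionPosterior:
    """Reload a serialized regression posterior; diagnostics are recomputed."""
    draws = _read_draws(path, REGRESSION_PARAMS)
    diag = _diag_from_frame(draws, REGRESSION_PARAMS)
    return RegressionPosterior(draws=draws, diagnostics=diag,
                               converged=diag.converged)


def read_noise_posterior(path) -> NoisePosterior:
    draws = _read_draws(path, NOISE_PARAMS)
    diag = _diag_from_frame(draws, NOISE_PARAMS)
    return NoisePosterior(draws=draws, diagnostics=diag, converged=diag.converged)


def write_experiments(experiments, path) -> None:
    """Write virtual experiments in tidy long format."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frames = [exp.to_frame(experiment_id=i) for i, exp in enumerate(experiments)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_power_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
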