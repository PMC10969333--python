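"""Calibration of per-individual measurement-noise levels.

Each individual's raw dose-response fit comes with an RMSE on the
suppression scale.  The measurement model, however, is additive noise on the
*logit* scale with standard deviation ``sigma_i``; there is no closed form
linking the two.  ``calibrate_sigma`` recovers ``sigma_i`` by simulation:
for a candidate sigma, noisy measurements of the individual's true curve are
simulated on the experimental illuminance grid, the RMSE against the true
curve is averaged over replicates, and a one-dimensional root-finder matches
that average to the observed RMSE.

A single block of standard-normal deviates is drawn once per calibration and
reused at every sigma evaluation (common random numbers).  This makes the
objective a deterministic, smooth, increasing function of sigma, so the
root-find is well posed; averaging over replicates serves the same
variance-reduction purpose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import DoseResponseParams, inv_logit, logit, suppression

__all__ = [
    "DEFAULT_MEASUREMENT_GRID",
    "validate_grid",
    "rmse",
    "simulated_mean_rmse",
    "calibrate_sigma",
    "calibrate_all",
]

# Experimental illuminance levels (photopic lux) of the source protocol.
DEFAULT_MEASUREMENT_GRID = (10.0, 30.0, 50.0, 100.0, 200.0, 400.0, 2000.0)

SIGMA_BRACKET = (1e-3, 10.0)
MAX_BRACKET_DOUBLINGS = 10


def validate_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("measurement grid must be a non-empty 1-D sequence")
    if np.any(grid < 1.0):
        raise ValueError("all grid illuminances must be >= 1 lux")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid illuminances must be strictly increasing")
    return grid


def rmse(measured, predicted) -> float:
    """Root-mean-square error between two suppression vectors (raw scale)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 1:
        raise ValueError(
            f"measured and predicted must have equal nonzero length; "
            f"got {measured.shape} vs {predicted.shape}"
        )
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def simulated_mean_rmse(
    params: DoseResponseParams,
    sigma: float,
    grid=DEFAULT_MEASUREMENT_GRID,
    noise_draws: np.ndarray | None = None,
    replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Average RMSE of simulated noisy experiments at noise level ``sigma``.

    One replicate measures the true curve once per grid illuminance with
    logit-normal noise; the RMSE against the true curve is averaged over
    ``replicates``.  If ``noise_draws`` (a replicates x grid block of
    standard-normal deviates) is supplied the result is deterministic.
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0; got {sigma}")
    grid = validate_grid(grid)
    if noise_draws is None:
        rng = rng if rng is not None else np.random.default_rng()
        noise_draws = rng.standard_normal((replicates, grid.size))
    else:
        noise_draws = np.asarray(noise_draws, dtype=float)
        if noise_draws.ndim != 2 or noise_draws.shape[1] != grid.size:
            raise ValueError(
                f"noise_draws must have shape (replicates, {grid.size}); "
                f"got {noise_draws.shape}"
            )
    true = suppression(grid, params)
    measured = inv_logit(logit(true)[None, :] + sigma * noise_draws)
    per_rep = np.sqrt(np.mean((measured - true[None, :]) ** 2, axis=1))
    return float(per_rep.mean())


def calibrate_sigma(
    params: DoseResponseParams,
    target_rmse: float,
    grid=DEFAULT_MEASUREMENT_GRID,
    replicates: int = 100,
    seed: int = 0,
    tol: float = 1e-4,
) -> float:
    """Find sigma whose average simulated RMSE matches ``target_rmse``.

    Brent root-finding on sigma in [1e-3, 10] (with bracket doubling if the
    target exceeds the achievable RMSE at the initial upper end), using one
    fixed common-random-number block so the objective is deterministic.
    """
    if not (target_rmse > 0):
        raise ValueError(f"target_rmse must be > 0; got {target_rmse}")
    grid = validate_grid(grid)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((replicates, grid.size))

    def objective(sigma: float) -> float:
        return simulated_mean_rmse(params, sigma, grid, noise_draws=noise) - target_rmse

    lo, hi = SIGMA_BRACKET
    f_lo = objective(lo)
    if f_lo > 0:
        raise ValueError(
            f"target RMSE {target_rmse:.4g} is below the achievable minimum "
            f"{f_lo + target_rmse:.4g} at sigma={lo}"
        )
    f_hi = objective(hi)
    doublings = 0
    while f_hi < 0 and doublings < MAX_BRACKET_DOUBLINGS:
        hi *= 2.0
        f_hi = objective(hi)
        doublings += 1
    if f_hi < 0:
        raise ValueError(
            f"target RMSE {target_rmse:.4g} exceeds the achievable maximum "
            f"{f_hi + target_rmse:.4g} at sigma={hi:.3g}"
        )
    return float(brentq(objective, lo, hi, xtol=tol))


def calibrate_all(
    raw: pd.DataFrame,
    grid=DEFAULT_MEASUREMENT_GRID,
    replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibrate sigma for every row of a raw-estimates table.

    Returns a copy of the table with an added ``sigma`` column.  Each
    individual gets an independent deviate block derived from ``seed``.
    """
    out = raw.copy()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(raw))
    sigmas = np.empty(len(raw))
    for i, (_, row) in enumerate(raw.iterrows()):
        params = DoseResponseParams(a=float(row["a"]), b=float(row["b"]))
        sigmas[i] = calibrate_sigma(
            params, float(row["rmse"]), grid=grid,
            replicates=replicates, seed=int(child_seeds[i] % (2**31)),
        )
    out["sigma"] = sigmas
    return out
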