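"""Virtual individuals and virtual experiments.

A fitted :class:`PopulationModel` can be sampled to produce *virtual
individuals* — dose-response curves plus a personal measurement-noise level —
and assembled into whole virtual experiments (n individuals measured once at
each illuminance of a grid, with logit-normal measurement noise).

Two sampling processes are provided:

* the unrestricted process: draw ``a`` from the fitted KDE by inverse
  transform, draw one posterior parameter set ``(alpha, beta, sigma0,
  sigma1)`` uniformly from the regression draws (so fitting uncertainty is
  part of between-individual variation), draw ``log b`` from the conditional
  regression, and reject any curve whose ED25 falls below half the smallest
  raw ED25 or whose ED75 exceeds 1.5 times the largest raw ED75 — keeping
  virtual curves no more extreme than the raw estimates support;

* the reduced-heterogeneity process, governed by ``eta`` in [0, 1]: the
  posterior draws of alpha and beta are first shrunk towards their posterior
  means by ``1 - eta``, the KDE draw of ``a`` is shrunk towards the empirical
  median ``a50``, and the conditional SD is scaled by ``eta`` (the sigma0,
  sigma1 draws themselves are sampled unshrunk, as the procedure is
  specified).  ``eta = 1`` reproduces the unrestricted process; ``eta = 0``
  collapses the population onto a single deterministic median curve.

Each individual's measurement-noise level ``sigma`` is drawn from a gamma
distribution whose (shape, rate) are a uniformly sampled draw of the fitted
noise-population posterior, and is held constant across that individual's
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import validate_grid
from .dose_response import (
    DoseResponseParams,
    _effective_dose_arrays,
    _suppression_arrays,
    inv_logit,
    logit,
    suppression,
)
from .population import ADistribution, NoisePosterior, RegressionPosterior

__all__ = [
    "PopulationModel",
    "VirtualIndividual",
    "VirtualExperiment",
    "rejection_bounds",
    "sample_individual",
    "sample_individual_reduced",
    "sample_individuals",
    "measure",
    "virtual_experiment",
    "experiment_checks",
]

MAX_REJECTION_ATTEMPTS = 10_000  # per requested individual

ONE_THIRD = 1.0 / 3.0


def rejection_bounds(raw: pd.DataFrame) -> tuple[float, float]:
    """ED25 floor and ED75 ceiling from a raw-estimates table.

    Floor = half the minimum raw ED25; ceiling = 1.5 times the maximum raw
    ED75.  Virtual curves outside these bounds are rejected.
    """
    a = np.asarray(raw["a"], dtype=float)
    b = np.asarray(raw["b"], dtype=float)
    ed25 = _effective_dose_arrays(0.25, a, b)
    ed75 = _effective_dose_arrays(0.75, a, b)
    return 0.5 * float(ed25.min()), 1.5 * float(ed75.max())


@dataclass(frozen=True)
class PopulationModel:
    """Sampleable joint population model of dose-response curves and noise."""

    a_dist: ADistribution
    regression: RegressionPosterior
    noise: NoisePosterior
    ed25_floor: float
    ed75_ceiling: float

    def __post_init__(self) -> None:
        if not (0 < self.ed25_floor < self.ed75_ceiling):
            raise ValueError(
                f"need 0 < ed25_floor < ed75_ceiling; got "
                f"({self.ed25_floor}, {self.ed75_ceiling})"
            )


@dataclass(frozen=True)
class VirtualIndividual:
    """One virtual participant: a curve plus a measurement-noise level."""

    params: DoseResponseParams
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma >= 0):
            raise ValueError(f"sigma must be >= 0; got {self.sigma}")


def _candidate_batch(
    model: PopulationModel, m: int, eta: float | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw m candidate (a, b) pairs, before the rejection step.

    ``eta=None`` is the unrestricted process (one joint posterior draw per
    candidate); a float eta runs the reduced-heterogeneity process.
    """
    alpha, beta, s0, s1 = model.regression.arrays()
    n_draws = alpha.size
    if eta is None:
        idx = rng.integers(n_draws, size=m)
        al, be, sg0, sg1 = alpha[idx], beta[idx], s0[idx], s1[idx]
        a = model.a_dist.quantile(rng.uniform(size=m))
        sd = sg0 + sg1 * a
    else:
        # shrink the (alpha, beta) draw set towards the posterior means,
        # then sample from the shrunk set; (sigma0, sigma1) sampled unshrunk
        # and independently, and the conditional SD is scaled by eta.
        abar, bbar = alpha.mean(), beta.mean()
        idx_ab = rng.integers(n_draws, size=m)
        al = abar + eta * (alpha[idx_ab] - abar)
        be = bbar + eta * (beta[idx_ab] - bbar)
        idx_s = rng.integers(n_draws, size=m)
        sg0, sg1 = s0[idx_s], s1[idx_s]
        a_prime = model.a_dist.quantile(rng.uniform(size=m))
        a = model.a_dist.a50 + eta * (a_prime - model.a_dist.a50)
        sd = eta * (sg0 + sg1 * a)
    logb = al + be * a + sd * rng.standard_normal(m)
    return a, np.exp(logb)


def _accept_mask(model: PopulationModel, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # overflowing ED75 is simply rejected
        ed25 = 10.0 ** (a * ONE_THIRD ** (1.0 / b))
        ed75 = 10.0 ** (a * 3.0 ** (1.0 / b))
    return (a > 0) & (ed25 >= model.ed25_floor) & (ed75 <= model.ed75_ceiling)


def _draw_sigmas(model: PopulationModel, m: int, rng: np.random.Generator) -> np.ndarray:
    c, d = model.noise.arrays()
    k = rng.integers(c.size, size=m)
    return rng.gamma(shape=c[k], scale=1.0 / d[k])


def sample_individuals(
    model: PopulationModel,
    n: int,
    eta: float | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = MAX_REJECTION_ATTEMPTS,
) -> pd.DataFrame:
    """Sample ``n`` virtual individuals; returns columns ``a, b, sigma``.

    ``eta=None`` (default) runs the unrestricted generation process; a
    numeric ``eta`` in [0, 1] runs the reduced-heterogeneity one (which at
    ``eta=1`` reproduces the unrestricted process distributionally).
    Candidates failing the ED25/ED75 rejection bounds are redrawn, with a
    cap of ``max_attempts`` candidate draws per requested individual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if eta is not None and not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0, 1]; got {eta}")
    rng = rng if rng is not None else np.random.default_rng()
    eta_arg = eta

    a_out = np.empty(n)
    b_out = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        m = max(n - got, 64)
        if attempts + m > max_attempts * n:
            m = max_attempts * n - attempts
            if m <= 0:
                raise RuntimeError(
                    f"rejection sampling exceeded {max_attempts} attempts per "
                    "individual; the fitted model appears inconsistent with its "
                    "own ED25/ED75 bounds"
                )
        a, b = _candidate_batch(model, m, eta_arg, rng)
        attempts += m
        ok = _accept_mask(model, a, b)
        take = min(int(ok.sum()), n - got)
        if take:
            sel = np.flatnonzero(ok)[:take]
            a_out[got : got + take] = a[sel]
            b_out[got : got + take] = b[sel]
            got += take
    sigma = _draw_sigmas(model, n, rng)
    return pd.DataFrame({"a": a_out, "b": b_out, "sigma": sigma})


def sample_individual(
    model: PopulationModel,
    rng: np.random.Generator | None = None,
) -> VirtualIndividual:
    """Sample one virtual individual by the unrestricted process."""
    df = sample_individuals(model, 1, eta=None, rng=rng)
    return VirtualIndividual(
        params=DoseResponseParams(a=float(df["a"][0]), b=float(df["b"][0])),
        sigma=float(df["sigma"][0]),
    )


def sample_individual_reduced(
    model: PopulationModel,
    eta: float,
    rng: np.random.Generator | None = None,
) -> VirtualIndividual:
    """Sample one virtual individual at heterogeneity level ``eta``."""
    df = sample_individuals(model, 1, eta=eta, rng=rng)
    return VirtualIndividual(
        params=DoseResponseParams(a=float(df["a"][0]), b=float(df["b"][0])),
        sigma=float(df["sigma"][0]),
    )


def measure(
    individual: VirtualIndividual,
    x,
    rng: np.random.Generator | None = None,
):
    """One noisy suppression measurement at illuminance ``x`` (lux).

    Noise is additive on the logit scale (SD = the individual's sigma), so
    measurements always lie strictly inside (0, 1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    s = suppression(x, individual.params)
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any((s_arr <= 0.0) | (s_arr >= 1.0)):
        raise ValueError(
            "true suppression is 0 or 1 at this illuminance; keep the "
            "measurement grid strictly above 1 lux"
        )
    z = logit(s_arr) + individual.sigma * rng.standard_normal(s_arr.shape)
    out = inv_logit(z)
    return float(out[0]) if np.isscalar(s) or np.ndim(s) == 0 else out


@dataclass(frozen=True)
class VirtualExperiment:
    """n virtual individuals measured once at each grid illuminance."""

    individuals: pd.DataFrame  # columns: a, b, sigma
    grid: np.ndarray
    true_suppression: np.ndarray  # n x len(grid)
    measured: np.ndarray  # n x len(grid), strictly inside (0, 1)
    eta: float | None  # None = unrestricted process

    @property
    def n(self) -> int:
        return len(self.individuals)

    def to_frame(self, experiment_id: int = 0) -> pd.DataFrame:
        """Tidy long-format view, one row per (individual, illuminance)."""
        n, g = self.true_suppression.shape
        ind = self.individuals
        return pd.DataFrame(
            {
                "experiment_id": experiment_id,
                "individual_id": np.repeat(np.arange(1, n + 1), g),
                "a": np.repeat(ind["a"].to_numpy(), g),
                "b": np.repeat(ind["b"].to_numpy(), g),
                "sigma": np.repeat(ind["sigma"].to_numpy(), g),
                "lux": np.tile(self.grid, n),
                "true_suppression": self.true_suppression.ravel(),
                "measured_suppression": self.measured.ravel(),
            }
        )


def virtual_experiment(
    model: PopulationModel,
    n: int,
    grid,
    eta: float | None = None,
    rng: np.random.Generator | None = None,
) -> VirtualExperiment:
    """Simulate one whole experiment: n individuals x illuminance grid."""
    grid = validate_grid(grid)
    rng = rng if rng is not None else np.random.default_rng()
    inds = sample_individuals(model, n, eta=eta, rng=rng)
    a = inds["a"].to_numpy()[:, None]
    b = inds["b"].to_numpy()[:, None]
    true = _suppression_arrays(grid[None, :], a, b)
    if np.any((true <= 0.0) | (true >= 1.0)):
        raise ValueError("true suppression hit 0 or 1; grid must stay above 1 lux")
    z = logit(true) + inds["sigma"].to_numpy()[:, None] * rng.standard_normal(true.shape)
    measured = inv_logit(z)
    return VirtualExperiment(
        individuals=inds, grid=grid, true_suppression=true,
        measured=measured, eta=eta,
    )


def experiment_checks(experiments: list[VirtualExperiment]) -> pd.DataFrame:
    """Extrema and saturation fractions per illuminance and experiment.

    For each experiment and grid illuminance: the minimum and maximum
    measured suppression, and the lower/upper saturation fractions (shares
    of measurements below 5% or above 95% suppression).  Used to compare
    replicate virtual experiments against real data.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    grid0 = experiments[0].grid
    rows = []
    for i, exp in enumerate(experiments):
        if exp.grid.shape != grid0.shape or not np.allclose(exp.grid, grid0):
            raise ValueError("all experiments must share the same measurement grid")
        meas = exp.measured
        rows.append(
            pd.DataFrame(
                {
                    "experiment_id": i,
                    "lux": exp.grid,
                    "min": meas.min(axis=0),
                    "max": meas.max(axis=0),
                    "frac_below_5pct": (meas < 0.05).mean(axis=0),
                    "frac_above_95pct": (meas > 0.95).mean(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
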