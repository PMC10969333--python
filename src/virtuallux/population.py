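"""Population model fitting: KDE over a, Bayesian regression of log b on a,
and a gamma population model over measurement-noise levels.

The sampleable population model has three fitted parts:

1. the marginal distribution of ``a = log10(ED50)`` across individuals,
   approximated by a Gaussian kernel density estimate of the raw estimates
   and sampled by inverse-transform sampling;
2. the conditional distribution of the shape parameter,
   ``log b_i ~ normal(alpha + beta * a_i, sigma0 + sigma1 * a_i)``,
   a heteroscedastic regression (the residual SD grows linearly with a)
   fitted by MCMC with priors alpha, beta ~ normal(0, 1) and
   sigma0, sigma1 ~ half-Cauchy(0, 1);
3. a gamma population model ``sigma_i ~ gamma(c, d)`` (shape-rate) over the
   calibrated per-individual measurement-noise levels, with half-Cauchy(0, 1)
   priors on c and d.

Sampling uses the emcee affine-invariant ensemble sampler.  The contract is
the convergence gate (rank-normalized split R-hat < 1.01, bulk and tail ESS
above 400), not the sampler: each "chain" of the 4-chain protocol is an
independent ensemble whose post-warm-up, thinned draws are subsampled to the
protocol's retained-draw count with a walker-rotating stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .diagnostics import Diagnostics, compute_diagnostics

__all__ = [
    "validate_raw_estimates",
    "ADistribution",
    "fit_a_distribution",
    "MCMCConfig",
    "RegressionPosterior",
    "fit_logb_regression",
    "NoisePosterior",
    "fit_sigma_population",
    "ppc_regression",
    "ConvergenceWarning",
]

MIN_N = 5  # fewer rows cannot support the 4-parameter regression


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when a fit fails the convergence gate."""


def validate_raw_estimates(raw: pd.DataFrame, require_rmse: bool = True) -> pd.DataFrame:
    """Validate a raw-estimates table (columns a, b and optionally rmse)."""
    needed = ["a", "b"] + (["rmse"] if require_rmse else [])
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"raw estimates missing column(s): {missing}")
    if len(raw) < MIN_N:
        raise ValueError(f"need at least {MIN_N} individuals; got {len(raw)}")
    for col in needed:
        vals = np.asarray(raw[col], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"column {col!r} contains non-finite values")
        if not np.all(vals > 0):
            raise ValueError(f"column {col!r} must be strictly positive")
    return raw


# --------------------------------------------------------------------------
# Marginal distribution of a (KDE + inverse transform)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ADistribution:
    """Kernel density estimate of the a = log10(ED50) distribution.

    Holds the density and cumulative distribution evaluated on a fixed grid;
    sampling is by inverse-transform through the gridded CDF (monotone
    linear interpolation).
    """

    grid: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    a50: float
    bandwidth: float

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def quantile(self, q):
        """Inverse CDF by monotone linear interpolation on the grid."""
        return np.interp(q, self.cdf, self.grid)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.quantile(rng.uniform(size=n))


def fit_a_distribution(
    raw: pd.DataFrame | np.ndarray,
    bandwidth: float | str = "silverman",
    grid_size: int = 512,
    grid_pad: float = 3.0,
) -> ADistribution:
    """Fit the KDE over a-values and precompute its CDF for sampling.

    Parameters
    ----------
    raw : DataFrame with an ``a`` column, or 1-D array of a-values.
    bandwidth : positive float, or "silverman" for the normal-reference rule.
    grid_size : number of evaluation points.
    grid_pad : grid extension beyond the data range, in bandwidths.
    """
    a = np.asarray(raw["a"] if isinstance(raw, pd.DataFrame) else raw, dtype=float)
    if len(a) < MIN_N:
        raise ValueError(f"need at least {MIN_N} a-values; got {len(a)}")
    if np.ptp(a) == 0:
        raise ValueError("column 'a' is degenerate (all values identical); cannot fit a KDE")

    if bandwidth == "silverman":
        # Silverman's normal-reference rule on the a sample
        bw = 0.9 * min(a.std(ddof=1), stats.iqr(a) / 1.34) * len(a) ** (-1 / 5)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(a, bw_method=bw / a.std(ddof=1))

    lo = max(a.min() - grid_pad * bw, 1e-8)  # a must stay positive
    hi = a.max() + grid_pad * bw
    grid = np.linspace(lo, hi, grid_size)
    density = kde(grid)
    area = np.trapezoid(density, grid)
    density = density / area
    cdf = cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    a50 = float(np.interp(0.5, cdf, grid))
    return ADistribution(grid=grid, density=density, cdf=cdf, a50=a50, bandwidth=bw)


# --------------------------------------------------------------------------
# MCMC machinery (shared by the regression and the noise-population fit)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol for one Bayesian fit.

    Defaults mirror the regression protocol: 4 chains, 4000 iterations per
    chain with 2000 discarded as warm-up, post-warm-up draws thinned by 2
    (1000 retained draws per chain).  ``walkers`` is the ensemble size per
    chain (an implementation detail of the ensemble sampler, not part of the
    protocol).
    """

    chains: int = 4
    iterations: int = 4000
    warmup: int = 2000
    thin: int = 2
    walkers: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split R-hat")
        if not (0 < self.warmup < self.iterations):
            raise ValueError("warmup must satisfy 0 < warmup < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin


NOISE_MCMC_DEFAULTS = dict(chains=4, iterations=2000, warmup=1000, thin=1)


def _run_ensemble_chains(
    log_prob,
    ndim: int,
    init_center: np.ndarray,
    init_scale: np.ndarray,
    config: MCMCConfig,
) -> np.ndarray:
    """Run ``config.chains`` independent emcee ensembles.

    Returns an array of shape (chains, draws_per_chain, ndim): post-warm-up
    thinned ensemble states flattened iteration-major and subsampled with a
    walker-rotating stride down to the protocol's retained-draw count.
    """
    import emcee

    n_keep = config.draws_per_chain
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    chains = np.empty((config.chains, n_keep, ndim))
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        p0 = init_center + init_scale * rng.standard_normal((config.walkers, ndim))
        # guard against pathological starts
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
        tries = 0
        while np.any(bad):
            p0[bad] = init_center + 0.1 * init_scale * rng.standard_normal(
                (bad.sum(), ndim)
            )
            lp0 = log_prob(p0)
            bad = ~np.isfinite(lp0)
            tries += 1
            if tries > 100:
                raise RuntimeError("could not initialise walkers at finite posterior density")
        sampler = emcee.EnsembleSampler(
            config.walkers, ndim, log_prob, vectorize=True,
        )
        sampler._random = np.random.RandomState(
            np.random.SeedSequence(chain_seeds[c].entropy, spawn_key=(c, 1)).generate_state(1)[0]
        )
        sampler.run_mcmc(p0, config.iterations, progress=False, skip_initial_state_check=True)
        kept = sampler.get_chain(discard=config.warmup, thin=config.thin)
        # (steps, walkers, ndim) -> iteration-major flat order, then rotate
        # through walkers so consecutive retained draws come from different
        # walkers at different iterations.
        steps, walkers = kept.shape[0], kept.shape[1]
        total = steps * walkers
        if total < n_keep:
            raise RuntimeError("ensemble produced fewer draws than the protocol retains")
        step_idx = (np.linspace(0, steps - 1, n_keep)).astype(int)
        walker_idx = np.arange(n_keep) % walkers
        chains[c] = kept[step_idx, walker_idx, :]
    return chains


def _draws_frame(chains: np.ndarray, names: list[str]) -> pd.DataFrame:
    n_chains, n_draws, _ = chains.shape
    df = pd.DataFrame(chains.reshape(-1, chains.shape[2]), columns=names)
    df.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
    df.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
    return df


def _check_gate(diag: Diagnostics, label: str) -> bool:
    if not diag.converged:
        warnings.warn(
            f"{label}: convergence gate failed "
            f"(max R-hat {diag.max_rhat:.4f}, min ESS {diag.min_ess:.0f}); "
            "treat this posterior with caution",
            ConvergenceWarning,
            stacklevel=3,
        )
        return False
    return True


# --------------------------------------------------------------------------
# Heteroscedastic regression of log b on a
# --------------------------------------------------------------------------

REGRESSION_PARAMS = ["alpha", "beta", "sigma0", "sigma1"]


@dataclass
class RegressionPosterior:
    """Posterior draws of (alpha, beta, sigma0, sigma1) with diagnostics."""

    draws: pd.DataFrame  # columns: chain, draw, alpha, beta, sigma0, sigma1
    diagnostics: Diagnostics
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.draws["sigma0"] <= 0) or np.any(self.draws["sigma1"] <= 0):
            raise ValueError("sigma0/sigma1 draws must all be positive")

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.draws
        return (
            d["alpha"].to_numpy(),
            d["beta"].to_numpy(),
            d["sigma0"].to_numpy(),
            d["sigma1"].to_numpy(),
        )

    def means(self) -> dict[str, float]:
        return {p: float(self.draws[p].mean()) for p in REGRESSION_PARAMS}


def _regression_log_prob(theta: np.ndarray, a: np.ndarray, logb: np.ndarray,
                         prior_only: bool) -> np.ndarray:
    """Vectorised log posterior over walkers.

    theta columns: alpha, beta, log sigma0, log sigma1 (unconstrained scale;
    the half-Cauchy prior carries the log-scale Jacobian).
    """
    out_of_bounds = np.any(np.abs(theta) > THETA_BOUND, axis=1)
    theta = np.where(out_of_bounds[:, None], 0.0, theta)
    alpha, beta = theta[:, 0], theta[:, 1]
    t0, t1 = theta[:, 2], theta[:, 3]
    s0, s1 = np.exp(t0), np.exp(t1)
    # priors: normal(0,1) on alpha/beta; half-Cauchy(0,1) on sigmas + Jacobian
    lp = (
        -0.5 * (alpha**2 + beta**2)
        - np.log1p(s0**2) + t0
        - np.log1p(s1**2) + t1
    )
    if not prior_only:
        mu = alpha[:, None] + beta[:, None] * a[None, :]
        sd = s0[:, None] + s1[:, None] * a[None, :]
        if np.any(sd <= 0):
            raise FloatingPointError("nonpositive residual SD evaluated in likelihood")
        lp = lp + np.sum(
            -0.5 * ((logb[None, :] - mu) / sd) ** 2 - np.log(sd), axis=1
        )
    return np.where(out_of_bounds, -np.inf, lp)


def fit_logb_regression(
    raw: pd.DataFrame,
    config: MCMCConfig | None = None,
    prior_only: bool = False,
) -> RegressionPosterior:
    """Fit ``log b ~ normal(alpha + beta*a, sigma0 + sigma1*a)`` by MCMC.

    Priors: alpha, beta ~ normal(0, 1); sigma0, sigma1 ~ half-Cauchy(0, 1).
    With ``prior_only=True`` the likelihood is dropped and the sampler
    targets the prior (a sanity-check mode).

    The returned posterior carries rank-normalized split R-hat and bulk/tail
    ESS; if the gate (max R-hat < 1.01, ESS > 400) fails, the result is
    flagged ``converged=False`` and a ``ConvergenceWarning`` is issued.
    """
    config = config or MCMCConfig()
    raw = validate_raw_estimates(raw, require_rmse=False)
    a = np.asarray(raw["a"], dtype=float)
    logb = np.log(np.asarray(raw["b"], dtype=float))

    if prior_only:
        center = np.array([0.0, 0.0, 0.0, 0.0])
        scale = np.array([1.0, 1.0, 1.0, 1.0])
    else:
        # initialise near an OLS fit to cut warm-up transients
        X = np.column_stack([np.ones_like(a), a])
        coef, *_ = np.linalg.lstsq(X, logb, rcond=None)
        resid_sd = max(np.std(logb - X @ coef), 1e-3)
        center = np.array([coef[0], coef[1], np.log(resid_sd / 2), np.log(resid_sd / (2 * max(a.mean(), 0.1)))])
        scale = np.array([0.2, 0.2, 0.5, 0.5])

    chains_u = _run_ensemble_chains(
        lambda th: _regression_log_prob(th, a, logb, prior_only),
        ndim=4, init_center=center, init_scale=scale, config=config,
    )
    chains = chains_u.copy()
    chains[..., 2] = np.exp(chains_u[..., 2])
    chains[..., 3] = np.exp(chains_u[..., 3])
    diag = compute_diagnostics(
        {p: chains[..., i] for i, p in enumerate(REGRESSION_PARAMS)}
    )
    converged = _check_gate(diag, "log-b regression")
    return RegressionPosterior(
        draws=_draws_frame(chains, REGRESSION_PARAMS),
        diagnostics=diag,
        converged=converged,
    )


# --------------------------------------------------------------------------
# Gamma population model over measurement-noise levels
# --------------------------------------------------------------------------

NOISE_PARAMS = ["c", "d"]


@dataclass
class NoisePosterior:
    """Posterior draws of the gamma (shape c, rate d) noise population."""

    draws: pd.DataFrame  # columns: chain, draw, c, d
    diagnostics: Diagnostics
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.draws["c"] <= 0) or np.any(self.draws["d"] <= 0):
            raise ValueError("c/d draws must all be positive")

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.draws["c"].to_numpy(), self.draws["d"].to_numpy()


THETA_BOUND = 30.0  # log-scale parameters beyond exp(30) are rejected outright


def _gamma_log_prob(theta: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    tc, td = theta[:, 0], theta[:, 1]
    out_of_bounds = np.any(np.abs(theta) > THETA_BOUND, axis=1)
    tc = np.where(out_of_bounds, 0.0, tc)
    td = np.where(out_of_bounds, 0.0, td)
    c, d = np.exp(tc), np.exp(td)
    lp = -np.log1p(c**2) + tc - np.log1p(d**2) + td  # half-Cauchy + Jacobian
    n = sigmas.size
    sum_log = np.sum(np.log(sigmas))
    sum_sig = np.sum(sigmas)
    from scipy.special import gammaln

    lp = lp + n * (c * np.log(d)) - n * gammaln(c) + (c - 1.0) * sum_log - d * sum_sig
    return np.where(out_of_bounds, -np.inf, lp)


def fit_sigma_population(
    sigmas,
    config: MCMCConfig | None = None,
) -> NoisePosterior:
    """Fit ``sigma_i ~ gamma(c, d)`` (shape-rate) with half-Cauchy(0,1) priors.

    Default protocol: 4 chains of 2000 iterations, 1000 warm-up, no thinning
    (1000 retained draws per chain); same convergence gate as the regression.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size < MIN_N:
        raise ValueError(f"need at least {MIN_N} sigma values; got {sigmas.size}")
    if np.any(sigmas <= 0) or not np.all(np.isfinite(sigmas)):
        raise ValueError("all sigma values must be positive and finite")
    degenerate = np.ptp(sigmas) == 0.0
    if degenerate:
        warnings.warn(
            "all sigma values are identical: the gamma population parameters "
            "are unidentified (shape/rate diverge along a ridge); the fit is "
            "flagged non-converged",
            ConvergenceWarning,
            stacklevel=2,
        )
    config = config or MCMCConfig(**NOISE_MCMC_DEFAULTS)

    m, v = sigmas.mean(), max(sigmas.var(ddof=1), 1e-12)
    c0 = np.clip(m**2 / v, 1e-2, 1e4)  # method-of-moments start
    d0 = np.clip(m / v, 1e-2, 1e6)
    center = np.log(np.array([c0, d0]))
    scale = np.array([0.3, 0.3])

    chains_u = _run_ensemble_chains(
        lambda th: _gamma_log_prob(th, sigmas),
        ndim=2, init_center=center, init_scale=scale, config=config,
    )
    chains = np.exp(chains_u)
    diag = compute_diagnostics({p: chains[..., i] for i, p in enumerate(NOISE_PARAMS)})
    converged = _check_gate(diag, "noise-population gamma fit") and not degenerate
    return NoisePosterior(
        draws=_draws_frame(chains, NOISE_PARAMS),
        diagnostics=diag,
        converged=converged,
    )


# --------------------------------------------------------------------------
# Posterior predictive check for the regression
# --------------------------------------------------------------------------

def ppc_regression(
    posterior: RegressionPosterior,
    raw: pd.DataFrame | None = None,
    a_grid: np.ndarray | None = None,
    grid_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive quantile ribbon for b as a function of a.

    For each a on the grid, one predictive log b is simulated per posterior
    draw (parameter draw plus observation noise) and the 2.5/50/97.5%
    quantiles of b are returned.  On well-specified data about 95% of raw
    points should fall inside the outer ribbon.
    """
    if a_grid is None:
        if raw is None:
            raise ValueError("provide raw estimates or an explicit a_grid")
        a = np.asarray(raw["a"], dtype=float)
        a_grid = np.linspace(a.min(), a.max(), grid_size)
    a_grid = np.asarray(a_grid, dtype=float)
    alpha, beta, s0, s1 = posterior.arrays()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(alpha), len(a_grid)))
    mu = alpha[:, None] + beta[:, None] * a_grid[None, :]
    sd = s0[:, None] + s1[:, None] * a_grid[None, :]
    pred_b = np.exp(mu + sd * z)
    lo, med, hi = np.percentile(pred_b, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame({"a": a_grid, "b_lo": lo, "b_med": med, "b_hi": hi})


def ppc_coverage(ribbon: pd.DataFrame, raw: pd.DataFrame) -> float:
    """Fraction of raw (a, b) points inside the 2.5-97.5% predictive ribbon."""
    a = np.asarray(raw["a"], dtype=float)
    b = np.asarray(raw["b"], dtype=float)
    lo = np.interp(a, ribbon["a"], ribbon["b_lo"])
    hi = np.interp(a, ribbon["a"], ribbon["b_hi"])
    return float(np.mean((b >= lo) & (b <= hi)))
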