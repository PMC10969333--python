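"""The fitted population model as a scikit-learn-style generative estimator.

:class:`VirtualPopulation` bundles the whole fitting pipeline — KDE over
``a``, Bayesian heteroscedastic regression of ``log b`` on ``a``, RMSE-based
calibration of per-individual noise levels and the gamma noise-population
fit — behind a ``fit`` / ``sample`` interface analogous to
``sklearn.mixture.GaussianMixture``.  Fitted state lives in
trailing-underscore attributes; ``get_params`` / ``set_params`` come from
``sklearn.base.BaseEstimator`` so the class composes with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import calibration, population, sampling
from .population import MCMCConfig, NOISE_MCMC_DEFAULTS

__all__ = ["VirtualPopulation"]


class VirtualPopulation(BaseEstimator):
    """Generative population model of light-sensitivity dose-response curves.

    Parameters
    ----------
    bandwidth : "silverman" or positive float
        KDE bandwidth for the a = log10(ED50) distribution.
    chains, iterations, warmup, thin, walkers :
        MCMC protocol for the log-b regression (defaults: 4 chains of 4000
        iterations, 2000 warm-up, thinned by 2).
    noise_iterations, noise_warmup :
        Protocol for the gamma noise-population fit (defaults 2000 / 1000,
        unthinned), sharing ``chains`` and ``walkers``.
    calibration_replicates : int
        Simulated experiments per RMSE evaluation during sigma calibration.
    measurement_grid : sequence of lux values
        Illuminances at which calibration experiments are simulated.
    random_state : int
        Seed for fitting (MCMC initialisation and calibration deviates).

    Attributes
    ----------
    a_distribution_ : fitted KDE with inverse-transform sampling.
    regression_ : posterior of (alpha, beta, sigma0, sigma1), with diagnostics.
    noise_ : posterior of the gamma (c, d) noise population.
    sigmas_ : calibrated per-individual noise levels (aligned with X).
    ed25_floor_, ed75_ceiling_ : rejection bounds for virtual curves.
    population_model_ : the sampleable :class:`sampling.PopulationModel`.
    converged_ : True when both MCMC fits passed the convergence gate.
    """

    def __init__(
        self,
        bandwidth="silverman",
        chains: int = 4,
        iterations: int = 4000,
        warmup: int = 2000,
        thin: int = 2,
        walkers: int = 32,
        noise_iterations: int = NOISE_MCMC_DEFAULTS["iterations"],
        noise_warmup: int = NOISE_MCMC_DEFAULTS["warmup"],
        calibration_replicates: int = 100,
        measurement_grid=calibration.DEFAULT_MEASUREMENT_GRID,
        random_state: int = 0,
    ):
        self.bandwidth = bandwidth
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.thin = thin
        self.walkers = walkers
        self.noise_iterations = noise_iterations
        self.noise_warmup = noise_warmup
        self.calibration_replicates = calibration_replicates
        self.measurement_grid = measurement_grid
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "VirtualPopulation":
        """Fit the population model to a raw-estimates table.

        ``X`` must have columns ``a``, ``b`` and either ``rmse`` (noise
        levels are then calibrated by simulation) or a precomputed ``sigma``
        column (calibration is skipped).
        """
        has_sigma = "sigma" in getattr(X, "columns", [])
        X = population.validate_raw_estimates(X, require_rmse=not has_sigma)
        seed = int(self.random_state)

        self.a_distribution_ = population.fit_a_distribution(X, bandwidth=self.bandwidth)
        self.regression_ = population.fit_logb_regression(
            X,
            MCMCConfig(
                chains=self.chains, iterations=self.iterations,
                warmup=self.warmup, thin=self.thin, walkers=self.walkers,
                seed=seed,
            ),
        )
        if has_sigma:
            sigmas = np.asarray(X["sigma"], dtype=float)
            if np.any(sigmas <= 0):
                raise ValueError("provided sigma column must be strictly positive")
        else:
            calibrated = calibration.calibrate_all(
                X, grid=self.measurement_grid,
                replicates=self.calibration_replicates, seed=seed + 1,
            )
            sigmas = calibrated["sigma"].to_numpy()
        self.sigmas_ = sigmas
        self.noise_ = population.fit_sigma_population(
            sigmas,
            MCMCConfig(
                chains=self.chains, iterations=self.noise_iterations,
                warmup=self.noise_warmup, thin=1, walkers=self.walkers,
                seed=seed + 2,
            ),
        )
        self.ed25_floor_, self.ed75_ceiling_ = sampling.rejection_bounds(X)
        self.population_model_ = sampling.PopulationModel(
            a_dist=self.a_distribution_,
            regression=self.regression_,
            noise=self.noise_,
            ed25_floor=self.ed25_floor_,
            ed75_ceiling=self.ed75_ceiling_,
        )
        self.converged_ = bool(self.regression_.converged and self.noise_.converged)
        self.n_individuals_ = len(X)
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "population_model_"):
            raise RuntimeError("this VirtualPopulation instance is not fitted yet")

    def sample(self, n: int, eta: float | None = None, random_state=None) -> pd.DataFrame:
        """Draw n virtual individuals (columns a, b, sigma).

        ``eta=None`` uses the unrestricted process; numeric ``eta`` in
        [0, 1] reduces population heterogeneity.
        """
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        return sampling.sample_individuals(self.population_model_, n, eta=eta, rng=rng)

    def simulate_experiment(
        self, n: int, grid=None, eta: float | None = None, random_state=None
    ) -> sampling.VirtualExperiment:
        """Simulate one virtual experiment (n individuals x grid)."""
        self._check_fitted()
        grid = self.measurement_grid if grid is None else grid
        rng = np.random.default_rng(random_state)
        return sampling.virtual_experiment(
            self.population_model_, n, grid, eta=eta, rng=rng
        )
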