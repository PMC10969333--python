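"""Synthetic raw dose-response estimates and the melanopic-EDI utility.

The population model is fitted to a table of per-individual raw estimates
``(a_i, b_i, rmse_i)`` obtained upstream by fitting dose-response curves to
laboratory melatonin data.  The original study's table is not redistributable,
so this module generates statistically plausible *synthetic* stand-ins with a
known ground truth, which makes every downstream fitting and power
computation testable end-to-end:

* ``a_i`` is drawn from a truncated normal on [1, 3] (log10-ED50 between 10
  and 1000 lux), sized so a sample of 41 spans roughly the 60-fold
  sensitivity range reported for real participants;
* ``log b_i = alpha + beta * a_i + normal(0, sigma0 + sigma1 * a_i)`` — the
  same heteroscedastic regression the population model assumes, so parameter
  recovery can be checked against the generating truth;
* ``rmse_i`` (curve-fit root-mean-square error, suppression scale) from a
  right-skewed gamma with mean ~0.1.

All defaults are frozen, documented constants; the data they produce are
synthetic and are never a claim about any real participant sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FixtureSpec",
    "generate_raw_estimates",
    "melanopic_edi",
    "melanopic_edi_lookup",
    "MELANOPIC_EDI_PAIRS",
]

# Printed photopic-lux -> melanopic-EDI pairs for the fluorescent source of the
# underlying study.  The 1106.21 entry was printed against "nominal 200 lx",
# an apparent typo for the 2000 lx level (200 lx already maps to 99.76).
MELANOPIC_EDI_PAIRS: dict[float, float] = {
    10.0: 1.58,
    100.0: 48.24,
    200.0: 99.76,
    400.0: 206.33,
    2000.0: 1106.21,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic raw-estimates table.

    Attributes
    ----------
    n : int
        Number of individuals (default 41, the real study's analysed sample).
    alpha, beta : float
        Intercept and slope of the ground-truth regression of log b on a.
    sigma0, sigma1 : float
        Intercept and slope of the residual standard deviation
        ``sigma0 + sigma1 * a`` (heteroscedastic when sigma1 > 0).
    a_mean, a_sd : float
        Location and scale of the truncated-normal a-distribution.
    a_bounds : tuple of float
        Truncation interval for a (default [1, 3]).
    rmse_shape, rmse_rate : float
        Gamma shape and rate for the per-individual curve-fit RMSE.
    seed : int
        Seed for the generator; fixed default so fixtures are reproducible.
    """

    n: int = 41
    alpha: float = -1.0
    beta: float = 0.6
    sigma0: float = 0.05
    sigma1: float = 0.1
    a_mean: float = 2.0
    a_sd: float = 0.45
    a_bounds: tuple[float, float] = (1.0, 3.0)
    rmse_shape: float = 4.0
    rmse_rate: float = 40.0
    seed: int = 1234

    def ground_truth(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma0": self.sigma0,
            "sigma1": self.sigma1,
        }


def generate_raw_estimates(spec: FixtureSpec = FixtureSpec()) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic raw-estimates table plus its ground-truth record.

    Returns
    -------
    raw : pandas.DataFrame
        Columns ``id``, ``a``, ``b``, ``rmse``; one row per individual.
    truth : dict
        The generating regression parameters, for recovery tests.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = spec.a_bounds
    if lo <= 0:
        raise ValueError("a_bounds must be positive (a = log10 ED50 > 0)")
    if spec.sigma0 < 0 or spec.sigma1 < 0:
        raise ValueError("sigma0 and sigma1 must be >= 0")
    rng = np.random.default_rng(spec.seed)

    za, zb = (lo - spec.a_mean) / spec.a_sd, (hi - spec.a_mean) / spec.a_sd
    a = stats.truncnorm.rvs(za, zb, loc=spec.a_mean, scale=spec.a_sd,
                            size=spec.n, random_state=rng)
    sd = spec.sigma0 + spec.sigma1 * a
    if np.any(sd < 0):
        raise ValueError("residual SD sigma0 + sigma1*a is negative for some a")
    logb = spec.alpha + spec.beta * a + rng.normal(0.0, sd)
    rmse = rng.gamma(spec.rmse_shape, 1.0 / spec.rmse_rate, size=spec.n)

    raw = pd.DataFrame(
        {
            "id": np.arange(1, spec.n + 1),
            "a": a,
            "b": np.exp(logb),
            "rmse": rmse,
        }
    )
    return raw, spec.ground_truth()


def melanopic_edi(photopic_lux: float, scale: float) -> float:
    """Convert photopic lux to melanopic EDI with a single scaling factor.

    Valid when the source spectrum does not change with intensity, so one
    multiplicative factor relates the two metrics.
    """
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    if photopic_lux < 0:
        raise ValueError("photopic_lux must be >= 0")
    return photopic_lux * scale


def melanopic_edi_lookup(nominal_photopic_lux: float) -> float:
    """Melanopic EDI for one of the five nominal photopic levels of the
    underlying study's light source, returned verbatim from the published
    per-level conversions (the ratio varies with level, ~0.16 at 10 lx to
    ~0.55 at 2000 lx, so no single scale factor reproduces them)."""
    key = float(nominal_photopic_lux)
    if key not in MELANOPIC_EDI_PAIRS:
        levels = sorted(MELANOPIC_EDI_PAIRS)
        raise KeyError(
            f"no melanopic-EDI entry for nominal {nominal_photopic_lux} photopic lx; "
            f"available levels: {levels}"
        )
    return MELANOPIC_EDI_PAIRS[key]
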