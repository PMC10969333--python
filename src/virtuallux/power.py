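"""Monte-Carlo power analysis for virtual melatonin-suppression experiments.

Two experiment classes are supported:

* **comparison** — does mean suppression differ between two illuminance
  levels ``x1`` and ``x2``?
* **intervention** — does an intervention that multiplies every individual's
  ED50 by ``chi`` change suppression at a fixed illuminance ``x``?

Each class can be run as a **within**-subjects design (the same N virtual
individuals measured under both conditions; paired t-test) or a
**between**-subjects design (two independent groups of N; independent
t-test, Welch by default).

A trial "succeeds" when the two-sided t-test rejects at the chosen test size
*and* the observed mean difference has the correct sign (higher illuminance
or a sensitising intervention, chi < 1, should raise suppression).  Under a
true null the success rate is therefore about alpha/2.  At chi = 1 the sign
is undefined and the trial scores plain rejection.  Power is the success
fraction over Monte-Carlo replicate trials, with the binomial standard error
attached.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import _suppression_arrays, inv_logit, logit
from .sampling import PopulationModel, sample_individuals

__all__ = [
    "DesignSpec",
    "PowerCell",
    "comparison_trial",
    "intervention_trial",
    "estimate_power",
    "power_grid",
    "FULL_ILLUMINANCE_LEVELS",
    "FULL_SAMPLE_SIZES",
    "FULL_ETA_LEVELS",
    "FULL_ALPHA_LEVELS",
    "FULL_CHI_LEVELS",
]

# Reference grid axes for full-scale power surfaces; any axis can be
# desk-scale runs.
FULL_ILLUMINANCE_LEVELS = tuple(range(10, 2000, 20))  # 10, 30, ..., 1990 lux
FULL_SAMPLE_SIZES = tuple(range(10, 101, 10))
FULL_ETA_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
FULL_ALPHA_LEVELS = (0.01, 0.05, 0.10)
FULL_CHI_LEVELS = tuple(round(0.2 * k, 1) for k in range(1, 11))  # 0.2 .. 2.0


@dataclass(frozen=True)
class DesignSpec:
    """One design point of a power analysis.

    For ``experiment="comparison"`` provide ``x1`` and ``x2`` (lux,
    different); for ``experiment="intervention"`` provide ``x`` (lux) and
    ``chi`` (ED50 multiplier).  ``N`` is the per-group (or paired) sample
    size, ``eta`` the population heterogeneity level and ``alpha`` the test
    size.
    """

    experiment: str  # "comparison" | "intervention"
    design: str  # "within" | "between"
    N: int
    eta: float = 1.0
    alpha: float = 0.05
    x1: float | None = None
    x2: float | None = None
    x: float | None = None
    chi: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("comparison", "intervention"):
            raise ValueError(f"unknown experiment class {self.experiment!r}")
        if self.design not in ("within", "between"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.experiment == "comparison":
            if self.x1 is None or self.x2 is None:
                raise ValueError("comparison needs x1 and x2")
            if self.x1 == self.x2:
                raise ValueError("comparison requires x1 != x2")
            if min(self.x1, self.x2) < 1:
                raise ValueError("illuminances must be >= 1 lux")
        else:
            if self.x is None or self.chi is None:
                raise ValueError("intervention needs x and chi")
            if self.x < 1:
                raise ValueError("illuminance must be >= 1 lux")
            if not (self.chi > 0):
                raise ValueError("chi must be > 0")


@dataclass(frozen=True)
class PowerCell:
    """Estimated power at one design point, with Monte-Carlo error."""

    spec: DesignSpec
    replicates: int
    power: float
    mc_standard_error: float
    seed: int


def _measure_at(a, b, sigma, x, rng):
    """Noisy measurements of individuals (a, b, sigma) at illuminance x."""
    s = _suppression_arrays(float(x), a, b)
    return inv_logit(logit(s) + sigma * rng.standard_normal(a.shape))


def _score(group_hi, group_lo, paired, alpha, equal_var, signed=True):
    """Two-sided t-test plus sign check.

    ``group_hi`` is the condition expected (by the model's monotonicity or
    the intervention direction) to show *higher* suppression.  With
    ``signed=False`` only rejection counts (the chi = 1 null, where no sign
    is defined).
    """
    diff_mean = group_hi.mean() - group_lo.mean()
    if paired:
        d = group_hi - group_lo
        if d.std(ddof=1) == 0.0:
            # zero-variance limit of the t statistic
            return diff_mean != 0.0 and (diff_mean > 0.0 or not signed)
        p = stats.ttest_rel(group_hi, group_lo).pvalue
    else:
        if group_hi.std(ddof=1) == 0.0 and group_lo.std(ddof=1) == 0.0:
            return diff_mean != 0.0 and (diff_mean > 0.0 or not signed)
        p = stats.ttest_ind(group_hi, group_lo, equal_var=equal_var).pvalue
    reject = bool(p < alpha)
    if not signed:
        return reject
    return reject and diff_mean > 0.0


def comparison_trial(
    model: PopulationModel,
    spec: DesignSpec,
    rng: np.random.Generator,
    equal_var: bool = False,
) -> bool:
    """Simulate one two-illuminance comparison experiment and test it.

    Within-subjects: N individuals, each measured at x1 and x2 with the same
    curve and noise level (independent noise realisations); paired t-test.
    Between-subjects: 2N distinct individuals, N per illuminance;
    independent t-test (Welch unless ``equal_var``).
    """
    if spec.experiment != "comparison":
        raise ValueError("spec is not a comparison design")
    x_lo, x_hi = sorted((spec.x1, spec.x2))
    if spec.design == "within":
        ind = sample_individuals(model, spec.N, eta=spec.eta, rng=rng)
        a, b, sg = (ind[c].to_numpy() for c in ("a", "b", "sigma"))
        m_lo = _measure_at(a, b, sg, x_lo, rng)
        m_hi = _measure_at(a, b, sg, x_hi, rng)
        return _score(m_hi, m_lo, paired=True, alpha=spec.alpha, equal_var=equal_var)
    ind = sample_individuals(model, 2 * spec.N, eta=spec.eta, rng=rng)
    a, b, sg = (ind[c].to_numpy() for c in ("a", "b", "sigma"))
    m_lo = _measure_at(a[: spec.N], b[: spec.N], sg[: spec.N], x_lo, rng)
    m_hi = _measure_at(a[spec.N :], b[spec.N :], sg[spec.N :], x_hi, rng)
    return _score(m_hi, m_lo, paired=False, alpha=spec.alpha, equal_var=equal_var)


def intervention_trial(
    model: PopulationModel,
    spec: DesignSpec,
    rng: np.random.Generator,
    equal_var: bool = False,
) -> bool:
    """Simulate one intervention experiment (ED50 multiplied by chi).

    Within-subjects: the same N individuals measured at ``x`` before and
    after the intervention (same sigma, independent noise).  Between:
    a baseline group and an independent intervention group of N each.
    chi < 1 sensitises (suppression should rise); chi > 1 desensitises; at
    chi = 1 the trial scores plain rejection (type-I behaviour).
    """
    if spec.experiment != "intervention":
        raise ValueError("spec is not an intervention design")
    shift = np.log10(spec.chi)
    signed = spec.chi != 1.0

    def shifted(a):
        a_new = a + shift
        if np.any(a_new <= 0):
            raise ValueError(
                f"chi={spec.chi} drives some sampled a = log10(ED50) below 0; "
                "intervention outside the model's domain"
            )
        return a_new

    if spec.design == "within":
        ind = sample_individuals(model, spec.N, eta=spec.eta, rng=rng)
        a, b, sg = (ind[c].to_numpy() for c in ("a", "b", "sigma"))
        m_nat = _measure_at(a, b, sg, spec.x, rng)
        m_int = _measure_at(shifted(a), b, sg, spec.x, rng)
        paired = True
    else:
        ind = sample_individuals(model, 2 * spec.N, eta=spec.eta, rng=rng)
        a, b, sg = (ind[c].to_numpy() for c in ("a", "b", "sigma"))
        m_nat = _measure_at(a[: spec.N], b[: spec.N], sg[: spec.N], spec.x, rng)
        m_int = _measure_at(
            shifted(a[spec.N :]), b[spec.N :], sg[spec.N :], spec.x, rng
        )
        paired = False
    # chi < 1 lowers the ED50, so intervention suppression should be higher
    hi, lo = (m_int, m_nat) if spec.chi <= 1.0 else (m_nat, m_int)
    return _score(hi, lo, paired=paired, alpha=spec.alpha,
                  equal_var=equal_var, signed=signed)


def estimate_power(
    model: PopulationModel,
    spec: DesignSpec,
    replicates: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
) -> PowerCell:
    """Monte-Carlo power at one design point: success fraction over trials."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    trial = comparison_trial if spec.experiment == "comparison" else intervention_trial
    wins = sum(trial(model, spec, rng, equal_var=equal_var) for _ in range(replicates))
    power = wins / replicates
    mc_se = float(np.sqrt(power * (1.0 - power) / replicates))
    return PowerCell(spec=spec, replicates=replicates, power=power,
                     mc_standard_error=mc_se, seed=seed)


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Counter-based per-cell seed, independent of grid iteration order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def power_grid(
    model: PopulationModel,
    experiment: str,
    design: str,
    *,
    x_pairs=None,
    x_levels=None,
    chi_levels=None,
    N_levels=(10, 50, 100),
    eta_levels=(1.0,),
    alpha_levels=(0.05,),
    replicates: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Estimate power over a grid of design points; one row per cell.

    Comparison grids iterate over ``x_pairs`` (iterable of (x1, x2));
    intervention grids over ``x_levels`` x ``chi_levels``.  Per-cell seeds
    are derived from ``seed`` and the cell's index by a counter-based
    scheme, so a rerun of the same grid is bit-identical and cells use
    independent random streams.
    """
    if experiment == "comparison":
        if not x_pairs:
            raise ValueError("comparison grid needs x_pairs")
        condition_axis = [{"x1": float(p[0]), "x2": float(p[1])} for p in x_pairs]
    elif experiment == "intervention":
        if not x_levels or not chi_levels:
            raise ValueError("intervention grid needs x_levels and chi_levels")
        condition_axis = [
            {"x": float(x), "chi": float(c)}
            for x, c in itertools.product(x_levels, chi_levels)
        ]
    else:
        raise ValueError(f"unknown experiment class {experiment!r}")
    for name, axis in (("N_levels", N_levels), ("eta_levels", eta_levels),
                       ("alpha_levels", alpha_levels)):
        if not axis:
            raise ValueError(f"{name} must be non-empty")

    rows = []
    for idx, (cond, N, eta, alpha) in enumerate(
        itertools.product(condition_axis, N_levels, eta_levels, alpha_levels)
    ):
        spec = DesignSpec(experiment=experiment, design=design, N=int(N),
                          eta=float(eta), alpha=float(alpha), **cond)
        cell = estimate_power(model, spec, replicates=replicates,
                              seed=_cell_seed(seed, idx), equal_var=equal_var)
        rows.append(
            {
                "experiment": experiment,
                "design": design,
                "x1": cond.get("x1"),
                "x2": cond.get("x2"),
                "x": cond.get("x"),
                "chi": cond.get("chi"),
                "N": int(N),
                "eta": float(eta),
                "alpha": float(alpha),
                "replicates": replicates,
                "power": cell.power,
                "mc_se": cell.mc_standard_error,
                "seed": cell.seed,
            }
        )
    return pd.DataFrame(rows)
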