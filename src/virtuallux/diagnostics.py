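"""MCMC convergence diagnostics and the convergence gate.

Convergence is diagnosed with rank-normalized split R-hat and bulk/tail
effective sample sizes; a fit passes the gate when max R-hat < 1.01 and the
smallest bulk or tail ESS exceeds 400.  The diagnostics themselves are
computed with arviz, the reference implementation of these criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Diagnostics", "compute_diagnostics", "RHAT_GATE", "ESS_GATE"]

RHAT_GATE = 1.01
ESS_GATE = 400.0


@dataclass(frozen=True)
class Diagnostics:
    """Per-parameter convergence diagnostics for one fit."""

    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(min(self.ess_bulk.values()), min(self.ess_tail.values()))

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_GATE and self.min_ess > ESS_GATE


def compute_diagnostics(draws_by_chain: dict[str, np.ndarray]) -> Diagnostics:
    """Rank-normalized split R-hat and bulk/tail ESS per parameter.

    Parameters
    ----------
    draws_by_chain : dict
        Maps a parameter name to an array of shape (n_chains, n_draws).
        At least 2 chains of at least 100 draws each are required (split
        R-hat is undefined for a single chain).
    """
    import arviz as az  # deferred: arviz import is slow

    for name, arr in draws_by_chain.items():
        arr = np.asarray(arr)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(
                f"parameter {name!r}: need >= 2 chains (shape (chains, draws)); "
                f"got shape {arr.shape}"
            )
        if arr.shape[1] < 100:
            raise ValueError(
                f"parameter {name!r}: need >= 100 draws per chain; got {arr.shape[1]}"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict({k: np.asarray(v) for k, v in draws_by_chain.items()})
        rhat = az.rhat(idata, method="rank")
        bulk = az.ess(idata, method="bulk")
        tail = az.ess(idata, method="tail")
    names = list(draws_by_chain)
    return Diagnostics(
        rhat={k: float(rhat[k].values) for k in names},
        ess_bulk={k: float(bulk[k].values) for k in names},
        ess_tail={k: float(tail[k].values) for k in names},
    )
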