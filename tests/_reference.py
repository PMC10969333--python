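"""Independent reference implementations used only as test oracles.

Rank-normalized split R-hat and Geyer-pair effective sample sizes,
implemented directly from the published diagnostic definitions so they can
cross-check the package's diagnostics (which are computed via arviz).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata


def _split(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    h = n // 2
    return np.vstack([x[:, :h], x[:, h : 2 * h]])


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average").reshape(x.shape)
    s = x.size
    return ndtri((r - 3.0 / 8.0) / (s - 2.0 * 3.0 / 8.0 + 1.0))


def _classic_rhat(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def reference_rhat(x) -> float:
    """Rank-normalized split R-hat (max of bulk and folded variants)."""
    x = np.asarray(x, dtype=float)
    s = _split(x)
    z_bulk = _rank_normalize(s)
    z_fold = _rank_normalize(np.abs(s - np.median(x)))
    return max(_classic_rhat(z_bulk), _classic_rhat(z_fold))


def _autocov(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    m = int(2 ** np.ceil(np.log2(2 * n)))
    xc = x - x.mean(axis=-1, keepdims=True)
    f = np.fft.rfft(xc, m, axis=-1)
    return np.fft.irfft(f * np.conj(f), m, axis=-1)[..., :n].real / n


def _ess_from_chains(z: np.ndarray) -> float:
    """Geyer initial-positive-monotone-sequence ESS on prepared chains."""
    m, n = z.shape
    acov = _autocov(z)
    mean_var = acov[:, 0].mean() * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += z.mean(axis=1).var(ddof=1)
    rho = 1.0 - (mean_var - acov.mean(axis=0)) / var_plus
    tau = -1.0
    prev_pair = np.inf
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    tau = max(tau, 1.0 / np.log10(m * n))
    return m * n / tau


def reference_ess_bulk(x) -> float:
    x = np.asarray(x, dtype=float)
    return _ess_from_chains(_rank_normalize(_split(x)))


def reference_ess_tail(x) -> float:
    x = np.asarray(x, dtype=float)
    s = _split(x)
    vals = []
    for q in (0.05, 0.95):
        ind = (s <= np.quantile(x, q)).astype(float)
        vals.append(_ess_from_chains(_rank_normalize(ind)))
    return min(vals)
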