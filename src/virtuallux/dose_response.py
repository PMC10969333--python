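"""Individual melatonin-suppression dose-response curves.

A single individual's response to evening light is modelled by a two-parameter
logistic-type curve on the log10-illuminance axis,

    s(x) = 1 - 1 / (1 + (log10(x) / a) ** b),

where ``x`` is photopic illuminance in lux, ``a = log10(ED50)`` locates the
curve (ED50 is the illuminance producing 50% melatonin suppression) and
``b > 0`` controls its steepness.  Suppression rises from 0 at 1 lux towards
100% as illuminance grows without bound.

The curve is only defined for ``x >= 1``: below 1 lux the ratio
``log10(x) / a`` is negative and non-integer powers of it are undefined.  The
dim-light control condition of laboratory protocols (< 1 lux) is represented
by zero suppression *by convention* where a caller needs it; ``suppression``
itself rejects ``x < 1`` rather than silently applying that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DoseResponseParams",
    "suppression",
    "suppression_from_log10",
    "effective_dose",
    "log10_effective_dose",
    "logit",
    "inv_logit",
    "apply_intervention",
]


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of one individual's dose-response curve.

    Parameters
    ----------
    a : float
        log10 of the ED50 in photopic lux.  Must be positive (ED50 above
        1 lux), which makes suppression monotone on the operational domain
        ``x >= 1``.
    b : float
        Shape (steepness) parameter; strictly positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be > 0 (ED50 above 1 lux); got a={self.a}")
        if not (self.b > 0):
            raise ValueError(f"b must be > 0; got b={self.b}")

    @property
    def ed50(self) -> float:
        """Illuminance (lux) producing 50% suppression."""
        return 10.0**self.a


def suppression(x, params: DoseResponseParams):
    """Melatonin suppression at illuminance ``x`` (lux).

    Accepts a scalar or array of illuminances, all of which must be >= 1 lux.
    Returns values in [0, 1), strictly increasing in ``x`` for ``x > 1``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0):
        raise ValueError(
            "suppression is undefined below 1 lux (log10(x)/a would be "
            "negative); represent dim control conditions as 0 explicitly"
        )
    s = _suppression_arrays(x, params.a, params.b)
    return float(s) if s.ndim == 0 else s


def _suppression_arrays(x, a, b):
    """Vectorised curve evaluation used by the samplers; no validation."""
    ratio = np.log10(x) / a
    return 1.0 - 1.0 / (1.0 + ratio**b)


def effective_dose(q, params: DoseResponseParams):
    """Illuminance (lux) producing suppression ``q``; the inverse of the curve.

    ``ed(q) = 10 ** (a * (-1 + 1/(1-q)) ** (1/b))`` for ``0 < q < 1``.
    ``effective_dose(0.5)`` is the ED50, ``10**a``.  For shallow curves
    (small b) and q near 1 the dose can exceed the double-precision range
    and overflows to inf; :func:`log10_effective_dose` stays finite there.
    """
    with np.errstate(over="ignore"):  # inf is the documented overflow value
        ed = np.asarray(10.0 ** np.asarray(log10_effective_dose(q, params)))
    return float(ed) if ed.ndim == 0 else ed


def log10_effective_dose(q, params: DoseResponseParams):
    """log10 of the effective dose; overflow-safe log-domain companion of
    :func:`effective_dose` (``a * (-1 + 1/(1-q)) ** (1/b)``)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError(f"effective dose requires 0 < q < 1; got {q}")
    ed = params.a * (-1.0 + 1.0 / (1.0 - q)) ** (1.0 / params.b)
    ed = np.asarray(ed)
    return float(ed) if ed.ndim == 0 else ed


def suppression_from_log10(log10_x, params: DoseResponseParams):
    """Suppression as a function of log10 illuminance (log-domain companion
    of :func:`suppression`; requires ``log10_x >= 0``, i.e. x >= 1 lux)."""
    lx = np.asarray(log10_x, dtype=float)
    if np.any(lx < 0.0):
        raise ValueError("suppression is undefined below 1 lux (log10 x < 0)")
    s = 1.0 - 1.0 / (1.0 + (lx / params.a) ** params.b)
    s = np.asarray(s)
    return float(s) if s.ndim == 0 else s


def _effective_dose_arrays(q, a, b):
    return 10.0 ** (a * (-1.0 + 1.0 / (1.0 - q)) ** (1.0 / b))


def logit(p):
    """log(p / (1 - p)) for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit requires 0 < p < 1")
    z = np.log(p) - np.log1p(-p)
    return float(z) if z.ndim == 0 else z


def inv_logit(z):
    """Inverse logit; maps the reals into (0, 1) (up to floating underflow
    at |z| beyond ~37)."""
    from scipy.special import expit

    p = np.asarray(expit(np.asarray(z, dtype=float)))
    return float(p) if p.ndim == 0 else p


def apply_intervention(params: DoseResponseParams, chi: float) -> DoseResponseParams:
    """Shift an individual's ED50 by the multiplier ``chi``; shape unchanged.

    An intervention that changes light sensitivity is modelled as a
    multiplicative shift of the ED50: the new ED50 is ``chi`` times the
    natural one, i.e. ``a -> a + log10(chi)``.  ``chi < 1`` makes the
    individual *more* sensitive (e.g. ``chi = 0.2`` divides the ED50 by 5);
    ``chi = 1`` is the identity.
    """
    if not (chi > 0):
        raise ValueError(f"chi must be > 0; got {chi}")
    a_new = params.a + np.log10(chi)
    if not (a_new > 0):
        raise ValueError(
            f"intervention multiplier chi={chi} would push a to {a_new:.4g} <= 0 "
            "(ED50 at or below 1 lux), outside the model's domain"
        )
    return replace(params, a=float(a_new))
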