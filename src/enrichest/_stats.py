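"""Numerically stable normal-distribution helpers.

The truncation corrections repeatedly evaluate ratios of the form
``(phi(a) - phi(b)) / (Phi(a) - Phi(b))`` with ``a >= b``.  When both
arguments sit far in the same tail the naive evaluation is 0/0; here the
ratio is computed in an exponentially scaled form via ``erfcx`` so it stays
finite for arbitrarily extreme truncation intervals.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx, ndtr

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


def npdf(x):
    """Standard normal density; 0 at infinite arguments."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape)
    finite = np.isfinite(x)
    out[finite] = np.exp(-0.5 * x[finite] ** 2) / _SQRT2PI
    return out


def ncdf(x):
    return ndtr(np.asarray(x, dtype=float))


def _ratio_same_tail(a, b):
    """Scaled (phi(a)-phi(b)) / (Phi(a)-Phi(b)) for 0 <= b <= a, finite.

    Factoring exp(-b^2/2) out of numerator and denominator:
      num = (exp(-(a^2-b^2)/2) - 1) / sqrt(2 pi)
      den = 0.5 [erfcx(b/sqrt2) - exp(-(a^2-b^2)/2) erfcx(a/sqrt2)]
    """
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.exp(-0.5 * (a - b) * (a + b))
    num = (e - 1.0) / _SQRT2PI
    den = 0.5 * (erfcx(b / _SQRT2) - e * erfcx(a / _SQRT2))
    return num / den


def trunc_phi_ratio(a, b):
    """(phi(a) - phi(b)) / (Phi(a) - Phi(b)) for a >= b, elementwise stable.

    Handles infinite endpoints (phi(+-inf) = 0, Phi(-inf) = 0, Phi(inf) = 1)
    and the degenerate limit a -> b, where the value is -a by l'Hopital.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    scalar = a.ndim == 0
    a = np.atleast_1d(a).astype(float)
    b = np.atleast_1d(b).astype(float)
    out = np.empty(a.shape)

    fin_a, fin_b = np.isfinite(a), np.isfinite(b)
    close = fin_a & fin_b & (np.abs(a - b) < 1e-12)
    out[close] = -0.5 * (a[close] + b[close])

    whole = ~fin_a & ~fin_b  # (-inf, inf): full support, correction vanishes
    out[whole] = 0.0

    lo_inf = ~fin_b & fin_a  # interval (-inf, a]: ratio = phi(a)/Phi(a)
    out[lo_inf] = np.sqrt(2.0 / np.pi) / erfcx(-a[lo_inf] / _SQRT2)

    hi_inf = ~fin_a & fin_b  # interval [b, inf): ratio = -phi(b)/Phi(-b)
    out[hi_inf] = -np.sqrt(2.0 / np.pi) / erfcx(b[hi_inf] / _SQRT2)

    both = fin_a & fin_b & ~close
    upper = both & (b >= 0)
    out[upper] = _ratio_same_tail(a[upper], b[upper])
    lower = both & (a <= 0)
    out[lower] = -_ratio_same_tail(-b[lower], -a[lower])
    mid = both & (b < 0) & (a > 0)  # straddles zero: direct form is stable
    out[mid] = (npdf(a[mid]) - npdf(b[mid])) / (ndtr(a[mid]) - ndtr(b[mid]))

    return float(out[0]) if scalar else out


def gauss_legendre_nodes(lo: float, hi: float, n: int):
    """Gauss-Legendre nodes and weights on [lo, hi]."""
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), half * w
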