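"""Beta-binomial probability layer with depth-dependent overdispersion.

Two sequencing libraries are compared gene by gene through the proportion
``p_i = n_i / (n_i + m_i)`` of tags that fall into library A. Conditional on
the total ``N_i = n_i + m_i``, the count ``n_i`` is modelled as beta-binomial
with mean proportion ``p`` and dispersion ``theta``, in the parameterization

    alpha = p / theta,   beta = (1 - p) / theta,

so ``p = alpha/(alpha+beta)`` and ``theta = 1/(alpha+beta)``. The binomial
distribution is the continuous limit ``theta -> 0``.

The central modelling assumption is that overdispersion shrinks with
sequencing depth,

    theta_i = D_i / N_i**gamma,

with one depth exponent ``gamma`` shared across genes and a per-gene scale
``D_i``. ``gamma = 0`` recovers the classical beta-binomial (depth-independent
overdispersion); ``0 < gamma < 1`` makes the variance of the proportion decay
like ``N**-gamma``, slower than the binomial's ``1/N`` but still vanishing at
large depth, which is what replicate RNA-Seq libraries empirically show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import binomtest

__all__ = [
    "P_EPS",
    "OverdispersionModel",
    "theta",
    "betabinom_logpmf",
    "binomial_test",
    "proportion_variance",
]

#: proportions are clamped to [P_EPS, 1 - P_EPS] inside likelihood
#: evaluations to keep optimizers in-domain
P_EPS = 1e-12

# betaln cancels catastrophically when alpha and beta are both huge
# (theta -> 0 with moderate p); below this scale a series around the
# binomial limit is exact to ~1e-7 in absolute log-likelihood
_SERIES_CUTOFF = 1e-4


def theta(D, N, gamma):
    """Depth-dependent overdispersion ``theta = D / N**gamma``.

    Parameters
    ----------
    D : float or array
        Per-gene overdispersion scale, >= 0.
    N : int or array
        Total tag count ``n + m``, >= 1.
    gamma : float
        Depth exponent, >= 0.
    """
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N < 1):
        raise ValueError("theta is undefined for N < 1")
    if np.any(D < 0):
        raise ValueError("D must be >= 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    out = D * N ** (-float(gamma))
    return out if out.ndim else float(out)


def _tri(j):
    # sum_{k=0}^{j-1} k
    return j * (j - 1.0) / 2.0


def _sqsum(j):
    # sum_{k=0}^{j-1} k^2
    return (j - 1.0) * j * (2.0 * j - 1.0) / 6.0


def _bb_core(n, m, p, th):
    """Log beta-binomial pmf *without* the binomial coefficient.

    Vectorized over broadcastable ``n, m, p, th``; ``p`` is clamped to the
    open unit interval. ``th == 0`` takes the exact binomial branch.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    th = np.asarray(th, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), P_EPS, 1.0 - P_EPS)
    n, m, p, th = np.broadcast_arrays(n, m, p, th)
    N = n + m

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        binom = n * np.log(p) + m * np.log1p(-p)

        th_safe = np.where(th > 0, th, 1.0)
        a = p / th_safe
        b = (1.0 - p) / th_safe
        exact = betaln(n + a, m + b) - betaln(a, b)

        # second-order expansion of
        #   sum log1p(k*th/p) + sum log1p(k*th/(1-p)) - sum log1p(k*th)
        t_p = th_safe / p
        t_q = th_safe / (1.0 - p)
        c1 = _tri(n) * t_p + _tri(m) * t_q - _tri(N) * th_safe
        c2 = _sqsum(n) * t_p**2 + _sqsum(m) * t_q**2 - _sqsum(N) * th_safe**2
        series = binom + c1 - 0.5 * c2

        small = (
            (N * th_safe < _SERIES_CUTOFF)
            & (n * t_p < _SERIES_CUTOFF)
            & (m * t_q < _SERIES_CUTOFF)
        )
        out = np.where(th > 0, np.where(small, series, exact), binom)
    return out


def betabinom_logpmf(n, m, p, theta):
    """Log pmf of observing ``n`` tags in A and ``m`` in B.

    ``log C(n+m, n) + log B(n+alpha, m+beta) - log B(alpha, beta)`` with
    ``alpha = p/theta``, ``beta = (1-p)/theta``; the ``theta -> 0`` limit is
    the exact binomial log pmf. Implemented through log-gamma throughout.

    Parameters broadcast; returns a scalar for scalar input.
    """
    n_a = np.asarray(n, dtype=float)
    m_a = np.asarray(m, dtype=float)
    p_a = np.asarray(p, dtype=float)
    th_a = np.asarray(theta, dtype=float)
    if np.any(n_a < 0) or np.any(m_a < 0):
        raise ValueError("counts must be >= 0")
    if np.any(n_a % 1 != 0) or np.any(m_a % 1 != 0):
        raise ValueError("counts must be integers")
    if np.any(n_a + m_a < 1):
        raise ValueError("n + m must be >= 1")
    if np.any(p_a <= 0) or np.any(p_a >= 1):
        raise ValueError("p must lie in the open interval (0, 1)")
    if np.any(th_a < 0):
        raise ValueError("theta must be >= 0")
    n_a, m_a, p_a, th_a = np.broadcast_arrays(n_a, m_a, p_a, th_a)
    N = n_a + m_a
    logc = gammaln(N + 1) - gammaln(n_a + 1) - gammaln(m_a + 1)
    out = logc + _bb_core(n_a, m_a, p_a, th_a)
    return out if out.ndim else float(out)


def binomial_test(n, m, p_n):
    """Exact two-sided binomial p-value of ``n`` successes in ``n + m``
    trials under success probability ``p_n``.

    Two-sidedness follows the minimum-likelihood convention (the sum of
    probabilities of outcomes no more probable than the observed one), so
    the p-value is 1 when the observation sits at the mode.
    """
    n_a = np.asarray(n)
    m_a = np.asarray(m)
    pn_a = np.asarray(p_n, dtype=float)
    if np.any(pn_a <= 0) or np.any(pn_a >= 1):
        raise ValueError("p_n must lie in (0, 1)")
    if np.any(n_a + m_a < 1):
        raise ValueError("n + m must be >= 1")
    n_b, m_b, pn_b = np.broadcast_arrays(n_a, m_a, pn_a)
    flat = [
        binomtest(int(ni), int(ni + mi), float(pi)).pvalue
        for ni, mi, pi in zip(n_b.ravel(), m_b.ravel(), pn_b.ravel())
    ]
    out = np.array(flat).reshape(n_b.shape)
    return out if out.ndim else float(out)


def proportion_variance(p, theta, N):
    """Exact conditional variance of the proportion ``n/N`` under the
    beta-binomial: ``p(1-p)(1 + N*theta) / (N(1 + theta))``.

    With ``theta = D/N**gamma`` and ``0 < gamma < 1`` this behaves like
    ``p(1-p) D N**-gamma`` at large ``N``: the error still vanishes with
    depth, but more slowly than the binomial's ``p(1-p)/N``.
    """
    p_a = np.asarray(p, dtype=float)
    th_a = np.asarray(theta, dtype=float)
    N_a = np.asarray(N, dtype=float)
    if np.any(N_a < 1):
        raise ValueError("N must be >= 1")
    if np.any(th_a < 0):
        raise ValueError("theta must be >= 0")
    if np.any(p_a < 0) or np.any(p_a > 1):
        raise ValueError("p must lie in [0, 1]")
    out = p_a * (1.0 - p_a) * (1.0 + N_a * th_a) / (N_a * (1.0 + th_a))
    return out if out.ndim else float(out)


@dataclass
class OverdispersionModel:
    """Fitted depth-dependent overdispersion: ``theta_i(N) = D_i / N**gamma``.

    Attributes
    ----------
    gamma : float
        Shared depth exponent (>= 0).
    D : dict
        Per-gene overdispersion scale (>= 0).
    loglik : float
        Attained maximum of the profile log-likelihood.
    gamma_grid : list of (gamma, loglik)
        The profile curve the maximum was read off.
    """

    gamma: float
    D: dict
    loglik: float
    gamma_grid: list = field(default_factory=list)

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if any(d < 0 for d in self.D.values()):
            raise ValueError("all D_i must be >= 0")

    def theta_of(self, gene_id, N):
        """theta for one gene at total count ``N`` (unknown genes -> 0)."""
        return theta(self.D.get(gene_id, 0.0), N, self.gamma)

    def theta_array(self, gene_ids, N):
        """Vectorized theta lookup; genes absent from the fit get D = 0."""
        D = np.array([self.D.get(g, 0.0) for g in gene_ids], dtype=float)
        return theta(D, N, self.gamma)

    @property
    def near_binomial(self) -> bool:
        """True when most genes fitted D essentially at the boundary, i.e.
        the data show no usable extra-binomial dispersion."""
        if not self.D:
            return True
        d = np.fromiter(self.D.values(), dtype=float)
        return float(np.mean(d <= 1e-6)) >= 0.5
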