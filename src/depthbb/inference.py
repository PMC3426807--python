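"""Profile maximum likelihood for (gamma, D_i), likelihood-ratio tests,
fold changes and the slope-based gamma estimate.

Fitting uses *duplicate pairs*: repeated A-vs-B sequencings of the same
biological material through independent library preparations. For gene i
and pair p the count ``n_ip`` is beta-binomial with a proportion ``p_i``
shared across pairs and dispersion ``theta_ip = D_i / N_ip**gamma`` at that
pair's observed total. Overdispersion is then identified from the scatter
of the per-pair proportions around the shared ``p_i``: at each candidate
``gamma`` the likelihood is maximized over (p_i, D_i) gene by gene, and the
profile curve over ``gamma`` is maximized on a grid.

Per-gene testing of one experiment-vs-control pair compares the
likelihood-maximizing proportion against the neutral ratio ``p_n`` with a
1-df chi-squared likelihood ratio test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountMatrix, GenePairCounts, GeneResultRow
from .errors import ConfigurationError, InsufficientDataError
from .model import P_EPS, OverdispersionModel, _bb_core, binomial_test, theta

__all__ = [
    "ReplicatePairSet",
    "VarianceTable",
    "DEFAULT_GAMMA_GRID",
    "estimate_phat",
    "profile_loglik",
    "fit_overdispersion",
    "lrt_pvalue",
    "fold_change",
    "fold_change_counts",
    "variance_table",
    "slope_gamma",
    "ttest_gold",
    "test_genes",
]

DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.0, 1.2001, 0.1), 10))
_D_LO, _D_HI = 1e-8, 10.0

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0
_INVPHI2 = (3.0 - math.sqrt(5.0)) / 2.0


@dataclass
class ReplicatePairSet:
    """Duplicate A-vs-B pairs over a common gene universe.

    ``n`` and ``m`` have shape (n_genes, n_pairs); column p holds the
    counts of pair ``pair_labels[p]``.
    """

    gene_ids: np.ndarray
    n: np.ndarray
    m: np.ndarray
    pair_labels: Sequence[str]

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.n.shape != self.m.shape or self.n.ndim != 2:
            raise ValueError("n and m must be 2-D and aligned")
        if self.n.shape[0] != len(self.gene_ids):
            raise ValueError("first axis must match gene_ids")
        if self.n.shape[1] != len(self.pair_labels):
            raise ValueError("second axis must match pair_labels")
        if np.any(self.n < 0) or np.any(self.m < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_pairs(cls, pairs: Sequence[GenePairCounts], labels=None):
        """Stack GenePairCounts sharing one gene ordering."""
        if not pairs:
            raise ValueError("need at least one pair")
        ref = pairs[0].gene_ids
        for p in pairs[1:]:
            if not np.array_equal(p.gene_ids, ref):
                raise ValueError("all pairs must share the same gene ordering")
        labels = list(labels) if labels is not None else [
            f"pair{j}" for j in range(len(pairs))
        ]
        return cls(
            gene_ids=ref.copy(),
            n=np.column_stack([p.n for p in pairs]),
            m=np.column_stack([p.m for p in pairs]),
            pair_labels=labels,
        )

    @property
    def N(self):
        return self.n + self.m

    @property
    def n_pairs(self):
        return self.n.shape[1]

    def pair(self, j: int) -> GenePairCounts:
        return GenePairCounts(self.gene_ids.copy(), self.n[:, j].copy(), self.m[:, j].copy())


@dataclass
class VarianceTable:
    """Per-gene empirical variance of the proportion versus mean depth."""

    gene_ids: np.ndarray
    mean_total: np.ndarray
    var_prop: np.ndarray

    def __post_init__(self):
        if np.any(self.var_prop < 0):
            raise ValueError("var_prop must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "mean_total": self.mean_total,
             "var_prop": self.var_prop}
        )


def _golden_max(f, lo, hi, iters):
    """Vectorized golden-section maximization of a unimodal f on [lo, hi].

    ``lo``/``hi`` are arrays (one bracket per element); ``f`` maps an array
    of abscissae to an array of objective values. One fresh evaluation per
    iteration; the bracket shrinks by the golden ratio each step.
    """
    lo = np.array(lo, dtype=float)
    hi = np.array(hi, dtype=float)
    h = hi - lo
    x1 = lo + _INVPHI2 * h
    x2 = lo + _INVPHI * h
    f1 = f(x1)
    f2 = f(x2)
    for _ in range(iters):
        keep_left = f1 >= f2
        hi = np.where(keep_left, x2, hi)
        lo = np.where(keep_left, lo, x1)
        h = hi - lo
        x1 = lo + _INVPHI2 * h
        x2 = lo + _INVPHI * h
        f_carry = np.where(keep_left, f1, f2)
        x_new = np.where(keep_left, x1, x2)
        f_new = f(x_new)
        f1 = np.where(keep_left, f_new, f_carry)
        f2 = np.where(keep_left, f_carry, f_new)
    return (lo + hi) / 2.0


def estimate_phat(n, m, theta, iters: int = 60):
    """The proportion maximizing the beta-binomial likelihood of a single
    observation (n, m) at fixed dispersion theta.

    Found by golden-section search on [P_EPS, 1 - P_EPS]; the beta-binomial
    log pmf is concave in p (differences of trigamma functions), so the
    search is exact up to bracket width. Coincides with n/(n+m) at
    theta = 0 and with 1/2 whenever n = m.
    """
    n_a = np.asarray(n, dtype=float)
    m_a = np.asarray(m, dtype=float)
    th_a = np.asarray(theta, dtype=float)
    if np.any(n_a + m_a < 1):
        raise ValueError("n + m must be >= 1")
    if np.any(th_a < 0):
        raise ValueError("theta must be >= 0")
    n_a, m_a, th_a = np.broadcast_arrays(n_a, m_a, th_a)
    lo = np.full(n_a.shape, P_EPS)
    hi = np.full(n_a.shape, 1.0 - P_EPS)
    out = _golden_max(lambda p: _bb_core(n_a, m_a, p, th_a), lo, hi, iters)
    return out if out.ndim else float(out)


def _logc(n, m):
    from scipy.special import gammaln

    return gammaln(n + m + 1.0) - gammaln(n + 1.0) - gammaln(m + 1.0)


def profile_loglik(
    data: ReplicatePairSet,
    gamma: float,
    d_bounds=( _D_LO, _D_HI ),
    d_iters: int = 40,
    p_iters: int = 35,
):
    """Profile log-likelihood at fixed gamma.

    For each gene, maximizes the summed beta-binomial log pmf over the
    shared proportion p_i and the dispersion scale D_i >= 0, with
    ``theta_ip = D_i / N_ip**gamma`` at each pair's own total. D_i is
    searched on a log scale with an explicit D_i = 0 (binomial) boundary
    check. Genes whose totals are zero in every pair carry no information
    and are excluded.

    Returns ``(loglik, D)``: the total over genes and pairs, and the
    per-gene argmax as a dict.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = np.asarray(data.n, dtype=float)
    m = np.asarray(data.m, dtype=float)
    N = n + m
    valid = N >= 1
    keep = valid.any(axis=1)
    n, m, N, valid = n[keep], m[keep], N[keep], valid[keep]
    if n.shape[0] == 0:
        raise InsufficientDataError("no gene has any observed tags")
    G = n.shape[0]
    Nf = np.where(valid, N, 1.0)
    depth_scale = Nf ** (-float(gamma))

    def gene_ll(D):
        """Summed log-likelihood per gene at vector D, p_i profiled out."""
        th = D[:, None] * depth_scale

        def over_p(p):
            ll = _bb_core(n, m, p[:, None], th)
            return np.where(valid, ll, 0.0).sum(axis=1)

        lo = np.full(G, P_EPS)
        hi = np.full(G, 1.0 - P_EPS)
        phat = _golden_max(over_p, lo, hi, p_iters)
        return over_p(phat)

    log_d = _golden_max(
        lambda x: gene_ll(np.exp(x)),
        np.full(G, math.log(d_bounds[0])),
        np.full(G, math.log(d_bounds[1])),
        d_iters,
    )
    d_hat = np.exp(log_d)
    ll_hat = gene_ll(d_hat)
    # boundary checks: exact binomial (D = 0) and the upper bracket edge
    ll_zero = gene_ll(np.zeros(G))
    ll_top = gene_ll(np.full(G, d_bounds[1]))
    d_best = np.where(ll_zero >= ll_hat, 0.0, d_hat)
    ll_best = np.maximum(ll_zero, ll_hat)
    d_best = np.where(ll_top > ll_best, d_bounds[1], d_best)
    ll_best = np.maximum(ll_best, ll_top)

    const = np.where(valid, _logc(n, m), 0.0).sum()
    total = float(ll_best.sum() + const)
    D = dict(zip(data.gene_ids[keep], d_best))
    return total, D


def fit_overdispersion(
    data: ReplicatePairSet, gamma_grid=None, **profile_kwargs
) -> OverdispersionModel:
    """Grid profile MLE of the depth exponent gamma.

    Evaluates :func:`profile_loglik` on each grid value (default 0 to 1.2
    in steps of 0.1) and returns the model at the grid argmax together
    with the whole profile curve.
    """
    grid = DEFAULT_GAMMA_GRID if gamma_grid is None else tuple(gamma_grid)
    if len(grid) == 0:
        raise ValueError("gamma grid must be non-empty")
    if any(g < 0 for g in grid):
        raise ValueError("gamma grid values must be >= 0")
    curve = []
    best = None
    for g in grid:
        ll, D = profile_loglik(data, g, **profile_kwargs)
        curve.append((float(g), ll))
        if best is None or ll > best[1]:
            best = (float(g), ll, D)
    gamma_hat, loglik, D = best
    return OverdispersionModel(gamma=gamma_hat, D=D, loglik=loglik, gamma_grid=curve)


def lrt_pvalue(n, m, theta, p_n, iters: int = 60):
    """Likelihood-ratio p-value of one observation against the neutral ratio.

    ``Lambda = 2 [l(p_hat) - l(p_n)]`` referred to the upper tail of a
    chi-squared distribution with 1 degree of freedom.
    """
    pn_a = np.asarray(p_n, dtype=float)
    if np.any(pn_a <= 0) or np.any(pn_a >= 1):
        raise ValueError("p_n must lie in (0, 1)")
    n_a = np.asarray(n, dtype=float)
    m_a = np.asarray(m, dtype=float)
    th_a = np.asarray(theta, dtype=float)
    n_a, m_a, th_a, pn_a = np.broadcast_arrays(n_a, m_a, th_a, pn_a)
    phat = estimate_phat(n_a, m_a, th_a, iters=iters)
    lam = 2.0 * (_bb_core(n_a, m_a, phat, th_a) - _bb_core(n_a, m_a, pn_a, th_a))
    lam = np.maximum(lam, 0.0)
    out = stats.chi2.sf(lam, df=1)
    return out if out.ndim else float(out)


def fold_change(p_i, p_n):
    """Odds-ratio fold change calibrated against the neutral ratio:
    ``FC = [p/(1-p)] * [(1-p_n)/p_n]``; FC = 1 iff p_i = p_n.

    Boundary proportions are a domain error — apply pseudo-counts first
    (:func:`fold_change_counts`).
    """
    p_a = np.asarray(p_i, dtype=float)
    pn_a = np.asarray(p_n, dtype=float)
    if np.any(p_a <= 0) or np.any(p_a >= 1):
        raise ValueError("p_i must lie strictly inside (0, 1); add pseudo-counts")
    if np.any(pn_a <= 0) or np.any(pn_a >= 1):
        raise ValueError("p_n must lie in (0, 1)")
    out = (p_a / (1.0 - p_a)) * ((1.0 - pn_a) / pn_a)
    return out if out.ndim else float(out)


def fold_change_counts(n, m, p_n, pseudo: float = 0.5):
    """Fold change from raw counts with a pseudo-count on both sides,
    guaranteeing a finite positive value."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    n_a = np.asarray(n, dtype=float)
    m_a = np.asarray(m, dtype=float)
    p = (n_a + pseudo) / (n_a + m_a + 2.0 * pseudo)
    return fold_change(p, p_n)


def variance_table(
    data: ReplicatePairSet, p_n: float, min_total: int = 1
) -> VarianceTable:
    """Empirical variance of the proportion around the neutral ratio.

    Per gene: ``var_prop`` is the mean over pairs of ``(p_ip - p_n)**2``
    and ``mean_total`` the mean of ``N_ip``, using pairs with at least one
    tag; genes with mean total below ``min_total`` are excluded.
    """
    if not (0.0 < p_n < 1.0):
        raise ValueError("p_n must lie in (0, 1)")
    n = np.asarray(data.n, dtype=float)
    m = np.asarray(data.m, dtype=float)
    N = n + m
    valid = N >= 1
    npairs = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, n / np.where(valid, N, 1.0), np.nan)
        dev2 = np.where(valid, (p - p_n) ** 2, 0.0)
        var_prop = dev2.sum(axis=1) / np.maximum(npairs, 1)
        mean_total = np.where(valid, N, 0.0).sum(axis=1) / np.maximum(npairs, 1)
    keep = (npairs > 0) & (mean_total >= min_total)
    return VarianceTable(
        gene_ids=data.gene_ids[keep],
        mean_total=mean_total[keep],
        var_prop=var_prop[keep],
    )


def slope_gamma(
    vt: VarianceTable, min_mean: float = 100.0, min_genes: int = 20
) -> float:
    """Depth exponent from the log-log variance-vs-depth slope.

    Ordinary least squares of log10(var_prop) on log10(mean_total)
    restricted to genes with mean total above ``min_mean`` (default 100
    tags); returns ``-slope``. A pure binomial gives slope -1.
    """
    mask = (vt.mean_total > min_mean) & (vt.var_prop > 0)
    if mask.sum() < min_genes:
        raise InsufficientDataError(
            f"need >= {min_genes} genes with mean total > {min_mean}"
        )
    fit = stats.linregress(
        np.log10(vt.mean_total[mask]), np.log10(vt.var_prop[mask])
    )
    return -float(fit.slope)


def ttest_gold(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_count: int = 20,
    fc_rule: Optional[float] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gold-standard differential-expression calls by per-gene t-test.

    Expression is log2(RPKM + 1) when gene lengths are available, else
    log2(counts-per-million + 1). Genes with no more than ``min_count``
    total tags across the used runs are excluded. With ``fc_rule`` unset,
    a gene is called DE when its Benjamini-Hochberg adjusted p-value is
    below ``alpha``; with ``fc_rule`` set (e.g. 2.0), when the raw p-value
    is below ``alpha`` and the fold change exceeds the rule in either
    direction.

    Returns a DataFrame indexed by gene id with columns
    ``p_raw, p_adj, log2fc, is_de``.
    """
    from statsmodels.stats.multitest import multipletests

    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigurationError("each group needs >= 2 runs for a t-test")
    ia = [cm.run_index(r) for r in group_a]
    ib = [cm.run_index(r) for r in group_b]

    if cm.lengths is not None:
        from .normalization import rpkm_values

        expr = np.column_stack(
            [rpkm_values(cm, r).to_numpy() for r in list(group_a) + list(group_b)]
        )
    else:
        used = cm.counts[:, ia + ib].astype(float)
        totals = used.sum(axis=0)
        expr = used / (totals / 1e6)
    expr = np.log2(expr + 1.0)
    xa = expr[:, : len(ia)]
    xb = expr[:, len(ia):]

    total_tags = cm.counts[:, ia + ib].sum(axis=1)
    keep = total_tags > min_count

    with np.errstate(invalid="ignore", divide="ignore"):
        tres = stats.ttest_ind(xa[keep], xb[keep], axis=1, equal_var=True)
    p_raw = np.where(np.isfinite(tres.pvalue), tres.pvalue, 1.0)
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if keep.any() else p_raw
    log2fc = xa[keep].mean(axis=1) - xb[keep].mean(axis=1)
    if fc_rule is None:
        is_de = p_adj < alpha
    else:
        is_de = (p_raw < alpha) & (np.abs(log2fc) > np.log2(fc_rule))
    return pd.DataFrame(
        {"p_raw": p_raw, "p_adj": p_adj, "log2fc": log2fc, "is_de": is_de},
        index=pd.Index(cm.gene_ids[keep], name="gene_id"),
    )


def test_genes(
    pair: GenePairCounts,
    p_n: float,
    method: str = "betabinom",
    model: Optional[OverdispersionModel] = None,
    pseudo: float = 0.5,
    min_count: int = 20,
) -> list:
    """Per-gene differential-expression calls for one A-vs-B comparison.

    ``method='binomial'`` uses the exact two-sided binomial test against
    the neutral ratio; ``method='betabinom'`` the likelihood-ratio test
    with ``theta_i = D_i / N_i**gamma`` from a fitted model (genes absent
    from the model fall back to D_i = 0). Genes with zero total are
    dropped; ``passed_min_count`` flags totals above ``min_count``.
    Pseudo-counts enter only the reported proportion and fold change,
    never the likelihoods.
    """
    if not (0.0 < p_n < 1.0):
        raise ValueError("p_n must lie in (0, 1)")
    if method not in ("binomial", "betabinom"):
        raise ValueError("method must be 'binomial' or 'betabinom'")
    mask = pair.N >= 1
    genes = pair.gene_ids[mask]
    n = pair.n[mask]
    m = pair.m[mask]
    N = n + m
    p_hat = (n + pseudo) / (N + 2.0 * pseudo)
    fc = fold_change(p_hat, p_n)
    if method == "binomial":
        pvals = np.atleast_1d(binomial_test(n, m, p_n))
    else:
        if model is None:
            raise ConfigurationError("betabinom testing requires a fitted model")
        th = model.theta_array(genes, N)
        pvals = np.atleast_1d(lrt_pvalue(n, m, th, p_n))
    return [
        GeneResultRow(
            gene_id=str(g),
            n=int(ni),
            m=int(mi),
            p_hat=float(ph),
            fold_change=float(f),
            p_value=float(pv),
            method=method,
            passed_min_count=bool(Ni > min_count),
        )
        for g, ni, mi, ph, f, pv, Ni in zip(genes, n, m, p_hat, fc, pvals, N)
    ]
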