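"""Neutral-ratio normalization for two-library comparisons.

Comparing libraries A and B through per-gene proportions
``p_i = n_i/(n_i + m_i)`` requires a *neutral ratio* ``p_n``: the
proportion at which a gene is considered equally expressed in both
libraries. Two estimators are provided.

peak
    Assumes most genes are unchanged, so the tallest peak of the
    proportion histogram marks the neutral ratio. A scaled beta density
    is least-squares fitted to the binned density in a window around the
    tallest bin; ``p_n`` is the mode of the fitted beta. A Gaussian fit
    to the same window is the fallback when the beta fit fails.

rpkm
    Assumes total mapped tags are proportional to total RNA, giving
    ``p_n = N/(N + M)`` from the two column totals — the proportion-scale
    equivalent of comparing RPKM values directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import CountMatrix, GenePairCounts
from .errors import ConfigurationError, DegenerateInputError, FitError, InsufficientDataError

__all__ = [
    "HistogramSpec",
    "NormalizationResult",
    "proportions",
    "peak_normalize",
    "rpkm_neutral",
    "rpkm_values",
    "median_log2_ratio",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning and fit-window choices for peak normalization.

    bin_width: histogram bin width on (0, 1).
    min_count: genes need at least this many total tags to enter the
        histogram (low-count proportions are too noisy to define a peak).
    fit_halfwidth: the beta fit uses bins within this distance of the
        tallest bin's center.
    """

    bin_width: float = 0.01
    min_count: int = 20
    fit_halfwidth: float = 0.15

    def __post_init__(self):
        if not (0 < self.bin_width < 0.5):
            raise ValueError("bin_width must lie in (0, 0.5)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not (self.bin_width <= self.fit_halfwidth <= 0.5):
            raise ValueError("fit_halfwidth out of range")


@dataclass
class NormalizationResult:
    """A neutral ratio together with the fit that produced it."""

    method: str  # "peak" or "rpkm"
    p_n: float
    beta_a: Optional[float] = None
    beta_b: Optional[float] = None
    fit_kind: Optional[str] = None  # "beta" or "gaussian" (peak method)
    histogram_spec: Optional[HistogramSpec] = None
    n_genes_used: int = 0
    bin_centers: Optional[np.ndarray] = field(default=None, repr=False)
    density: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.method not in ("peak", "rpkm"):
            raise ValueError("method must be 'peak' or 'rpkm'")
        if not (0.0 < self.p_n < 1.0):
            raise ValueError("p_n must lie in (0, 1)")
        if self.fit_kind == "beta":
            mode = (self.beta_a - 1.0) / (self.beta_a + self.beta_b - 2.0)
            if abs(mode - self.p_n) > 1e-12:
                raise ValueError("p_n must equal the fitted beta mode")


def proportions(pair: GenePairCounts, min_count: int = 1) -> pd.Series:
    """Per-gene proportions ``p_i = n_i/N_i`` for genes with
    ``N_i >= min_count``; other genes are omitted."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    N = pair.N
    keep = N >= min_count
    return pd.Series(
        pair.n[keep] / N[keep],
        index=pd.Index(pair.gene_ids[keep], name="gene_id"),
        name="p",
    )


def _beta_mode(a, b):
    return (a - 1.0) / (a + b - 2.0)


def peak_normalize(props, spec: HistogramSpec | None = None) -> NormalizationResult:
    """Neutral ratio from the tallest peak of the proportion histogram.

    ``props`` is a mapping/array of per-gene proportions (already filtered
    for minimum count, e.g. via :func:`proportions`). At least 100
    proportions are required — a histogram peak is meaningless below that.
    """
    spec = spec or HistogramSpec()
    x = np.asarray(
        props.to_numpy() if isinstance(props, pd.Series) else list(props)
        if isinstance(props, dict) else props,
        dtype=float,
    )
    if isinstance(props, dict):
        x = np.asarray(list(props.values()), dtype=float)
    if x.size < 100:
        raise InsufficientDataError(
            f"peak normalization needs >= 100 proportions, got {x.size}"
        )
    edges = np.arange(0.0, 1.0 + spec.bin_width / 2, spec.bin_width)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    density = counts / (x.size * spec.bin_width)

    peak_center = centers[int(np.argmax(counts))]
    window = np.abs(centers - peak_center) <= spec.fit_halfwidth
    cw, dw = centers[window], density[window]

    # moment-based start values from the raw proportions inside the window;
    # sorted so the fit is exactly invariant under gene reordering
    xw = np.sort(x[np.abs(x - peak_center) <= spec.fit_halfwidth])
    mu = float(np.mean(xw))
    var = float(np.var(xw)) or spec.bin_width**2
    kappa = max(mu * (1.0 - mu) / var - 1.0, 2.5)
    a0 = max(mu * kappa, 1.01)
    b0 = max((1.0 - mu) * kappa, 1.01)

    p_n = beta_a = beta_b = None
    fit_kind = None
    try:
        popt, _ = optimize.curve_fit(
            lambda t, s, a, b: s * stats.beta.pdf(t, a, b),
            cw,
            dw,
            p0=[1.0, a0, b0],
            bounds=([1e-9, 1.0 + 1e-6, 1.0 + 1e-6], [1e9, 1e6, 1e6]),
            maxfev=20000,
        )
        _, beta_a, beta_b = (float(v) for v in popt)
        cand = _beta_mode(beta_a, beta_b)
        if 0.0 < cand < 1.0:
            p_n, fit_kind = cand, "beta"
    except (RuntimeError, ValueError):
        pass

    if p_n is None:
        # Gaussian fallback on the same window
        try:
            popt, _ = optimize.curve_fit(
                lambda t, s, loc, sig: s * np.exp(-0.5 * ((t - loc) / sig) ** 2),
                cw,
                dw,
                p0=[float(dw.max()), peak_center, max(np.std(xw), spec.bin_width)],
                bounds=([1e-9, 1e-6, 1e-4], [1e9, 1.0 - 1e-6, 1.0]),
                maxfev=20000,
            )
            p_n, fit_kind = float(popt[1]), "gaussian"
            beta_a = beta_b = None
        except (RuntimeError, ValueError):
            raise FitError(
                "histogram peak fit did not converge",
                bin_centers=centers,
                density=density,
            ) from None

    return NormalizationResult(
        method="peak",
        p_n=p_n,
        beta_a=beta_a,
        beta_b=beta_b,
        fit_kind=fit_kind,
        histogram_spec=spec,
        n_genes_used=int(x.size),
        bin_centers=centers,
        density=density,
    )


def rpkm_neutral(pair: GenePairCounts) -> NormalizationResult:
    """Neutral ratio implied by total-count (RPKM-style) normalization:
    ``p_n = N/(N + M)`` with N, M the two column totals."""
    N = int(pair.n.sum())
    M = int(pair.m.sum())
    if N == 0 or M == 0:
        raise DegenerateInputError("both libraries need a positive total")
    return NormalizationResult(
        method="rpkm", p_n=N / (N + M), n_genes_used=len(pair.gene_ids)
    )


def rpkm_values(cm: CountMatrix, run: str) -> pd.Series:
    """Reads per kilobase of gene length per million mapped tags for one run:
    ``count / (total/1e6) / (length/1e3)``."""
    if cm.lengths is None:
        raise ConfigurationError("RPKM requires gene lengths")
    j = cm.run_index(run)
    total = cm.counts[:, j].sum()
    if total == 0:
        raise DegenerateInputError(f"run {run!r} has zero total tags")
    vals = cm.counts[:, j] / (total / 1e6) / (cm.lengths / 1e3)
    return pd.Series(vals, index=pd.Index(cm.gene_ids, name="gene_id"), name="rpkm")


def median_log2_ratio(
    pair: GenePairCounts, p_n: float, min_count: int = 20, pseudo: float = 0.5
) -> float:
    """Median over qualifying genes of the base-2 log fold change under the
    given neutral ratio — a scalar summary of how well the normalization
    centers the comparison (0 means perfectly centered)."""
    from .inference import fold_change_counts

    keep = pair.N >= min_count
    if not keep.any():
        return 0.0
    fc = fold_change_counts(pair.n[keep], pair.m[keep], p_n, pseudo=pseudo)
    return float(np.median(np.log2(fc)))
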