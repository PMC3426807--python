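"""Method evaluation: empirical FDR from same-sample nulls, ROC against a
gold standard, p-value calibration diagnostics, and top-k overlap.

The empirical FDR protocol treats every gene called differentially
expressed between two replicates of the *same* biological sample as a
false discovery: at the p-value threshold that yields k discoveries in
the real sample-vs-control comparison, the FDR estimate is the number of
null-comparison genes below that threshold divided by k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "EvaluationCurves",
    "empirical_fdr",
    "roc",
    "roc_auc",
    "pvalue_calibration",
    "top_k_overlap",
]


@dataclass
class EvaluationCurves:
    """Bundle of evaluation outputs for one method comparison."""

    fdr_curve: pd.DataFrame
    roc: Optional[pd.DataFrame] = None
    overlap: Optional[dict] = None
    k_top: int = 300


def _values(x):
    if isinstance(x, pd.Series):
        return x.to_numpy(dtype=float)
    if isinstance(x, Mapping):
        return np.asarray(list(x.values()), dtype=float)
    return np.asarray(x, dtype=float)


def empirical_fdr(null_pvals, test_pvals, k_max: int = 1000) -> pd.DataFrame:
    """Empirical FDR curve from a same-sample null comparison.

    For each k, the threshold is the k-th smallest test p-value and
    ``FDR(k) = #{null p <= threshold} / k`` capped at 1. Both inputs must
    come from the same method and normalization.

    Returns a DataFrame with columns ``k`` (1..min(k_max, #test)) and
    ``fdr``.
    """
    null_p = np.sort(_values(null_pvals))
    test_p = np.sort(_values(test_pvals))
    if null_p.size == 0 or test_p.size == 0:
        raise InsufficientDataError("both p-value sets must be non-empty")
    ks = np.arange(1, min(k_max, test_p.size) + 1)
    thresholds = test_p[ks - 1]
    false = np.searchsorted(null_p, thresholds, side="right")
    fdr = np.minimum(false / ks, 1.0)
    return pd.DataFrame({"k": ks, "fdr": fdr})


def roc(scores, gold) -> pd.DataFrame:
    """ROC curve by sweeping a threshold over a ranking statistic.

    Larger scores rank a gene as more confidently differentially
    expressed. Tied scores are grouped into a single point. The curve
    starts at (0, 0) and ends at (1, 1). When both arguments are
    mappings/Series they are aligned on gene id first.
    """
    if isinstance(scores, (pd.Series, Mapping)) and isinstance(gold, (pd.Series, Mapping)):
        s = pd.Series(dict(scores) if isinstance(scores, Mapping) and not isinstance(scores, pd.Series) else scores)
        g = pd.Series(dict(gold) if isinstance(gold, Mapping) and not isinstance(gold, pd.Series) else gold)
        g = g.loc[s.index]
        score_arr = s.to_numpy(dtype=float)
        gold_arr = g.to_numpy(dtype=bool)
    else:
        score_arr = np.asarray(scores, dtype=float)
        gold_arr = np.asarray(gold, dtype=bool)
    pos = int(gold_arr.sum())
    neg = int(gold_arr.size - pos)
    if pos == 0 or neg == 0:
        raise DegenerateInputError("gold standard needs >= 1 positive and >= 1 negative")
    order = np.argsort(-score_arr, kind="mergesort")
    sorted_scores = score_arr[order]
    tp = np.cumsum(gold_arr[order])
    fp = np.cumsum(~gold_arr[order])
    # keep the last index of each tie block
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[last] / pos]
    fpr = np.r_[0.0, fp[last] / neg]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_auc(scores, gold) -> float:
    """Area under the ROC curve (trapezoid over the tie-grouped points;
    equals the Mann-Whitney probability of correct ranking)."""
    curve = roc(scores, gold)
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


def pvalue_calibration(pvals) -> dict:
    """Uniformity diagnostics for a set of p-values.

    Returns the one-sample Kolmogorov-Smirnov statistic and p-value
    against Uniform(0, 1) plus the fraction of p-values below 0.05. On a
    correctly specified null the histogram is flat and the fraction is
    about 0.05; overdispersion ignored by the test inflates it.
    """
    p = _values(pvals)
    if p.size < 100:
        raise InsufficientDataError("need >= 100 p-values for calibration")
    ks = stats.kstest(p, "uniform")
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "frac_below_005": float(np.mean(p < 0.05)),
    }


def _top_k(rank: Mapping, k: int) -> set:
    items = sorted(rank.items(), key=lambda kv: (kv[1], kv[0]))
    return {g for g, _ in items[:k]}


def top_k_overlap(rank_a, rank_b, rank_c, k: int = 300) -> dict:
    """Region counts of the three top-k gene sets (Venn regions).

    ``rank_*`` map gene id to p-value over a common universe; ties at the
    k-th p-value break by gene id so results are reproducible. Keys of
    the returned dict name exclusive regions: ``a``, ``b``, ``c``,
    ``ab``, ``ac``, ``bc``, ``abc``.
    """
    maps = []
    for r in (rank_a, rank_b, rank_c):
        maps.append(dict(r) if not isinstance(r, pd.Series) else r.to_dict())
    universe = set(maps[0])
    if set(maps[1]) != universe or set(maps[2]) != universe:
        raise ValueError("rankings must share one gene universe")
    if k > len(universe):
        raise ValueError(f"k = {k} exceeds the {len(universe)}-gene universe")
    A, B, C = (_top_k(m, k) for m in maps)
    return {
        "a": len(A - B - C),
        "b": len(B - A - C),
        "c": len(C - A - B),
        "ab": len((A & B) - C),
        "ac": len((A & C) - B),
        "bc": len((B & C) - A),
        "abc": len(A & B & C),
    }
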