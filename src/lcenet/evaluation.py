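"""Diagnostic, prognostic and co-expression evaluation of selected features.

ROC/AUC for tumor-versus-normal discrimination, Kaplan-Meier curves with a
log-rank test after an expression-percentile split (median split by default,
mirroring the OncoLnc web tool's stratification), pairwise Pearson
correlation on non-log expression values, and a generic hypergeometric
over-representation test for user-supplied gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import pearsonr
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .stats import bh_adjust, hypergeometric_tail

log = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "KmResult",
    "OraResult",
    "roc_auc",
    "km_logrank",
    "correlate_pair",
    "gene_set_ora",
]


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class KmResult:
    strata: pd.Series  # sample -> 'high' / 'low'
    curves: dict  # stratum -> DataFrame(time, survival)
    statistic: float
    p_value: float


@dataclass
class OraResult:
    name: str
    overlap: int
    set_size: int
    universe_size: int
    query_size: int
    p_value: float
    adj_p: float = np.nan


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for a binary tumor/normal discrimination.

    The AUC equals the rank (Mann-Whitney) statistic; ties are handled by
    midrank, so a constant score gives 0.5.  Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(float(_trapezoid_auc(fpr, tpr)), fpr, tpr)


def km_logrank(
    records: pd.DataFrame,
    upper_fraction: float = 0.5,
    lower_fraction: float = 0.5,
) -> KmResult:
    """Kaplan-Meier curves and log-rank test after an expression split.

    ``records`` has columns time, event, expression (indexed by sample).  The
    high stratum is the top ``floor(upper_fraction * n)`` samples by
    expression, the low stratum the bottom ``floor(lower_fraction * n)``;
    with the default 50/50 this is a median split (odd middle sample goes to
    neither).  Ties in expression are broken by sample order for a
    deterministic assignment.  The p-value is undefined (NaN) when no events
    are observed.
    """
    if upper_fraction + lower_fraction > 1 + 1e-9:
        raise ValueError("upper_fraction + lower_fraction must be <= 1")
    n = len(records)
    order = records["expression"].to_numpy().argsort(kind="stable")
    n_low = int(np.floor(lower_fraction * n))
    n_high = int(np.floor(upper_fraction * n))
    if n_low < 2 or n_high < 2:
        raise ValueError("need >= 2 records per stratum after the split")
    strata = pd.Series("mid", index=records.index, name="stratum")
    strata.iloc[order[:n_low]] = "low"
    strata.iloc[order[n - n_high:]] = "high"
    curves = {}
    for name in ("high", "low"):
        sub = records[strata == name]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    hi = records[strata == "high"]
    lo = records[strata == "low"]
    if hi["event"].sum() + lo["event"].sum() == 0:
        return KmResult(strata, curves, np.nan, np.nan)
    res = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
    return KmResult(strata, curves, float(res.test_statistic), float(res.p_value))


def correlate_pair(x, y) -> tuple[float, float]:
    """Pearson R and two-sided P on untransformed expression values.

    Returns ``(nan, nan)`` for a zero-variance vector (undefined rather than
    an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan)
    r, p = pearsonr(x, y)
    return float(r), float(p)


def gene_set_ora(
    query: set,
    universe: set,
    gene_sets: dict,
    alpha: float = 0.05,
    top_k: int = 5,
) -> list:
    """Hypergeometric over-representation of a query set in named gene sets.

    Each set is intersected with the universe; the P-value is the upper tail
    of drawing the observed overlap when sampling ``|query|`` genes from the
    universe, BH-corrected across sets.  Returns all results sorted by
    adjusted P, with the ``top_k`` most enriched first (callers typically
    display only those with ``adj_p < alpha``).
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = len(members & query)
        p = hypergeometric_tail(len(universe), len(members), len(query), overlap)
        results.append(OraResult(name, overlap, len(members), len(universe), len(query), p))
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (r.adj_p, r.p_value, r.name))
    for r in results[:top_k]:
        log.info("ORA %s: overlap %d/%d, adj_p=%.3g", r.name, r.overlap, r.set_size, r.adj_p)
    return results
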