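"""Shared statistical primitives.

The competition test at the heart of the pipeline asks: if ``n_lnc`` of the
``n_total`` miRNAs in the background regulate a lncRNA and ``n_mrna`` regulate
an mRNA, how surprising is it that ``x`` or more miRNAs regulate both?  The
answer is the upper tail of a hypergeometric distribution; the same primitive
is reused for gene-set over-representation analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeometric_tail", "bh_adjust"]


def hypergeometric_tail(n_total: int, n_lnc: int, n_mrna: int, x: int) -> float:
    """Upper-tail probability P(X >= x) of sharing ``x`` regulators by chance.

    X follows a hypergeometric law with population ``n_total`` (background
    miRNAs), ``n_lnc`` marked elements (miRNAs regulating the lncRNA) and
    ``n_mrna`` draws (miRNAs regulating the mRNA).  The two marked/draw roles
    are exchangeable.

    Parameters
    ----------
    n_total
        Background number of miRNAs (``N_T``), positive.
    n_lnc, n_mrna
        Number of miRNAs regulating each partner; both in ``[0, n_total]``.
    x
        Observed shared-miRNA count, in ``[0, min(n_lnc, n_mrna)]``.

    Returns
    -------
    float
        ``P(X >= x)``, clipped to ``[0, 1]``.  ``x = 0`` gives exactly 1.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_lnc <= n_total and 0 <= n_mrna <= n_total):
        raise ValueError(
            f"n_lnc={n_lnc}, n_mrna={n_mrna} must lie in [0, n_total={n_total}]"
        )
    if not (0 <= x <= min(n_lnc, n_mrna)):
        raise ValueError(
            f"x={x} outside [0, min(n_lnc={n_lnc}, n_mrna={n_mrna})]"
        )
    if x == 0:
        return 1.0
    # sf(x-1) = P(X >= x); scipy computes this in a numerically stable way.
    p = float(hypergeom.sf(x - 1, n_total, n_lnc, n_mrna))
    return min(1.0, max(0.0, p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order.

    Standard step-up with cumulative-min monotonicity enforcement and clipping
    at 1.  Raises ``ValueError`` on values outside ``[0, 1]``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
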