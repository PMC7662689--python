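"""Context-specific ceRNA networks.

A context network for a contrast (e.g. colon M0 vs normal) is built in two
steps: triplets of the global network whose lncRNA, miRNA and mRNA are all
differentially expressed in that contrast are extracted, then lncRNA-mRNA
pairs whose expression is not significantly positively correlated across the
contrast's tumor samples (Pearson R > 0.5, P < 0.05) are removed.  The
resulting tripartite graph is summarized by node degrees, hub membership
(top 5% by degree) and a log-log power-law fit of the degree distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

log = logging.getLogger(__name__)

__all__ = [
    "ContextLceNET",
    "PowerLawFit",
    "extract_context_candidates",
    "pearson_filter",
    "topology_report",
    "powerlaw_fit",
    "shared_interactions",
]


@dataclass
class ContextLceNET:
    """Tripartite lncRNA-miRNA-mRNA network for one contrast."""

    label: str
    triplets: list = field(default_factory=list)  # (lncrna, mirna, mrna)
    pair_stats: pd.DataFrame | None = None  # lncrna, mrna, x, r, p

    @property
    def edges(self) -> set:
        """Distinct (miRNA, target) edges of the tripartite edge list."""
        out = set()
        for l, m, a in self.triplets:
            out.add((m, l))
            out.add((m, a))
        return out

    def nodes_by_class(self) -> dict:
        lncs = {t[0] for t in self.triplets}
        mirs = {t[1] for t in self.triplets}
        mrnas = {t[2] for t in self.triplets}
        return {"lncRNA": lncs, "miRNA": mirs, "mRNA": mrnas}

    def degrees(self) -> dict:
        deg: dict = {}
        for m, t in self.edges:
            deg[m] = deg.get(m, 0) + 1
            deg[t] = deg.get(t, 0) + 1
        return deg


@dataclass
class PowerLawFit:
    """Least-squares line on (log10 degree, log10 frequency) points."""

    slope: float
    intercept: float
    r_squared: float
    points: list  # (degree, frequency)
    defined: bool = True


def extract_context_candidates(global_triplets, de_sets: dict) -> list:
    """Triplets whose three members are all differentially expressed.

    ``de_sets`` maps class name ('lncRNA', 'miRNA', 'mRNA') to the contrast's
    significant feature ids.  An empty DE set in any class yields an empty
    candidate list (with a log warning).
    """
    lnc = de_sets.get("lncRNA", set())
    mir = de_sets.get("miRNA", set())
    mrna = de_sets.get("mRNA", set())
    if not (lnc and mir and mrna):
        log.warning("empty DE set in at least one class; no candidate triplets")
        return []
    return [t for t in global_triplets if t[0] in lnc and t[1] in mir and t[2] in mrna]


def pearson_filter(
    candidates: list,
    expression: pd.DataFrame,
    label: str = "",
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> ContextLceNET:
    """Keep triplets whose lncRNA-mRNA pair is positively co-expressed.

    ``expression`` holds (non-log) expression values, features x tumor samples
    of the contrast.  Pearson R and its two-sided t-based P are computed once
    per distinct pair; pairs failing R > r_min and P < p_max drop with all
    their triplets.  Pairs with a zero-variance member are skipped (R
    undefined) and logged.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 tumor samples for the correlation filter")
    pairs: dict = {}
    for l, m, a in candidates:
        pairs.setdefault((l, a), set()).add(m)
    rows = []
    kept_pairs = set()
    for (l, a), mirs in sorted(pairs.items()):
        x = expression.loc[l].to_numpy(dtype=float)
        y = expression.loc[a].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.warning("zero-variance expression for pair (%s, %s); skipped", l, a)
            rows.append((l, a, len(mirs), np.nan, np.nan, False))
            continue
        r, p = pearsonr(x, y)
        ok = (r > r_min) and (p < p_max)
        rows.append((l, a, len(mirs), float(r), float(p), bool(ok)))
        if ok:
            kept_pairs.add((l, a))
    net = ContextLceNET(
        label,
        [t for t in candidates if (t[0], t[2]) in kept_pairs],
        pd.DataFrame(rows, columns=["lncrna", "mrna", "x", "r", "p", "kept"]),
    )
    log.info("%s: %d/%d pairs pass the correlation filter", label, len(kept_pairs), len(pairs))
    return net


def topology_report(net: ContextLceNET, hub_fraction: float = 0.05):
    """Node table with degree and hub flag, plus a power-law degree fit.

    Hubs are the top ``ceil(hub_fraction * n_nodes)`` nodes by degree, ties
    broken lexicographically by node id.  The fit regresses log10 frequency on
    log10 degree over distinct observed degrees; it is undefined (flagged)
    with fewer than three distinct degrees.
    """
    if not net.triplets:
        raise ValueError("empty network")
    deg = net.degrees()
    classes = net.nodes_by_class()
    cls_of = {n: c for c, ns in classes.items() for n in ns}
    n_hubs = math.ceil(hub_fraction * len(deg))
    ranked = sorted(deg, key=lambda n: (-deg[n], n))
    hubs = set(ranked[:n_hubs])
    node_table = pd.DataFrame(
        [(n, cls_of[n], deg[n], n in hubs) for n in ranked],
        columns=["node", "class", "degree", "is_hub"],
    )
    return node_table, hubs, powerlaw_fit(list(deg.values()))


def powerlaw_fit(degree_values) -> PowerLawFit:
    """Fit log10 frequency ~ log10 degree over distinct observed degrees.

    Undefined (flagged) with fewer than three distinct degrees.
    """
    values, counts = np.unique(np.asarray(degree_values, dtype=float),
                               return_counts=True)
    points = list(zip(values.tolist(), counts.tolist()))
    if len(values) < 3:
        return PowerLawFit(np.nan, np.nan, np.nan, points, defined=False)
    res = linregress(np.log10(values), np.log10(counts))
    return PowerLawFit(float(res.slope), float(res.intercept),
                       float(res.rvalue**2), points)


def shared_interactions(nets: list) -> set:
    """Triplets present in every provided context network."""
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    sets = [set(n.triplets) for n in nets]
    return set.intersection(*sets)
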