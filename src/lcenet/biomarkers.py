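"""NSM / NSR biomarker model and key-triplet screening.

Two network statistics drive biomarker selection in a context network:

* NSM ("number of shared miRNAs") scores each lncRNA by the shared-miRNA
  counts of its competing lncRNA-mRNA pairs; a lncRNA whose NSM values are
  significantly higher than the pooled pair-level values of the whole network
  (one-sided rank-sum, P < 0.05) is a lncRNA biomarker — a strong competitor
  for the miRNA pool.

* NSR ("number of single-line regulated RNAs") scores each miRNA by how many
  of its targets have no other miRNA regulator in the network.  Single-line
  regulation is a vulnerable control point; miRNAs with NSR above the network
  mean and a significant one-sided rank-sum on their per-target single-line
  indicators are miRNA biomarkers.

Key triplets combine both biomarker sets with expression-direction opposition
(miRNA opposite to both partners) and a tumor-associated-gene or prognosis
annotation on the mRNA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .context import ContextLceNET

log = logging.getLogger(__name__)

__all__ = [
    "NSMProfile",
    "NSRProfile",
    "TripletCandidate",
    "compute_nsm_profiles",
    "select_lncrna_biomarkers",
    "compute_nsr_profiles",
    "select_mirna_biomarkers",
    "screen_key_triplets",
]


def _ranksum_greater(values, background) -> float:
    """One-sided rank-sum P(values stochastically greater than background)."""
    values = np.asarray(values, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(set(values.tolist()) | set(background.tolist())) == 1:
        return 1.0  # everything tied: no evidence either way
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            mannwhitneyu(values, background, alternative="greater",
                         method="asymptotic").pvalue
        )


@dataclass
class NSMProfile:
    lncrna_id: str
    pair_nsm_values: list  # shared-miRNA count per competing pair
    test_p: float
    degenerate: bool = False


@dataclass
class NSRProfile:
    mirna_id: str
    nsr: int
    n_targets: int
    passes_mean: bool
    test_p: float


@dataclass
class TripletCandidate:
    lncrna: str
    mirna: str
    mrna: str
    directions: dict  # id -> 'up' / 'down'
    mrna_is_tag: bool
    mrna_prognosis: bool


def _pair_nsm(net: ContextLceNET) -> dict:
    """Map lncRNA -> list of shared-miRNA counts of its pairs in the network."""
    pairs: dict = {}
    for l, m, a in net.triplets:
        pairs.setdefault((l, a), set()).add(m)
    by_lnc: dict = {}
    for (l, a), mirs in sorted(pairs.items()):
        by_lnc.setdefault(l, []).append(len(mirs))
    return by_lnc


def compute_nsm_profiles(net: ContextLceNET, include_self: bool = True) -> dict:
    """NSM profile per lncRNA, tested against the pooled pair values.

    The background is the pair-level NSM values of the whole context network;
    by default it includes the focal lncRNA's own pairs (set
    ``include_self=False`` to exclude them).  A network with a single lncRNA
    gives a degenerate self-comparison, flagged on the profile.
    """
    by_lnc = _pair_nsm(net)
    if not by_lnc:
        raise ValueError("empty network")
    pooled_all = [v for vals in by_lnc.values() for v in vals]
    degenerate = len(by_lnc) == 1
    profiles = {}
    for lnc, vals in by_lnc.items():
        if include_self:
            background = pooled_all
        else:
            background = [v for other, vs in by_lnc.items() if other != lnc for v in vs]
        p = _ranksum_greater(vals, background) if background else 1.0
        profiles[lnc] = NSMProfile(lnc, vals, p, degenerate=degenerate)
    return profiles


def select_lncrna_biomarkers(profiles: dict, alpha: float = 0.05) -> set:
    """lncRNAs with NSM significantly above background (strict P < alpha)."""
    return {l for l, prof in profiles.items() if prof.test_p < alpha}


def compute_nsr_profiles(net: ContextLceNET) -> dict:
    """NSR profile per miRNA.

    A target (lncRNA or mRNA) is single-line iff exactly one miRNA edge is
    incident to it in the context network.  NSR is the count of a miRNA's
    single-line targets; the test compares the miRNA's per-target single-line
    indicators against the indicators of all miRNA-target edges (one-sided,
    greater).
    """
    regulators: dict = {}
    targets_of: dict = {}
    for m, t in net.edges:
        regulators.setdefault(t, set()).add(m)
        targets_of.setdefault(m, set()).add(t)
    if not targets_of:
        raise ValueError("empty network")
    single_line = {t for t, regs in regulators.items() if len(regs) == 1}
    pooled = [
        1 if t in single_line else 0
        for m in sorted(targets_of) for t in targets_of[m]
    ]
    nsr_values = {m: sum(1 for t in ts if t in single_line) for m, ts in targets_of.items()}
    mean_nsr = float(np.mean(list(nsr_values.values())))
    profiles = {}
    for m in sorted(targets_of):
        indicators = [1 if t in single_line else 0 for t in targets_of[m]]
        profiles[m] = NSRProfile(
            m,
            nsr=nsr_values[m],
            n_targets=len(targets_of[m]),
            passes_mean=nsr_values[m] > mean_nsr,
            test_p=_ranksum_greater(indicators, pooled),
        )
    return profiles


def select_mirna_biomarkers(profiles: dict, alpha: float = 0.05,
                            require_mean: bool = True) -> set:
    """miRNAs with NSR above the network mean (strict) and P < alpha."""
    return {
        m for m, prof in profiles.items()
        if prof.test_p < alpha and (prof.passes_mean or not require_mean)
    }


def screen_key_triplets(
    net: ContextLceNET,
    lnc_biomarkers: set,
    mir_biomarkers: set,
    directions: dict,
    tag_genes: set,
    prognosis_genes: set,
) -> list:
    """Key lncRNA-miRNA-mRNA triplets of a context network.

    A triplet is kept iff (1) its lncRNA is a lncRNA biomarker, (2) its miRNA
    is a miRNA biomarker, (3) its mRNA is a listed tumor-associated gene or
    prognosis-associated, and (4) the miRNA's expression direction is opposite
    to both the lncRNA's and the mRNA's.  Triplets with a missing direction
    are skipped with a log entry.
    """
    kept = []
    for l, m, a in net.triplets:
        if l not in lnc_biomarkers or m not in mir_biomarkers:
            continue
        is_tag = a in tag_genes
        is_prog = a in prognosis_genes
        if not (is_tag or is_prog):
            continue
        try:
            dl, dm, da = directions[l], directions[m], directions[a]
        except KeyError as e:
            log.warning("triplet (%s, %s, %s) skipped: missing direction for %s",
                        l, m, a, e.args[0])
            continue
        if dm != dl and dm != da:
            kept.append(TripletCandidate(l, m, a, {l: dl, m: dm, a: da}, is_tag, is_prog))
    return kept
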