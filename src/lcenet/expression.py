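"""Expression filtering, differential expression, and cross-contrast overlap.

Counts are organized as a features x samples matrix with a feature class
(lncRNA / miRNA / mRNA) per row and a tissue (normal / M0 / M1) and site
(colon / rectal) annotation per sample.  Four contrasts are analyzed: each
site's M0 and M1 tumors against that site's normal tissue.

The default differential-expression engine is a per-feature two-sided
Wilcoxon rank-sum test on CPM with a pseudocount fold change; an external DE
table (e.g. from a count-model package) can be ingested verbatim instead.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .stats import bh_adjust

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("lncRNA", "miRNA", "mRNA")
TISSUES = ("normal", "M0", "M1")
SITES = ("colon", "rectal")
CONTRAST_LABELS = ("colon_M0N", "colon_M1N", "rectal_M0N", "rectal_M1N")

__all__ = [
    "ExpressionStudy",
    "Contrast",
    "contrasts_from_study",
    "cpm",
    "filter_expressed",
    "differential_expression",
    "ingest_de_table",
    "select_de",
    "overlap_de_sets",
]


@dataclass
class ExpressionStudy:
    """Count matrix plus feature and sample annotations.

    ``counts``: non-negative integer DataFrame, features x samples.
    ``feature_class``: Series indexed like ``counts`` rows.
    ``samples``: DataFrame indexed by sample id with 'tissue' and 'site'.
    ``library_sizes``: per-sample totals; defaults to column sums.
    """

    counts: pd.DataFrame
    feature_class: pd.Series
    samples: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.feature_class.index):
            raise ValueError("feature_class index must match counts rows")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"unannotated samples: {sorted(missing)[:5]}")
        bad = set(self.feature_class) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {bad}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.samples = self.samples.loc[self.counts.columns]

    def subset_features(self, keep) -> "ExpressionStudy":
        return ExpressionStudy(
            self.counts.loc[keep],
            self.feature_class.loc[keep],
            self.samples,
            self.library_sizes,
        )

    def sample_ids(self, site: str, tissue: str) -> list:
        m = (self.samples["site"] == site) & (self.samples["tissue"] == tissue)
        return list(self.samples.index[m])


@dataclass
class Contrast:
    """Tumor group versus its reference normal group."""

    label: str
    group_a: list  # tumor samples
    group_b: list  # normal samples

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError(f"{self.label}: both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"{self.label}: groups overlap")

    @property
    def all_samples(self) -> list:
        return list(self.group_a) + list(self.group_b)


def contrasts_from_study(study: ExpressionStudy) -> dict:
    """The four standard site x stage contrasts present in the study."""
    out = {}
    for site in SITES:
        normal = study.sample_ids(site, "normal")
        for stage in ("M0", "M1"):
            tumor = study.sample_ids(site, stage)
            label = f"{site}_{stage}N"
            if tumor and normal:
                out[label] = Contrast(label, tumor, normal)
    return out


def cpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6."""
    libs = library_sizes.loc[counts.columns]
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"non-positive library size for sample(s) {list(zero.index)}")
    return counts / libs * 1e6


def filter_expressed(
    study: ExpressionStudy,
    sample_subset: list | None = None,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.8,
) -> tuple["ExpressionStudy", pd.Index]:
    """Keep features with CPM > threshold in at least 80% of the samples.

    The rule is evaluated on ``sample_subset`` (a contrast's combined tumor +
    normal samples) or on all samples; the required count is
    ``ceil(sample_fraction * n_samples)``.  Returns the filtered study and the
    index of dropped features.
    """
    if cpm_threshold <= 0 or not (0 < sample_fraction <= 1):
        raise ValueError("thresholds must be positive")
    cols = list(sample_subset) if sample_subset is not None else list(study.counts.columns)
    mat = cpm(study.counts[cols], study.library_sizes)
    need = math.ceil(sample_fraction * len(cols))
    ok = (mat > cpm_threshold).sum(axis=1) >= need
    dropped = study.counts.index[~ok]
    log.info("expression filter: kept %d / %d features", int(ok.sum()), len(ok))
    return study.subset_features(study.counts.index[ok]), dropped


def differential_expression(
    study: ExpressionStudy,
    contrast: Contrast,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Rank-sum differential expression of tumor (group_a) versus normal.

    Per feature: two-sided Wilcoxon rank-sum on CPM between groups;
    log2FC = log2((mean CPM_a + pseudocount) / (mean CPM_b + pseudocount)).
    BH is applied within each feature class separately (the three RNA classes
    come from separate sequencing assays and are treated as separate test
    families).  Returns columns: feature_id, feature_class, log2_fc, p_value,
    fdr, direction.
    """
    if len(contrast.group_a) < 2 or len(contrast.group_b) < 2:
        raise ValueError(f"{contrast.label}: each group needs >= 2 samples")
    mat = cpm(study.counts[contrast.all_samples], study.library_sizes)
    a = mat[contrast.group_a].to_numpy()
    b = mat[contrast.group_b].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied rows trigger benign warnings
        res = mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
    lfc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    out = pd.DataFrame(
        {
            "feature_id": study.counts.index,
            "feature_class": study.feature_class.values,
            "log2_fc": lfc,
            "p_value": pvals,
        }
    )
    out["fdr"] = 1.0
    for cls, idx in out.groupby("feature_class").groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def ingest_de_table(df: pd.DataFrame) -> pd.DataFrame:
    """Adopt an externally computed DE table (feature, class, logFC, FDR)."""
    required = {"feature_id", "feature_class", "log2_fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external DE table missing columns {sorted(missing)}")
    out = df.copy()
    if "direction" not in out.columns:
        out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


def select_de(records: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05) -> pd.DataFrame:
    """Significant DE features: |log2FC| >= lfc_min and FDR < fdr_max."""
    keep = (records["log2_fc"].abs() >= lfc_min) & (records["fdr"] < fdr_max)
    return records[keep].reset_index(drop=True)


def de_sets_by_class(selected: pd.DataFrame) -> dict:
    """Map feature class -> set of significant feature ids."""
    return {
        cls: set(selected.loc[selected["feature_class"] == cls, "feature_id"])
        for cls in FEATURE_CLASSES
    }


def overlap_de_sets(sets_by_contrast: dict) -> dict:
    """Venn-region counts across contrast DE sets plus the common intersection.

    ``sets_by_contrast`` maps contrast label -> set of feature ids.  Returns
    ``{"regions": {frozenset(labels): count}, "common": set}`` where each
    region counts features in exactly that subset of contrasts.
    """
    labels = sorted(sets_by_contrast)
    if len(labels) < 2:
        raise ValueError("need at least two contrasts to overlap")
    regions: dict = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets_by_contrast[c] for c in combo))
            outside = set.union(
                set(), *(sets_by_contrast[c] for c in labels if c not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)
    common = set.intersection(*(sets_by_contrast[c] for c in labels))
    return {"regions": regions, "common": common}
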