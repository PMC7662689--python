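"""Seeded synthetic studies with planted ground truth.

The generator emulates the statistical structure the ceRNA pipeline assumes,
at desk scale, so that every stage has a recoverable answer:

* an interaction catalog with three planted tiers of competing lncRNA-mRNA
  pairs — four "biomarker" lncRNA modules whose pairs share many miRNAs
  (high NSM), a set of pairs regulated in-context by a single biomarker
  miRNA (high NSR), and weak background pairs — plus sparse random decoy
  edges that should not survive the competition test;
* negative-binomial counts for two sites (colon, rectal) with normal / M0 /
  M1 groups, planted fold changes (miRNAs opposite in sign to their
  lncRNA/mRNA partners), and a shared latent factor per planted module that
  induces positive lncRNA-mRNA correlation of target strength ``rho`` in
  tumor samples with a negative miRNA loading;
* exponential survival times whose hazard is multiplied for samples in the
  high-expression half of each hazard gene, with uniform censoring.

Everything is a pure function of the config: one seed sequence is spawned
into independent child streams per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import LNCRNA, MRNA, InteractionCatalog, InteractionEdge
from .expression import ExpressionStudy

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_catalog",
    "generate_expression",
    "generate_survival",
    "simulate_survival_records",
    "make_fixture",
]

_SOURCE = "synthetic"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset (seed-deterministic)."""

    seed: int = 7
    # universe sizes
    n_mirna: int = 60
    n_lncrna: int = 80
    n_mrna: int = 400
    # samples per site
    n_normal: int = 30
    n_m0: int = 30
    n_m1: int = 20
    # planted catalog structure
    n_biomarker_lncrnas: int = 4
    partners_per_biomarker: int = 6
    module_shared: int = 8          # miRNAs shared by a biomarker pair
    n_singleline_pairs: int = 10    # pairs regulated in-context only by m*
    n_weak_lncrnas: int = 8
    partners_per_weak: int = 2
    weak_shared: int = 3
    background_degree: tuple = (2, 5)  # inclusive range of decoy node degree
    # expression
    de_effect: float = 2.0          # log2 fold change of planted DE features
    n_extra_de_lncrna: int = 10
    n_extra_de_mrna: int = 40
    n_site_specific_de: int = 10    # colon-only mRNAs
    n_stage_specific_de: int = 10   # M1-only mRNAs
    rho: float = 0.8                # target lncRNA-mRNA Pearson in tumors
    nb_dispersion: float = 0.05
    depth: float = 2.0e5            # expected library size
    planted_base_mean: float = 400.0
    n_low_expressed: int = 20       # mRNAs below the CPM filter
    # survival
    hazard_ratio: float = 3.0
    baseline_median_days: float = 1095.0
    censor_max_days: float = 2500.0

    def validate(self):
        pool = (
            self.n_biomarker_lncrnas * self.module_shared
            + 1  # the biomarker miRNA
            + 6  # weak-pair miRNA pool
            + 2 * self.n_singleline_pairs
        )
        if pool > self.n_mirna:
            raise ValueError(
                f"planted structure needs {pool} miRNAs but n_mirna={self.n_mirna}"
            )
        if self.module_shared + 1 > self.n_mirna:
            raise ValueError("shared-miRNA count exceeds the miRNA universe")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted answers, consistent with the generated data by construction."""

    pairs: list = field(default_factory=list)          # (lncrna, mrna)
    global_triplets: list = field(default_factory=list)
    context_triplets: list = field(default_factory=list)  # DE-miRNA triplets
    de_directions: dict = field(default_factory=dict)  # contrast -> id -> dir
    lncrna_biomarkers: list = field(default_factory=list)
    mirna_biomarkers: list = field(default_factory=list)
    key_triplets: list = field(default_factory=list)
    hazard_genes: list = field(default_factory=list)
    tag_genes: list = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["pairs"] = [list(p) for p in d["pairs"]]
        for k in ("global_triplets", "context_triplets", "key_triplets"):
            d[k] = [list(t) for t in d[k]]
        return json.dumps(d, indent=1, sort_keys=True)


class _Layout:
    """Deterministic id bookkeeping for the planted structure."""

    def __init__(self, cfg: SyntheticConfig):
        cfg.validate()
        self.cfg = cfg
        self.mirnas = [f"hsa-mir-{i:03d}" for i in range(1, cfg.n_mirna + 1)]
        self.lncs = [f"LNC{i:03d}" for i in range(1, cfg.n_lncrna + 1)]
        self.mrnas = [f"GENE{i:04d}" for i in range(1, cfg.n_mrna + 1)]

        nb, ps, ms = cfg.n_biomarker_lncrnas, cfg.partners_per_biomarker, cfg.module_shared
        self.module_mirnas = [self.mirnas[ms * i: ms * (i + 1)] for i in range(nb)]
        k = ms * nb
        self.m_star = self.mirnas[k]
        self.weak_pool = self.mirnas[k + 1: k + 7]
        d0 = k + 7
        self.decoy_mirnas = self.mirnas[d0: d0 + 2 * cfg.n_singleline_pairs]

        self.bio_lncs = self.lncs[:nb]
        n2a = cfg.n_singleline_pairs
        self.sl_lncs = self.lncs[nb: nb + n2a]
        nw = cfg.n_weak_lncrnas
        self.weak_lncs = self.lncs[nb + n2a: nb + n2a + nw]
        self.extra_de_lncs = self.lncs[nb + n2a + nw: nb + n2a + nw + cfg.n_extra_de_lncrna]
        self.background_lncs = self.lncs[nb + n2a + nw:]

        self.bio_mrnas = self.mrnas[: nb * ps]  # partners, module-major
        a = nb * ps
        self.sl_mrnas = self.mrnas[a: a + n2a]
        a += n2a
        self.weak_mrnas = self.mrnas[a: a + nw * cfg.partners_per_weak]
        a += nw * cfg.partners_per_weak
        self.extra_de_mrnas = self.mrnas[a: a + cfg.n_extra_de_mrna]
        a += cfg.n_extra_de_mrna
        self.site_de_mrnas = self.mrnas[a: a + cfg.n_site_specific_de]
        a += cfg.n_site_specific_de
        self.stage_de_mrnas = self.mrnas[a: a + cfg.n_stage_specific_de]
        a += cfg.n_stage_specific_de
        self.background_mrnas = self.mrnas[a:]
        self.low_mrnas = self.mrnas[-cfg.n_low_expressed:] if cfg.n_low_expressed else []
        # the two key-triplet partner mRNAs (first partner of modules 0 and 1)
        if nb >= 2 and ps >= 1:
            self.key_mrnas = [self.bio_mrnas[0], self.bio_mrnas[ps]]
        else:
            self.key_mrnas = []
        # one hazard gene keeps the planted survival signal identifiable
        self.hazard_genes = self.key_mrnas[1:2]
        self.tag_genes = self.key_mrnas[:1] + self.background_mrnas[:10]

    def partner_block(self, i: int) -> list:
        ps = self.cfg.partners_per_biomarker
        return self.bio_mrnas[ps * i: ps * (i + 1)]

    def planted_network_genes(self) -> dict:
        """class -> ids of genes in the planted network (all DE)."""
        de_mirnas = [m for mod in self.module_mirnas for m in mod]
        if self.cfg.n_biomarker_lncrnas or self.cfg.n_singleline_pairs:
            de_mirnas.append(self.m_star)
        if self.cfg.n_weak_lncrnas:
            de_mirnas += self.weak_pool
        return {
            "lncRNA": self.bio_lncs + self.sl_lncs + self.weak_lncs,
            "miRNA": de_mirnas,
            "mRNA": self.bio_mrnas + self.sl_mrnas + self.weak_mrnas,
        }


@dataclass
class SyntheticStudy:
    """Bundle of everything one seed generates."""

    config: SyntheticConfig
    catalog: InteractionCatalog
    study: ExpressionStudy
    survival: dict  # site -> DataFrame(sample, time, event)
    tag_genes: list
    gene_sets: dict
    truth: GroundTruth

    def write_dir(self, out_dir) -> None:
        from .io import write_study_dir

        write_study_dir(self, out_dir)


def _streams(cfg: SyntheticConfig) -> dict:
    names = ("catalog", "expression", "survival", "genesets")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def generate_catalog(cfg: SyntheticConfig, rng=None) -> tuple[InteractionCatalog, GroundTruth]:
    """Planted interaction catalog plus the ground-truth fragment it defines."""
    lay = _Layout(cfg)
    if rng is None:
        rng = _streams(cfg)["catalog"]
    sets_lnc: dict = {}
    sets_mrna: dict = {}

    truth = GroundTruth(
        lncrna_biomarkers=list(lay.bio_lncs),
        mirna_biomarkers=[lay.m_star],
        hazard_genes=list(lay.hazard_genes),
        tag_genes=list(lay.tag_genes),
    )

    # tier 1: biomarker modules, pairs sharing a full module of miRNAs
    for i, lnc in enumerate(lay.bio_lncs):
        module = set(lay.module_mirnas[i])
        lnc_set = set(module)
        if i < 2:  # modules 0 and 1 host the key triplets through m*
            lnc_set.add(lay.m_star)
        sets_lnc[lnc] = lnc_set
        for j, mrna in enumerate(lay.partner_block(i)):
            mset = set(module)
            if i < 2 and j == 0:
                mset.add(lay.m_star)
            sets_mrna[mrna] = mset
            truth.pairs.append((lnc, mrna))

    # tier 2a: pairs whose only differentially expressed regulator is m*
    for j, (lnc, mrna) in enumerate(zip(lay.sl_lncs, lay.sl_mrnas)):
        shared = {lay.m_star, lay.decoy_mirnas[2 * j], lay.decoy_mirnas[2 * j + 1]}
        sets_lnc[lnc] = set(shared)
        sets_mrna[mrna] = set(shared)
        truth.pairs.append((lnc, mrna))

    # tier 2b: weak pairs sharing a small pool triple
    triples = list(combinations(lay.weak_pool, cfg.weak_shared))
    for j, lnc in enumerate(lay.weak_lncs):
        shared = set(triples[j % len(triples)])
        sets_lnc[lnc] = set(shared)
        for mrna in lay.weak_mrnas[
            cfg.partners_per_weak * j: cfg.partners_per_weak * (j + 1)
        ]:
            sets_mrna[mrna] = set(shared)
            truth.pairs.append((lnc, mrna))

    # sparse background edges on all remaining nodes (decoy pairs)
    lo, hi = cfg.background_degree
    for lnc in lay.background_lncs:
        d = int(rng.integers(lo, hi + 1))
        sets_lnc[lnc] = set(rng.choice(lay.mirnas, size=d, replace=False))
    for mrna in lay.mrnas:
        if mrna in sets_mrna:
            continue
        d = int(rng.integers(lo, hi + 1))
        sets_mrna[mrna] = set(rng.choice(lay.mirnas, size=d, replace=False))

    edges = []
    for lnc, ms in sets_lnc.items():
        edges += [InteractionEdge(m, lnc, LNCRNA, frozenset([_SOURCE])) for m in sorted(ms)]
    for mrna, ms in sets_mrna.items():
        edges += [InteractionEdge(m, mrna, MRNA, frozenset([_SOURCE])) for m in sorted(ms)]
    catalog = InteractionCatalog(sorted(edges, key=lambda e: (e.mirna_id, e.target_class, e.target_id)),
                                 n_mirna_universe=cfg.n_mirna)

    de_mirnas = set(lay.planted_network_genes()["miRNA"])
    for lnc, mrna in truth.pairs:
        shared = sorted(sets_lnc[lnc] & sets_mrna[mrna])
        truth.global_triplets += [(lnc, m, mrna) for m in shared]
        truth.context_triplets += [(lnc, m, mrna) for m in shared if m in de_mirnas]
    if len(lay.key_mrnas) == 2:
        truth.key_triplets = [
            (lay.bio_lncs[0], lay.m_star, lay.key_mrnas[0]),
            (lay.bio_lncs[1], lay.m_star, lay.key_mrnas[1]),
        ]
    return catalog, truth


def _sample_frame(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for site in ("colon", "rectal"):
        for tissue, n in (("normal", cfg.n_normal), ("M0", cfg.n_m0), ("M1", cfg.n_m1)):
            rows += [(f"{site}_{tissue}_{i:02d}", tissue, site) for i in range(1, n + 1)]
    return pd.DataFrame(rows, columns=["sample", "tissue", "site"]).set_index("sample")


def _factor_loading(cfg: SyntheticConfig, base_sum: float) -> float:
    """Latent-factor scale giving count-level Pearson ~ rho in tumors.

    For two genes sharing a log-normal factor exp(s*z - s^2/2) on top of NB
    noise, corr = v / (v + cv2) with v = exp(s^2) - 1 and cv2 the NB squared
    coefficient of variation (1/mu + dispersion).  Solving for corr = rho
    gives v = cv2 * rho / (1 - rho).
    """
    mu_tumor = cfg.depth * (cfg.planted_base_mean / base_sum) * 2.0 ** cfg.de_effect
    cv2 = 1.0 / mu_tumor + cfg.nb_dispersion
    v = cv2 * cfg.rho / (1.0 - cfg.rho)
    return float(np.sqrt(np.log1p(v)))


def generate_expression(
    cfg: SyntheticConfig, truth: GroundTruth | None = None, rng=None
) -> tuple[ExpressionStudy, GroundTruth]:
    """Negative-binomial counts with planted DE and ceRNA correlation."""
    lay = _Layout(cfg)
    if rng is None:
        rng = _streams(cfg)["expression"]
    if truth is None:
        truth = GroundTruth()
    samples = _sample_frame(cfg)
    features = lay.lncs + lay.mirnas + lay.mrnas
    classes = (["lncRNA"] * cfg.n_lncrna + ["miRNA"] * cfg.n_mirna
               + ["mRNA"] * cfg.n_mrna)
    n_feat, n_samp = len(features), len(samples)
    fidx = {f: i for i, f in enumerate(features)}
    tumor = (samples["tissue"] != "normal").to_numpy()
    m1 = (samples["tissue"] == "M1").to_numpy()
    colon_tumor = tumor & (samples["site"] == "colon").to_numpy()

    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_feat)
    net = lay.planted_network_genes()
    planted = (
        net["lncRNA"] + net["miRNA"] + net["mRNA"]
        + lay.extra_de_lncs + lay.extra_de_mrnas
        + lay.site_de_mrnas + lay.stage_de_mrnas
    )
    for f in planted:
        base[fidx[f]] = cfg.planted_base_mean
    for f in lay.low_mrnas:
        base[fidx[f]] = 0.05
    base_sum = float(base.sum())

    # planted fold changes: network lncRNA/mRNA up, miRNA down, extras random
    up, down = 2.0 ** cfg.de_effect, 2.0 ** (-cfg.de_effect)
    fold = np.ones((n_feat, n_samp))
    directions: dict = {}

    def plant(fid, direction, mask):
        fold[fidx[fid], mask] = up if direction == "up" else down
        directions[fid] = direction

    for f in net["lncRNA"] + net["mRNA"]:
        plant(f, "up", tumor)
    for f in net["miRNA"]:
        plant(f, "down", tumor)
    for f in lay.extra_de_lncs + lay.extra_de_mrnas:
        plant(f, "up" if rng.random() < 0.5 else "down", tumor)
    site_dirs = {f: ("up" if rng.random() < 0.5 else "down") for f in lay.site_de_mrnas}
    stage_dirs = {f: ("up" if rng.random() < 0.5 else "down") for f in lay.stage_de_mrnas}
    for f, d in site_dirs.items():
        fold[fidx[f], colon_tumor] = up if d == "up" else down
    for f, d in stage_dirs.items():
        fold[fidx[f], m1] = up if d == "up" else down

    # per-contrast expected DE directions
    common = dict(directions)
    truth.de_directions = {
        "colon_M0N": {**common, **{f: d for f, d in site_dirs.items()}},
        "colon_M1N": {**common, **site_dirs, **stage_dirs},
        "rectal_M0N": dict(common),
        "rectal_M1N": {**common, **stage_dirs},
    }

    # latent factors inducing lncRNA-mRNA correlation (miRNA loading negative)
    s = _factor_loading(cfg, base_sum)
    factor = np.ones((n_feat, n_samp))

    def load(members_pos, members_neg):
        z = rng.standard_normal(n_samp)
        for f in members_pos:
            factor[fidx[f], tumor] *= np.exp(s * z[tumor] - s * s / 2.0)
        for f in members_neg:
            factor[fidx[f], tumor] *= np.exp(-s * z[tumor] - s * s / 2.0)

    for i, lnc in enumerate(lay.bio_lncs):
        load([lnc] + lay.partner_block(i), lay.module_mirnas[i])
    for j, (lnc, mrna) in enumerate(zip(lay.sl_lncs, lay.sl_mrnas)):
        load([lnc, mrna], [lay.m_star] if j == 0 else [])
    for j, lnc in enumerate(lay.weak_lncs):
        block = lay.weak_mrnas[cfg.partners_per_weak * j: cfg.partners_per_weak * (j + 1)]
        load([lnc] + block, [lay.weak_pool[j % len(lay.weak_pool)]])

    u = rng.uniform(0.7, 1.3, size=n_samp)
    mu = (cfg.depth * u) * (base[:, None] / base_sum) * fold * factor
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    study = ExpressionStudy(
        pd.DataFrame(counts, index=pd.Index(features, name="feature"),
                     columns=samples.index),
        pd.Series(classes, index=pd.Index(features, name="feature")),
        samples,
    )
    return study, truth


def generate_survival(
    cfg: SyntheticConfig, study: ExpressionStudy, truth: GroundTruth, rng=None
) -> dict:
    """Per-site survival tables with expression-dependent hazards.

    For each hazard gene, tumor samples in its high-expression half (within
    site) have their event hazard multiplied by ``hazard_ratio``; hazards
    multiply across hazard genes.  Event times are exponential; censoring is
    independent uniform on (0, censor_max_days).
    """
    if rng is None:
        rng = _streams(cfg)["survival"]
    lam0 = np.log(2.0) / cfg.baseline_median_days
    out = {}
    for site in ("colon", "rectal"):
        ids = [s for s in study.samples.index
               if study.samples.loc[s, "site"] == site
               and study.samples.loc[s, "tissue"] != "normal"]
        lam = np.full(len(ids), lam0)
        libs = study.library_sizes.loc[ids].to_numpy(dtype=float)
        for gene in truth.hazard_genes:
            # hazard follows relative abundance, not raw depth-confounded counts
            expr = study.counts.loc[gene, ids].to_numpy(dtype=float) / libs
            high = expr >= np.median(expr)
            lam = lam * np.where(high, cfg.hazard_ratio, 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(0.0, cfg.censor_max_days, size=len(ids))
        time = np.minimum(t_event, t_censor)
        event = t_event <= t_censor
        out[site] = pd.DataFrame(
            {"sample": ids, "time": time, "event": event.astype(int)}
        ).set_index("sample")
    return out


def simulate_survival_records(
    n: int, hazard_ratio: float, seed: int,
    baseline_median_days: float = 1095.0, censor_max_days: float = 2500.0,
) -> pd.DataFrame:
    """Stand-alone survival cohort for power/null checks of the log-rank test.

    Expression is log-normal; the high-expression half has its hazard
    multiplied by ``hazard_ratio``.  Returns columns time, event, expression.
    """
    rng = np.random.default_rng(seed)
    expr = rng.lognormal(mean=5.0, sigma=1.0, size=n)
    high = expr >= np.median(expr)
    lam = (np.log(2.0) / baseline_median_days) * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, censor_max_days, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
            "expression": expr,
        },
        index=[f"s{i:03d}" for i in range(n)],
    )


def _gene_sets(cfg: SyntheticConfig, lay: _Layout, rng) -> dict:
    """A handful of gene sets, one enriched in the planted DE mRNAs."""
    de = lay.extra_de_mrnas
    bg = [m for m in lay.background_mrnas if m not in lay.low_mrnas]
    n_pad, n_rand = min(10, len(bg)), min(25, len(bg))
    sets = {
        "planted_pathway": de[:15] + list(rng.choice(bg, size=n_pad, replace=False)),
    }
    for k in range(4):
        sets[f"random_set_{k + 1}"] = list(rng.choice(bg, size=n_rand, replace=False))
    return sets


def make_fixture(seed: int = 7, cfg: SyntheticConfig | None = None) -> SyntheticStudy:
    """The canonical small study used by the end-to-end regression test."""
    if cfg is None:
        cfg = SyntheticConfig(seed=seed)
    else:
        cfg.seed = seed
    streams = _streams(cfg)
    catalog, truth = generate_catalog(cfg, streams["catalog"])
    study, truth = generate_expression(cfg, truth, streams["expression"])
    survival = generate_survival(cfg, study, truth, streams["survival"])
    lay = _Layout(cfg)
    gene_sets = _gene_sets(cfg, lay, streams["genesets"])
    return SyntheticStudy(cfg, catalog, study, survival,
                          list(truth.tag_genes), gene_sets, truth)
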