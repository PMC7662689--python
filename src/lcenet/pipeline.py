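"""End-to-end orchestration: catalog -> global net -> DE -> context nets ->
biomarkers -> key triplets -> evaluation.

``run_all`` takes in-memory inputs (an interaction catalog, an expression
study, per-site survival tables, a tumor-associated-gene list) plus a
threshold configuration, and returns a :class:`PipelineResult` whose
``manifest`` records per-stage record counts for regression checking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import biomarkers as bm
from . import context as ctx
from . import evaluation as ev
from . import expression as ex
from .catalog import InteractionCatalog
from .global_network import GlobalLceNET, build_global_lcenet

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults follow the analysis contract)."""

    alpha_pair: float = 0.01
    cpm_threshold: float = 1.0
    sample_fraction: float = 0.8
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    r_min: float = 0.5
    p_max: float = 0.05
    hub_fraction: float = 0.05
    alpha_biomarker: float = 0.05
    prognosis_alpha: float = 0.05
    survival_upper: float = 0.5
    survival_lower: float = 0.5

    def validate(self):
        for name in ("alpha_pair", "fdr_max", "p_max", "alpha_biomarker",
                     "prognosis_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction outside (0, 1]")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    global_net: GlobalLceNET
    de_records: dict = field(default_factory=dict)      # contrast -> DataFrame
    de_selected: dict = field(default_factory=dict)     # contrast -> DataFrame
    de_overlap: dict = field(default_factory=dict)      # class -> overlap dict
    context_nets: dict = field(default_factory=dict)    # contrast -> ContextLceNET
    topology: dict = field(default_factory=dict)        # contrast -> (nodes, hubs, fit)
    nsm_profiles: dict = field(default_factory=dict)
    nsr_profiles: dict = field(default_factory=dict)
    lnc_biomarkers: dict = field(default_factory=dict)  # contrast -> set
    mir_biomarkers: dict = field(default_factory=dict)
    key_triplets: dict = field(default_factory=dict)    # contrast -> list
    shared_triplets: set = field(default_factory=set)
    roc: dict = field(default_factory=dict)             # contrast -> {id: auc}
    survival_tests: dict = field(default_factory=dict)  # contrast -> {id: p}
    manifest: dict = field(default_factory=dict)


def _prognosis_genes(study, site_survival, genes, config) -> set:
    """Genes whose expression split separates survival (log-rank p < alpha)."""
    out = set()
    tumor_ids = [s for s in site_survival.index if s in study.counts.columns]
    expr = ex.cpm(study.counts[tumor_ids], study.library_sizes)
    for g in sorted(genes):
        if g not in expr.index:
            continue
        rec = pd.DataFrame(
            {
                "time": site_survival.loc[tumor_ids, "time"],
                "event": site_survival.loc[tumor_ids, "event"],
                "expression": expr.loc[g, tumor_ids],
            }
        )
        try:
            res = ev.km_logrank(rec, config.survival_upper, config.survival_lower)
        except ValueError:
            continue
        if res.p_value < config.prognosis_alpha:
            out.add(g)
    return out


def run_all(
    catalog: InteractionCatalog,
    study: ex.ExpressionStudy,
    survival: dict,
    tag_genes,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute every stage and assemble a manifest of record counts."""
    config = config or PipelineConfig()
    config.validate()
    manifest: dict = {"config_digest": config.digest()}
    manifest["catalog_edges"] = len(catalog.edges)

    gnet = build_global_lcenet(catalog, config.alpha_pair)
    manifest["pairs_tested"] = gnet.n_tested
    manifest["pairs_significant"] = len(gnet.pairs)
    manifest["global_triplets"] = len(gnet.triplets)

    result = PipelineResult(config, gnet)
    contrasts = ex.contrasts_from_study(study)
    tag_set = set(tag_genes)

    for label, contrast in sorted(contrasts.items()):
        filtered, _ = ex.filter_expressed(
            study, contrast.all_samples, config.cpm_threshold, config.sample_fraction
        )
        records = ex.differential_expression(filtered, contrast)
        selected = ex.select_de(records, config.lfc_min, config.fdr_max)
        result.de_records[label] = records
        result.de_selected[label] = selected
        de_sets = ex.de_sets_by_class(selected)
        manifest[f"de_{label}"] = {c: len(s) for c, s in sorted(de_sets.items())}

        candidates = ctx.extract_context_candidates(gnet.triplets, de_sets)
        tumor_expr = ex.cpm(
            filtered.counts[contrast.group_a], filtered.library_sizes
        )
        needed = sorted({t[0] for t in candidates} | {t[2] for t in candidates})
        net = ctx.pearson_filter(
            candidates, tumor_expr.loc[needed], label, config.r_min, config.p_max
        ) if candidates else ctx.ContextLceNET(label)
        result.context_nets[label] = net
        manifest[f"context_{label}"] = {
            "candidates": len(candidates),
            "triplets": len(net.triplets),
            "nodes": sum(len(v) for v in net.nodes_by_class().values()),
        }
        if not net.triplets:
            log.warning("%s: empty context network; downstream stages empty", label)
            result.key_triplets[label] = []
            continue

        nodes, hubs, fit = ctx.topology_report(net, config.hub_fraction)
        result.topology[label] = (nodes, hubs, fit)
        manifest[f"hubs_{label}"] = len(hubs)

        nsm = bm.compute_nsm_profiles(net)
        nsr = bm.compute_nsr_profiles(net)
        lnc_b = bm.select_lncrna_biomarkers(nsm, config.alpha_biomarker)
        mir_b = bm.select_mirna_biomarkers(nsr, config.alpha_biomarker)
        result.nsm_profiles[label] = nsm
        result.nsr_profiles[label] = nsr
        result.lnc_biomarkers[label] = lnc_b
        result.mir_biomarkers[label] = mir_b
        manifest[f"biomarkers_{label}"] = {"lncRNA": len(lnc_b), "miRNA": len(mir_b)}

        directions = dict(zip(selected["feature_id"], selected["direction"]))
        site = label.split("_")[0]
        candidate_mrnas = {
            t[2] for t in net.triplets if t[0] in lnc_b and t[1] in mir_b
        }
        prognosis = _prognosis_genes(
            study, survival[site], candidate_mrnas - tag_set, config
        ) if site in survival else set()
        result.survival_tests[label] = {"prognosis_genes": sorted(prognosis)}
        key = bm.screen_key_triplets(net, lnc_b, mir_b, directions, tag_set, prognosis)
        result.key_triplets[label] = key
        manifest[f"key_triplets_{label}"] = len(key)

        # diagnostic AUC of each biomarker, tumor vs normal on CPM; the score
        # is oriented by the marker's regulation direction so AUC reads as
        # discriminative ability for up- and down-regulated markers alike
        mat = ex.cpm(study.counts[contrast.all_samples], study.library_sizes)
        labels01 = [1] * len(contrast.group_a) + [0] * len(contrast.group_b)
        aucs = {}
        for fid in sorted(lnc_b | mir_b):
            scores = mat.loc[fid].to_numpy()
            if directions.get(fid) == "down":
                scores = -scores
            aucs[fid] = ev.roc_auc(scores, labels01).auc
        result.roc[label] = aucs

    # cross-contrast DE overlap per class and shared context interactions
    for cls in ex.FEATURE_CLASSES:
        sets = {
            label: set(sel.loc[sel["feature_class"] == cls, "feature_id"])
            for label, sel in result.de_selected.items()
        }
        if len(sets) >= 2:
            result.de_overlap[cls] = ex.overlap_de_sets(sets)
            manifest[f"de_common_{cls}"] = len(result.de_overlap[cls]["common"])
    nets = [n for n in result.context_nets.values() if n.triplets]
    if len(nets) >= 2:
        result.shared_triplets = ctx.shared_interactions(nets)
        manifest["shared_triplets"] = len(result.shared_triplets)

    result.manifest = manifest
    return result
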