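"""Plain-text input/output: study directories, network exports, gene sets.

All on-disk formats are standard text: TSV tables, GMT gene sets, SIF and
GraphML network exports (Cytoscape-ready, with a node ``type`` attribute in
{lncRNA, miRNA, mRNA}).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import ExpressionStudy

__all__ = [
    "write_sif",
    "write_graphml",
    "triplet_graph",
    "read_gmt",
    "write_gmt",
    "write_study_dir",
    "read_study_dir",
]


def triplet_graph(triplets) -> nx.Graph:
    """Tripartite graph of (lncRNA, miRNA, mRNA) triplets with typed nodes."""
    g = nx.Graph()
    for l, m, a in triplets:
        g.add_node(l, type="lncRNA")
        g.add_node(m, type="miRNA")
        g.add_node(a, type="mRNA")
        g.add_edge(m, l, interaction="mirna-lncrna")
        g.add_edge(m, a, interaction="mirna-mrna")
    return g


def write_sif(triplets, path) -> None:
    g = triplet_graph(triplets)
    with open(path, "w") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{d['interaction']}\t{v}\n")


def write_graphml(triplets, path) -> None:
    nx.write_graphml(triplet_graph(triplets), path)


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def write_study_dir(bundle, out_dir) -> None:
    """Write a SyntheticStudy as the text inputs the pipeline reads."""
    from .catalog import write_catalog

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(bundle.catalog, out / "catalog.tsv")
    bundle.study.counts.to_csv(out / "counts.tsv", sep="\t")
    ann = bundle.study.samples.copy()
    ann.to_csv(out / "samples.tsv", sep="\t")
    bundle.study.feature_class.rename("feature_class").to_csv(
        out / "features.tsv", sep="\t"
    )
    for site, df in bundle.survival.items():
        df.to_csv(out / f"survival_{site}.tsv", sep="\t")
    with open(out / "tag_genes.txt", "w") as fh:
        fh.write("\n".join(bundle.tag_genes) + "\n")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    with open(out / "ground_truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())


def read_study_dir(in_dir):
    """Read counts/annotations/survival/TAG/GMT back from a study directory.

    Returns a dict with keys: study, survival, tag_genes, gene_sets, and (if
    present) catalog.
    """
    from .catalog import read_catalog

    d = Path(in_dir)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    classes = pd.read_csv(d / "features.tsv", sep="\t", index_col=0)["feature_class"]
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    study = ExpressionStudy(counts, classes, samples)
    survival = {
        p.stem.replace("survival_", ""): pd.read_csv(p, sep="\t", index_col=0)
        for p in sorted(d.glob("survival_*.tsv"))
    }
    tag_path = d / "tag_genes.txt"
    tags = [l.strip() for l in tag_path.read_text().splitlines() if l.strip()] \
        if tag_path.exists() else []
    gmt = read_gmt(d / "gene_sets.gmt") if (d / "gene_sets.gmt").exists() else {}
    out = {"study": study, "survival": survival, "tag_genes": tags, "gene_sets": gmt}
    if (d / "catalog.tsv").exists():
        out["catalog"] = read_catalog(d / "catalog.tsv")
    return out


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
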