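"""Diagnostic, prognostic and functional evaluation of the selections.

ROC/AUC of each biomarker for tumor-versus-normal discrimination, Kaplan-
Meier + log-rank of the planted hazard gene per site cohort, and
over-representation of the DE mRNAs in the bundled gene sets.  Writes
summaries under results/evaluation/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from lcenet import evaluation as ev
from lcenet.expression import cpm
from lcenet.io import read_study_dir, write_json
from lcenet.pipeline import run_all

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    data = read_study_dir(ROOT / "study")
    truth = json.loads((ROOT / "study" / "ground_truth.json").read_text())
    study = data["study"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_all(data["catalog"], study, data["survival"], data["tag_genes"])
    out = ROOT / "evaluation"
    out.mkdir(parents=True, exist_ok=True)

    write_json(res.roc, out / "roc_auc.json")
    for label, aucs in sorted(res.roc.items()):
        shown = {k: round(v, 3) for k, v in sorted(aucs.items())}
        print(f"{label} biomarker AUC: {shown}")

    gene = truth["hazard_genes"][0]
    km_out = {}
    for site, surv in data["survival"].items():
        ids = list(surv.index)
        expr = cpm(study.counts[ids], study.library_sizes)
        rec = pd.DataFrame({"time": surv["time"], "event": surv["event"],
                            "expression": expr.loc[gene, ids]})
        r = ev.km_logrank(rec)
        km_out[site] = {"gene": gene, "logrank_p": r.p_value,
                        "statistic": r.statistic}
        print(f"{site}: hazard gene {gene} log-rank p = {r.p_value:.4f}")
    write_json(km_out, out / "km_hazard_gene.json")

    universe = set(study.counts.index[study.feature_class == "mRNA"])
    sel = res.de_selected["colon_M0N"]
    query = set(sel.loc[sel["feature_class"] == "mRNA", "feature_id"])
    ora = ev.gene_set_ora(query, universe, data["gene_sets"])
    pd.DataFrame([vars(r) for r in ora]).to_csv(out / "ora_colon_M0N.tsv",
                                                sep="\t", index=False)
    print("top enriched set:", ora[0].name, f"adj_p={ora[0].adj_p:.2e}")


if __name__ == "__main__":
    main()
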