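"""NSM/NSR biomarker screening and key-triplet selection.

For each context network: NSM profiles per lncRNA (shared-miRNA counts of
its competing pairs, tested against the pooled pair values), NSR profiles
per miRNA (single-line regulated targets, mean and rank-sum gates), and the
key triplets combining both biomarker sets with direction opposition and
TAG/prognosis annotation.  Compares the selections with the planted truth
and writes the tables under results/biomarkers/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from lcenet.io import read_study_dir
from lcenet.pipeline import run_all

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    data = read_study_dir(ROOT / "study")
    truth = json.loads((ROOT / "study" / "ground_truth.json").read_text())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_all(data["catalog"], data["study"], data["survival"],
                      data["tag_genes"])
    out = ROOT / "biomarkers"
    out.mkdir(parents=True, exist_ok=True)
    long_rows = []
    for label in sorted(res.context_nets):
        nsm = res.nsm_profiles[label]
        nsr = res.nsr_profiles[label]
        pd.DataFrame(
            [(p.lncrna_id, ";".join(map(str, p.pair_nsm_values)), p.test_p)
             for p in nsm.values()],
            columns=["lncrna", "pair_nsm_values", "test_p"],
        ).to_csv(out / f"nsm_{label}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(p.mirna_id, p.nsr, p.n_targets, p.passes_mean, p.test_p)
             for p in nsr.values()],
            columns=["mirna", "nsr", "n_targets", "passes_mean", "test_p"],
        ).to_csv(out / f"nsr_{label}.tsv", sep="\t", index=False)
        key = res.key_triplets[label]
        long_rows += [(t.lncrna, t.mirna, t.mrna, label) for t in key]
        print(f"{label}: lncRNA biomarkers {sorted(res.lnc_biomarkers[label])}, "
              f"miRNA biomarkers {sorted(res.mir_biomarkers[label])}, "
              f"{len(key)} key triplets")
    pd.DataFrame(long_rows, columns=["lncrna", "mirna", "mrna", "contrast"]).to_csv(
        out / "key_triplets_long.tsv", sep="\t", index=False)
    print(f"planted truth: lncRNA {truth['lncrna_biomarkers']}, "
          f"miRNA {truth['mirna_biomarkers']}, "
          f"key triplets {truth['key_triplets']}")


if __name__ == "__main__":
    main()
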