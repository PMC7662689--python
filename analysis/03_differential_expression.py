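"""Differential expression for the four site/stage contrasts.

CPM > 1 in >= 80% of contrast samples, rank-sum testing on CPM, selection at
|log2FC| >= 1 and FDR < 0.05, plus the cross-contrast Venn overlap of DE
sets per RNA class.  Writes per-contrast DE tables and an overlap JSON under
results/de/.
"""

import json
import warnings
from pathlib import Path

from lcenet import expression as ex
from lcenet.io import read_study_dir, write_json

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    study = read_study_dir(ROOT / "study")["study"]
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    selected = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, contrast in sorted(ex.contrasts_from_study(study).items()):
            filtered, dropped = ex.filter_expressed(study, contrast.all_samples)
            rec = ex.differential_expression(filtered, contrast)
            sel = ex.select_de(rec)
            rec.to_csv(out / f"de_{label}.tsv", sep="\t", index=False)
            sel.to_csv(out / f"de_{label}_selected.tsv", sep="\t", index=False)
            selected[label] = sel
            print(f"{label}: {len(dropped)} low-expressed dropped, "
                  f"{len(sel)}/{len(rec)} DE selected")

    overlap_out = {}
    for cls in ex.FEATURE_CLASSES:
        sets = {
            label: set(sel.loc[sel["feature_class"] == cls, "feature_id"])
            for label, sel in selected.items()
        }
        ov = ex.overlap_de_sets(sets)
        overlap_out[cls] = {
            "common": sorted(ov["common"]),
            "regions": {"+".join(sorted(k)): v for k, v in ov["regions"].items()},
        }
        print(f"{cls}: {len(ov['common'])} DE features common to all four contrasts")
    write_json(overlap_out, out / "overlap.json")


if __name__ == "__main__":
    main()
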