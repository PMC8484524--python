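"""Diagnose the three group contrasts by logistic regression + ROC.

Candidate predictors are the surviving-cluster variability extracts plus
the cognitive composites; univariately significant ones (likelihood-ratio
p < 0.05) enter the multivariable model, pruned by likelihood-ratio
backward elimination.  In-sample AUC, sensitivity and specificity at the
Youden-optimal threshold summarise each contrast.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import common
from tripledfc.classify import classify_contrast

CONTRASTS = (("HC", "SCD"), ("HC", "aMCI"), ("SCD", "aMCI"))
DOMAINS = ["EM", "EF", "IPS", "VF"]


def main() -> None:
    data = common.load_arrays("dfc")
    table = pd.read_csv(common.RESULTS / "participants.tsv", sep="\t")
    table = table[table.subject_id.isin(data["subjects"])].reset_index(drop=True)
    features = table[DOMAINS].copy()
    try:
        cmasks = common.load_arrays("cluster_masks")
        for name in cmasks.files:
            net = name.split(":")[0]
            features[name] = data[f"var_{net}"].astype(float)[
                :, cmasks[name]].mean(axis=1)
    except FileNotFoundError:
        print("no imaging clusters survived; classifying on composites only")

    report = {}
    roc_rows = []
    for pair in CONTRASTS:
        res = classify_contrast(features, table["group"], pair)
        m = res["multivariable"]
        key = f"{pair[0]}_vs_{pair[1]}"
        report[key] = {
            "auc": round(m.auc, 3),
            "sensitivity": round(m.sensitivity, 3),
            "specificity": round(m.specificity, 3),
            "predictors": m.predictors,
            "univariate_auc": {k: round(v["auc"], 3)
                               for k, v in res["univariate"].items()},
        }
        roc_rows.append(m.roc_points.assign(contrast=key))
        print(f"{key}: AUC {m.auc:.3f}, sensitivity {m.sensitivity:.1%}, "
              f"specificity {m.specificity:.1%}; predictors: "
              f"{', '.join(m.predictors) or '(intercept only)'}")

    with open(common.RESULTS / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1)
    pd.concat(roc_rows).to_csv(common.RESULTS / "roc_curves.tsv", sep="\t",
                               index=False)


if __name__ == "__main__":
    main()
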