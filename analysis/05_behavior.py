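"""Relate altered DFC variability to cognition in the patient groups.

Mean variability is extracted from every surviving post-hoc cluster and
partially correlated (age, sex, education controlled) with the four
cognitive-domain composites over the pooled SCD + aMCI subjects, with
Bonferroni correction over the cluster x domain family.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import common
from tripledfc.behavior import behavior_correlations
from tripledfc.inference import covariate_matrix

DOMAINS = ["EM", "EF", "IPS", "VF"]


def main() -> None:
    data = common.load_arrays("dfc")
    try:
        cmasks = common.load_arrays("cluster_masks")
    except FileNotFoundError:
        print("no surviving clusters; nothing to correlate")
        return
    table = pd.read_csv(common.RESULTS / "participants.tsv", sep="\t")
    table = table[table.subject_id.isin(data["subjects"])].reset_index(drop=True)

    extracts = pd.DataFrame({
        name: data[f"var_{name.split(':')[0]}"].astype(float)[
            :, cmasks[name]].mean(axis=1)
        for name in cmasks.files})
    patients = table["group"].isin(["SCD", "aMCI"]).to_numpy()
    covars = covariate_matrix(table)
    out = behavior_correlations(extracts.loc[patients].reset_index(drop=True),
                                table.loc[patients, DOMAINS].reset_index(drop=True),
                                covars[patients])
    out.to_csv(common.RESULTS / "behavior.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))
    sig = out[out.significant]
    print(f"\n{len(sig)} Bonferroni-significant association(s)")


if __name__ == "__main__":
    main()
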