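"""Three-group ANCOVA and post-hoc pairwise tests within each network.

Per network: voxel-wise partial F for the group factor (age, sex, education
as covariates) with Freedman-Lane permutations and cluster-extent
correction; post-hoc two-sample tests inside the ANCOVA mask with
TFCE-FWE.  Cluster tables go to results/clusters.tsv, cluster masks to
scratch for the behaviour and classification stages.

At this miniature scale the extent rules are scaled with the geometry
(10 / 5 voxels instead of the full-grid 20 / 10).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import common
from tripledfc.inference import (InferenceConfig, covariate_matrix,
                                 permutation_cluster_threshold,
                                 posthoc_pairwise)

CONTRASTS = (("HC", "SCD"), ("HC", "aMCI"), ("SCD", "aMCI"))


def main() -> None:
    d = common.design()
    data = common.load_arrays("dfc")
    tmpl = common.load_arrays("templates")
    table = pd.read_csv(common.RESULTS / "participants.tsv", sep="\t")
    table = table[table.subject_id.isin(data["subjects"])].reset_index(drop=True)
    groups = table["group"]
    covars = covariate_matrix(table)
    rng = np.random.default_rng(common.SEED + 1)
    cfg = InferenceConfig(n_perm=common.N_PERM, ancova_min_voxels=10,
                          posthoc_min_voxels=5)

    all_rows, cluster_masks = [], {}
    for net in ("aDMN", "pDMN", "SN", "ECN"):
        maps = data[f"var_{net}"].astype(float)
        anc, _ = permutation_cluster_threshold(
            maps, groups, covars, tmpl[net], d.affine, d.voxel_size_mm,
            cfg, rng)
        labels = anc.attrs["labels"]
        anc_mask = np.zeros(tmpl[net].shape, dtype=bool)
        for _, row in anc.iterrows():
            anc_mask |= labels == row.cluster_id
            all_rows.append({"network": net, "analysis": "ANCOVA", **row})
        if not anc_mask.any():
            print(f"{net}: no ANCOVA clusters")
            continue
        for pair in CONTRASTS:
            pt, _ = posthoc_pairwise(maps, groups, pair, covars, anc_mask,
                                     d.affine, d.voxel_size_mm, cfg, rng)
            plabels = pt.attrs["labels"]
            for _, row in pt.iterrows():
                name = f"{net}:{pair[1]}v{pair[0]}:c{int(row.cluster_id)}"
                cluster_masks[name] = plabels == int(row.cluster_id)
                all_rows.append({"network": net,
                                 "analysis": f"{pair[1]} vs {pair[0]}", **row})

    clusters = pd.DataFrame(all_rows)
    clusters.to_csv(common.RESULTS / "clusters.tsv", sep="\t", index=False)
    if cluster_masks:
        common.save_arrays("cluster_masks", **cluster_masks)
    with pd.option_context("display.width", 120):
        print(clusters.round(3).to_string(index=False) if len(clusters)
              else "no surviving clusters")


if __name__ == "__main__":
    main()
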