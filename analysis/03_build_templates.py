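"""Define the four network templates from the control group.

One-sample t-tests on the HC static Fisher-z maps with sign-flip
permutations, TFCE enhancement and FWE correction; voxels with
significantly positive connectivity form each network's template.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import common
from tripledfc.networks import one_sample_template


def main() -> None:
    data = common.load_arrays("dfc")
    gm = data["gm"]
    rng = np.random.default_rng(common.SEED)
    masks, rows = {}, []
    for net in ("aDMN", "pDMN", "SN", "ECN"):
        tmpl = one_sample_template(data[f"hcz_{net}"].astype(float), net, gm,
                                   n_perm=max(common.N_PERM, 100),
                                   alpha=0.05, rng=rng)
        masks[net] = tmpl.mask
        rows.append({"network": net, "n_voxels": int(tmpl.mask.sum()),
                     "n_subjects": tmpl.n_subjects,
                     "n_permutations": tmpl.n_permutations})
    common.save_arrays("templates", **masks)
    table = pd.DataFrame(rows)
    table.to_csv(common.RESULTS / "templates.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"(GM mask: {int(gm.sum())} voxels)")


if __name__ == "__main__":
    main()
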