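"""Preprocess every subject and compute per-network DFC variability maps.

Each run is discarded to 230 volumes, detrended, nuisance-regressed
(Friston-24 + tissue means), band-passed to 0.01-0.08 Hz and smoothed;
sliding 40-TR windows in steps of 2 give 96 windowed Fisher-z values per
voxel, whose standard deviation is the DFC variability map.  Also computes
the HC static z-maps needed for template definition.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import common
from tripledfc import synth
from tripledfc.dfc import make_windows, variability_map
from tripledfc.networks import make_seed_mask, seed_timeseries, static_fc_zmap
from tripledfc.preproc import PreprocParams, preprocess_subject


def main() -> None:
    common.ensure_dirs()
    d = common.design()
    tissue = synth.tissue_masks(d)
    scheme = make_windows(d.n_volumes - d.n_discard, d.window_width, 2)
    pre = PreprocParams()
    print(f"windows per run: {scheme.n_windows} "
          f"(width {scheme.width} TRs, step {scheme.step})")

    var_maps = {s.network: [] for s in d.seed_specs}
    hc_z = {s.network: [] for s in d.seed_specs}
    kept, excluded = [], []
    for rec, raw, motion, _ in synth.iter_subjects(d):
        clean = preprocess_subject(raw, motion, tissue, pre)
        if clean is None:
            excluded.append(rec["subject_id"])
            continue
        kept.append(rec["subject_id"])
        for seed in d.seed_specs:
            if rec["group"] == "HC":
                smask = make_seed_mask(seed, clean.data.shape[:3], clean.affine)
                ts = seed_timeseries(clean, smask)
                hc_z[seed.network].append(static_fc_zmap(clean, ts, tissue["GM"]))
            var_maps[seed.network].append(
                variability_map(clean, seed, scheme, tissue["GM"]))

    common.save_arrays(
        "dfc",
        subjects=np.array(kept),
        gm=tissue["GM"],
        **{f"var_{net}": np.stack(v).astype(np.float32)
           for net, v in var_maps.items()},
        **{f"hcz_{net}": np.stack(v).astype(np.float32)
           for net, v in hc_z.items()},
    )
    print(f"preprocessed {len(kept)} subjects; excluded for motion: "
          f"{excluded or 'none'}")
    for net, v in var_maps.items():
        stack = np.stack(v)
        print(f"  {net}: mean in-GM variability "
              f"{stack[:, tissue['GM']].mean():.3f}")


if __name__ == "__main__":
    main()
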