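"""Validate the inference machinery: null calibration and recovery rates.

Runs the Monte-Carlo studies at reduced scale — family-wise false-positive
rates for the ANCOVA-cluster and post-hoc TFCE paths under the
exchangeable null, plus detection / sign / correlation / AUC recovery of
the injected ground truth — and writes the rates to results/.
Repeat counts here are kept small for a quick narrative run; the test
suite and scripts/acceptance.py run the full 200-repeat versions.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import common
from tripledfc import studies


def main() -> None:
    common.ensure_dirs()
    anc = studies.null_ancova_fwe(n_repeats=100, seed=common.SEED)
    post = studies.null_posthoc_fwe(n_repeats=50, seed=common.SEED)
    rec = studies.recovery_study(n_repeats=10, seed=common.SEED)
    out = {
        "ancova_null_fwe": anc,
        "posthoc_null_fwe": post,
        "recovery": {
            "detection_rate": rec.detection_rate,
            "sign_correct_rate": rec.sign_correct_rate,
            "partial_r_em": rec.partial_r_em,
            "partial_r_ef": rec.partial_r_ef,
            "mean_aucs": rec.mean_aucs,
            "auc_above_0.8_rates": rec.auc_rates,
            "n_repeats": rec.n_repeats,
        },
    }
    with open(common.RESULTS / "validation.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
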