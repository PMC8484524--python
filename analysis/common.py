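"""Shared paths and the study design used by the numbered analysis drivers.

The drivers run the full chain at a reduced desk scale: an 18^3 grid with
proportionally remapped seed coordinates, 12/10/11 subjects, and 199
permutations, so the whole sequence completes in a few minutes on one CPU.
Intermediate arrays live under scratch/ (not part of the deliverable);
tables and summaries go to results/.
"""

from pathlib import Path

import numpy as np

from tripledfc import synth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20260921
N_PERM = 199
GROUP_SIZES = {"HC": 20, "SCD": 16, "aMCI": 18}  # ~1/3 of the full cohort
GRID = (18, 18, 18)


def design() -> synth.CohortDesign:
    return synth.compact_design(grid_shape=GRID, group_sizes=GROUP_SIZES,
                                rng_seed=SEED)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def save_arrays(name: str, **arrays) -> Path:
    ensure_dirs()
    path = SCRATCH / f"{name}.npz"
    np.savez_compressed(path, **arrays)
    return path


def load_arrays(name: str):
    return np.load(SCRATCH / f"{name}.npz", allow_pickle=False)
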