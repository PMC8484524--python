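"""Synthetic resting-state cohort generator with known dynamic-connectivity truth.

The generator emulates a three-group (HC / SCD / aMCI) resting-state fMRI
study: per subject an 8-minute BOLD run (240 volumes at TR = 2 s) on a 3 mm
isotropic MNI-like grid, a 6-parameter motion trace, and cognitive-domain
composite scores.  Network structure is seed-driven: each network's seed
carries a band-limited (0.01-0.08 Hz) latent signal s(t); designated target
regions receive ``c(t) * s(t)`` plus thermal noise, where the coupling
``c(t) = mu + A * m(t)`` fluctuates through a slow two-state modulator m(t).
The fluctuation amplitude ``A`` depends on (group, region), which is what the
downstream variability analysis is meant to recover.  Cognitive composites
are linear functions of the injected subject-level amplitudes plus noise, so
behaviour-stage correlations are recoverable by construction.

Ground truth (amplitudes, couplings) is stored alongside the dataset for
recovery tests and is never consumed by the analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tripledfc.core import BoldImage, compact_grid, mni_3mm_grid, remap_mni

GROUPS = ("HC", "SCD", "aMCI")


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed ROI at a fixed MNI centre."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0
    network: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


#: The four canonical seeds defining the triple-network model.
DEFAULT_SEEDS = (
    SeedSpec("vmPFC", (0.0, 52.0, -6.0), 10.0, "aDMN"),
    SeedSpec("PCC", (0.0, -53.0, 26.0), 10.0, "pDMN"),
    SeedSpec("rAI", (38.0, 22.0, -10.0), 10.0, "SN"),
    SeedSpec("DLPFC", (48.0, 12.0, 34.0), 10.0, "ECN"),
)


@dataclass(frozen=True)
class RegionEffect:
    """A network target region with group-dependent coupling fluctuation.

    ``mu`` is the static seed-voxel coupling; ``amplitude[g]`` the coupling
    fluctuation amplitude injected for group ``g``.
    """

    name: str
    network: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    mu: float
    amplitude: dict[str, float]


def _default_effect_table(region_radius: float = 9.0) -> tuple[RegionEffect, ...]:
    """Group-amplitude profiles mirroring the direction of the clinical findings.

    aMCI loses coupling dynamics in anterior-DMN regions, SCD in the posterior
    DMN; both patient groups gain dynamics in salience regions; executive
    regions carry the graded HC < SCD < aMCI profile that drives the cognitive
    correlations.
    """

    def eff(name, network, center, hc, scd, amci):
        return RegionEffect(name, network, center, region_radius, 0.4,
                            {"HC": hc, "SCD": scd, "aMCI": amci})

    return (
        eff("right_angular", "aDMN", (42.0, -51.0, 24.0), 0.30, 0.30, 0.12),
        eff("right_SFG", "aDMN", (24.0, 39.0, 33.0), 0.30, 0.30, 0.12),
        eff("right_MTG", "pDMN", (66.0, -45.0, 0.0), 0.30, 0.12, 0.25),
        eff("left_putamen", "SN", (-30.0, -3.0, -3.0), 0.10, 0.30, 0.30),
        eff("left_insula", "SN", (-45.0, 12.0, 3.0), 0.10, 0.30, 0.15),
        eff("left_IFG", "ECN", (-39.0, 9.0, 24.0), 0.10, 0.25, 0.40),
        eff("right_MFG", "ECN", (33.0, 54.0, 9.0), 0.10, 0.30, 0.10),
    )


#: Cognitive-domain generating model: domain -> (intercept, {region: slope}, noise sd).
#: Episodic memory and executive function decline with executive-region
#: fluctuation amplitude (negative slopes); processing speed and visuospatial
#: function track the anterior-DMN amplitude that aMCI loses.
DEFAULT_COGNITIVE_MODEL: dict[str, tuple[float, dict[str, float], float]] = {
    "EM": (0.70, {"left_IFG": -5.0}, 0.8),
    "EF": (0.58, {"left_IFG": -4.0}, 0.8),
    "IPS": (-0.70, {"right_angular": 3.0}, 0.8),
    "VF": (-0.50, {"right_angular": 2.0}, 0.9),
}

#: Per-group demographic distributions: (age mean, age sd, edu mean, edu sd,
#: male fraction), matched to a typical memory-clinic cohort.
DEFAULT_DEMOGRAPHICS: dict[str, tuple[float, float, float, float, float]] = {
    "HC": (63.3, 6.3, 12.4, 2.5, 25 / 58),
    "SCD": (66.0, 7.8, 12.3, 2.6, 8 / 44),
    "aMCI": (63.6, 7.6, 11.0, 3.0, 13 / 49),
}


@dataclass
class CohortDesign:
    """Full parameterisation of a synthetic cohort.

    The defaults reproduce the study conditions: 58/44/49 subjects, 240
    volumes at TR = 2 s (8 min), 3 mm isotropic grid, four 10-mm network
    seeds, and a 40-TR analysis window after discarding 10 volumes.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 58, "SCD": 44, "aMCI": 49})
    n_volumes: int = 240
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (61, 73, 61)
    voxel_size_mm: float = 3.0
    affine: np.ndarray | None = None
    seed_specs: tuple[SeedSpec, ...] = DEFAULT_SEEDS
    effect_table: tuple[RegionEffect, ...] = field(default_factory=_default_effect_table)
    cognitive_model: dict = field(default_factory=lambda: dict(DEFAULT_COGNITIVE_MODEL))
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    noise_sd: float = 1.0
    seed_noise_sd: float = 1.0
    amplitude_jitter: float = 0.05
    dwell_s: float = 40.0
    modulator: str = "markov"  # or "sinusoid"
    band_hz: tuple[float, float] = (0.01, 0.08)
    hrf: bool = False
    motion_sd: float = 0.02
    n_discard: int = 10
    window_width: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.affine is None:
            full_shape, full_affine = mni_3mm_grid()
            if tuple(self.grid_shape) == full_shape:
                self.affine = full_affine
            else:
                self.affine = compact_grid(self.grid_shape, self.voxel_size_mm)
        self.validate()

    def validate(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must all be positive")
        if any(g not in GROUPS for g in self.group_sizes):
            raise ValueError(f"unknown group label in {tuple(self.group_sizes)}")
        if self.n_volumes - self.n_discard <= self.window_width:
            raise ValueError(
                "n_volumes must exceed the analysis window after volume discard")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.modulator not in ("markov", "sinusoid"):
            raise ValueError("modulator must be 'markov' or 'sinusoid'")
        for reg in self.effect_table:
            ijk = np.linalg.inv(self.affine) @ np.r_[reg.center_mm, 1.0]
            if np.any(ijk[:3] < -0.5) or np.any(ijk[:3] > np.array(self.grid_shape) - 0.5):
                raise ValueError(f"effect region {reg.name!r} lies outside the grid")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(s.network for s in self.seed_specs)


def compact_design(grid_shape: tuple[int, int, int] = (18, 18, 18),
                   group_sizes: dict[str, int] | None = None,
                   seed_radius: float = 6.0,
                   region_radius: float = 5.0,
                   **kwargs) -> CohortDesign:
    """Miniature design for fixtures: coordinates remapped proportionally
    from the full MNI bounding box onto a small grid, sphere radii shrunk so
    seeds and regions stay disjoint."""
    seeds = tuple(
        SeedSpec(s.name, remap_mni(s.center_mm, grid_shape), seed_radius, s.network)
        for s in DEFAULT_SEEDS
    )
    effects = tuple(
        RegionEffect(r.name, r.network, remap_mni(r.center_mm, grid_shape),
                     region_radius, r.mu, dict(r.amplitude))
        for r in _default_effect_table()
    )
    sizes = group_sizes or {"HC": 8, "SCD": 8, "aMCI": 8}
    return CohortDesign(group_sizes=sizes, grid_shape=grid_shape,
                        seed_specs=seeds, effect_table=effects, **kwargs)


@dataclass
class GroundTruth:
    """Generating parameters stored next to a dataset for recovery tests.

    Never consumed by any analysis stage.
    """

    subject_id: str
    group: str
    amplitudes: dict[str, float]  # region -> subject-level A
    mus: dict[str, float]
    modulators: dict[str, np.ndarray] | None = None  # region -> m(t), in-memory only

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "amplitudes": {k: float(v) for k, v in self.amplitudes.items()},
            "mus": {k: float(v) for k, v in self.mus.items()},
        }


def band_limited_noise(n: int, tr: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band via FFT."""
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(x)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def markov_modulator(n: int, tr: float, dwell_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Two-state +/-1 Markov switching signal with mean dwell time ``dwell_s``."""
    p_switch = min(1.0, tr / dwell_s)
    flips = rng.random(n) < p_switch
    state = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0)
    return state if rng.random() < 0.5 else -state


def sinusoid_modulator(n: int, tr: float, dwell_s: float,
                       rng: np.random.Generator) -> np.ndarray:
    # period = two dwell times, random phase
    t = np.arange(n) * tr
    phase = rng.uniform(0, 2 * np.pi)
    return np.sin(2 * np.pi * t / (2 * dwell_s) + phase)


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response function sampled at TR."""
    from scipy.stats import gamma

    t = np.arange(0, duration_s, tr)
    h = gamma.pdf(t, 6) - gamma.pdf(t, 16) / 6.0
    return h / h.sum()


def _sphere_mask(center_mm, radius_mm, shape, affine) -> np.ndarray:
    ijk = np.indices(shape).reshape(3, -1).T
    xyz = (np.c_[ijk, np.ones(len(ijk))] @ np.asarray(affine).T)[:, :3]
    d2 = ((xyz - np.asarray(center_mm)) ** 2).sum(axis=1)
    return (d2 <= radius_mm ** 2).reshape(shape)


def simulate_subject(design: CohortDesign, group: str, subject_seed: int,
                     subject_id: str = "sub-000"
                     ) -> tuple[BoldImage, np.ndarray, GroundTruth]:
    """Simulate one subject's BOLD run, motion trace and ground truth.

    The output is a pure function of ``(design, group, subject_seed)``.
    """
    if group not in design.group_sizes:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(subject_seed)
    T = design.n_volumes
    shape = tuple(design.grid_shape)
    affine = design.affine

    # latent band-limited seed signals, one per network
    latents = {
        s.network: band_limited_noise(T, design.tr, design.band_hz, rng)
        for s in design.seed_specs
    }
    if design.hrf:
        h = canonical_hrf(design.tr)
        for k, v in latents.items():
            x = np.convolve(v, h)[:T]
            latents[k] = (x - x.mean()) / (x.std() or 1.0)

    data = rng.normal(0.0, design.noise_sd, size=shape + (T,))

    # seed spheres carry the latent signal itself (plus the thermal noise)
    for s in design.seed_specs:
        m = _sphere_mask(s.center_mm, s.radius_mm, shape, affine)
        if not m.any():
            raise ValueError(f"seed {s.name!r} falls outside the grid")
        data[m] += latents[s.network]

    mod_fn = markov_modulator if design.modulator == "markov" else sinusoid_modulator
    amplitudes, mus, modulators = {}, {}, {}
    for reg in design.effect_table:
        a_group = reg.amplitude[group]
        a_subj = float(np.clip(rng.normal(a_group, design.amplitude_jitter), 0.0, 1.0))
        m_t = mod_fn(T, design.tr, design.dwell_s, rng)
        c_t = reg.mu + a_subj * m_t
        mask = _sphere_mask(reg.center_mm, reg.radius_mm, shape, affine)
        data[mask] += c_t * latents[reg.network]
        amplitudes[reg.name] = a_subj
        mus[reg.name] = reg.mu
        modulators[reg.name] = m_t

    # bounded random-walk motion: reflect at +/-2 to stay under exclusion limits
    steps = rng.normal(0.0, design.motion_sd, size=(T, 6))
    motion = _fold(np.cumsum(steps, axis=0), 2.0)
    img = BoldImage(data, affine, design.tr)
    truth = GroundTruth(subject_id, group, amplitudes, mus, modulators)
    return img, motion, truth


def _fold(x: np.ndarray, bound: float) -> np.ndarray:
    """Reflect an unbounded walk into [-bound, bound] (triangle fold)."""
    y = np.mod(x + bound, 4.0 * bound)
    return np.where(y < 2.0 * bound, y - bound, 3.0 * bound - y)


def tissue_masks(design: CohortDesign) -> dict[str, np.ndarray]:
    """Synthetic GM / WM / CSF label masks on the design grid.

    GM is everything network-related plus a surrounding shell; WM and CSF are
    disjoint corner blocks used only as nuisance-signal sources.
    """
    shape = tuple(design.grid_shape)
    gm = np.zeros(shape, dtype=bool)
    for s in design.seed_specs:
        gm |= _sphere_mask(s.center_mm, s.radius_mm * 2.0, shape, design.affine)
    for r in design.effect_table:
        gm |= _sphere_mask(r.center_mm, r.radius_mm * 2.0, shape, design.affine)
    nz = max(1, shape[2] // 6)
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    wm[: shape[0] // 4, : shape[1] // 4, :nz] = True
    csf[-(shape[0] // 4):, -(shape[1] // 4):, :nz] = True
    wm &= ~gm
    csf &= ~gm & ~wm
    return {"GM": gm, "WM": wm, "CSF": csf}


def region_mask(design: CohortDesign, region_name: str) -> np.ndarray:
    """Ground-truth voxel mask of a named effect region."""
    for r in design.effect_table:
        if r.name == region_name:
            return _sphere_mask(r.center_mm, r.radius_mm,
                                tuple(design.grid_shape), design.affine)
    raise KeyError(region_name)


def _subject_seeds(design: CohortDesign) -> list[int]:
    ss = np.random.SeedSequence(design.rng_seed)
    return [int(s) for s in ss.generate_state(design.n_subjects) % (2 ** 31)]


def subject_table(design: CohortDesign) -> pd.DataFrame:
    """Demographics + group labels, deterministic in the design seed."""
    rng = np.random.default_rng(np.random.SeedSequence((design.rng_seed, 7001)))
    rows = []
    i = 0
    for group in GROUPS:
        n = design.group_sizes.get(group, 0)
        age_m, age_sd, edu_m, edu_sd, male_frac = design.demographics[group]
        for _ in range(n):
            i += 1
            rows.append({
                "subject_id": f"sub-{i:03d}",
                "group": group,
                "age": round(float(np.clip(rng.normal(age_m, age_sd), 50, 90)), 1),
                "sex": int(rng.random() < male_frac),  # 1 = male
                "education": round(float(np.clip(rng.normal(edu_m, edu_sd), 6, 22)), 1),
            })
    return pd.DataFrame(rows)


def cognitive_scores(design: CohortDesign, truths: list[GroundTruth]) -> pd.DataFrame:
    """Domain composites as linear functions of injected amplitudes plus noise."""
    rng = np.random.default_rng(np.random.SeedSequence((design.rng_seed, 7002)))
    rows = []
    for t in truths:
        row = {"subject_id": t.subject_id}
        for domain, (b0, slopes, noise) in design.cognitive_model.items():
            val = b0 + sum(k * t.amplitudes[reg] for reg, k in slopes.items())
            row[domain] = float(val + rng.normal(0.0, noise))
        rows.append(row)
    return pd.DataFrame(rows)


def iter_subjects(design: CohortDesign):
    """Yield ``(record, BoldImage, motion, GroundTruth)`` per subject.

    Record order is HC block, SCD block, aMCI block, matching
    :func:`subject_table`.
    """
    table = subject_table(design)
    seeds = _subject_seeds(design)
    for (idx, rec), seed in zip(table.iterrows(), seeds):
        img, motion, truth = simulate_subject(design, rec["group"], seed,
                                              subject_id=rec["subject_id"])
        yield rec, img, motion, truth


def simulate_cohort(design: CohortDesign, out_dir: str | Path
                    ) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Write a full cohort to disk: per-subject NIfTI + motion text, a TSV
    subject table with cognitive composites, and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    records = []
    for rec, img, motion, truth in iter_subjects(design):
        sid = rec["subject_id"]
        img.save(out / f"{sid}_bold.nii.gz")
        np.savetxt(out / f"{sid}_motion.txt", motion, fmt="%.6f")
        truths.append(truth)
        records.append(rec)
    table = pd.DataFrame(records).reset_index(drop=True)
    cog = cognitive_scores(design, truths)
    table = table.merge(cog, on="subject_id")
    table.to_csv(out / "participants.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump([t.to_json_dict() for t in truths], fh, indent=1)
    return table, truths


def cohort_table(design: CohortDesign, truths: list[GroundTruth]) -> pd.DataFrame:
    """In-memory equivalent of the participants table written by
    :func:`simulate_cohort`."""
    table = subject_table(design)
    return table.merge(cognitive_scores(design, truths), on="subject_id")
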