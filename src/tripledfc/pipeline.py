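"""End-to-end orchestration: simulate -> preprocess -> templates -> DFC ->
group inference -> behaviour -> classification, from a single config.

Every stage parameter has the study default baked in (10 discarded volumes,
0.01-0.08 Hz band, 6 mm FWHM, 40-TR windows in steps of 2, 1000
permutations, 20- and 10-voxel extent rules) and is overridable.  A manifest
records the verbatim config, package versions and the global seed so a rerun
with the same config reproduces all deterministic outputs.
"""

from __future__ import annotations

import json
import hashlib
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tripledfc
from tripledfc import synth
from tripledfc.behavior import behavior_correlations
from tripledfc.classify import classify_contrast
from tripledfc.dfc import make_windows, variability_map
from tripledfc.inference import (InferenceConfig, cluster_voxels,
                                 covariate_matrix, permutation_cluster_threshold,
                                 posthoc_pairwise)
from tripledfc.preproc import PreprocParams, preprocess_subject

CONTRASTS = (("HC", "SCD"), ("HC", "aMCI"), ("SCD", "aMCI"))


@dataclass
class RunConfig:
    """Single-run configuration; defaults are the study conditions."""

    out_dir: str = "derivatives"
    seed: int = 0
    # cohort scale ('full' uses the 61x73x61 grid and 58/44/49 subjects)
    scale: str = "compact"            # 'full' or 'compact'
    grid_shape: tuple[int, int, int] = (18, 18, 18)
    group_sizes: dict | None = None   # None -> scale default
    n_volumes: int = 240
    tr: float = 2.0
    # preprocessing
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 6.0
    motion_limit: tuple[float, float] = (3.0, 3.0)
    # windows
    width: int = 40
    step: int = 2
    # inference
    n_perm: int = 1000
    template_n_perm: int | None = None  # None -> n_perm
    alpha: float = 0.05
    ancova_min_voxels: int = 20
    posthoc_min_voxels: int = 10
    # outputs
    write_maps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def design(self) -> synth.CohortDesign:
        if self.scale == "full":
            sizes = self.group_sizes or {"HC": 58, "SCD": 44, "aMCI": 49}
            return synth.CohortDesign(group_sizes=dict(sizes),
                                      n_volumes=self.n_volumes, tr=self.tr,
                                      n_discard=self.n_discard,
                                      window_width=self.width,
                                      rng_seed=self.seed)
        sizes = self.group_sizes or {"HC": 8, "SCD": 8, "aMCI": 8}
        return synth.compact_design(grid_shape=tuple(self.grid_shape),
                                    group_sizes=dict(sizes),
                                    n_volumes=self.n_volumes, tr=self.tr,
                                    n_discard=self.n_discard,
                                    window_width=self.width,
                                    rng_seed=self.seed)


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory results and writes tables,
    masks and a manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 5150)))
    pre = PreprocParams(n_discard=config.n_discard,
                        trans_limit_mm=config.motion_limit[0],
                        rot_limit_deg=config.motion_limit[1],
                        band=tuple(config.band), fwhm_mm=config.fwhm_mm)
    tissue = synth.tissue_masks(design)
    scheme = make_windows(config.n_volumes - config.n_discard,
                          config.width, config.step)

    # ---- simulate + preprocess + per-subject maps (single pass)
    from tripledfc.networks import make_seed_mask, seed_timeseries, static_fc_zmap

    records, truths = [], []
    hc_zmaps = {s.network: [] for s in design.seed_specs}
    var_maps = {s.network: [] for s in design.seed_specs}
    excluded = []
    for rec, img, motion, truth in synth.iter_subjects(design):
        clean = preprocess_subject(img, motion, tissue, pre)
        if clean is None:
            excluded.append(rec["subject_id"])
            continue
        records.append(rec)
        truths.append(truth)
        for seed in design.seed_specs:
            smask = make_seed_mask(seed, clean.data.shape[:3], clean.affine)
            ts = seed_timeseries(clean, smask)
            if rec["group"] == "HC":
                hc_zmaps[seed.network].append(
                    static_fc_zmap(clean, ts, tissue["GM"]))
            var_maps[seed.network].append(
                variability_map(clean, seed, scheme, tissue["GM"]).astype(np.float32))

    table = pd.DataFrame(records).reset_index(drop=True)
    table = table.merge(synth.cognitive_scores(design, truths), on="subject_id")
    table.to_csv(out / "participants.tsv", sep="\t", index=False)
    groups = table["group"]
    covars = covariate_matrix(table)

    # ---- network templates from the HC group
    tmpl_nperm = config.template_n_perm or config.n_perm
    templates = {}
    for seed in design.seed_specs:
        from tripledfc.networks import one_sample_template
        templates[seed.network] = one_sample_template(
            np.stack(hc_zmaps[seed.network]), seed.network, tissue["GM"],
            tmpl_nperm, config.alpha, rng=rng)
        if templates[seed.network].is_empty:
            raise RuntimeError(f"templates stage: empty {seed.network} template")

    # ---- group inference per network
    icfg = InferenceConfig(n_perm=config.n_perm,
                           voxel_alpha=config.alpha,
                           cluster_alpha=config.alpha,
                           ancova_min_voxels=config.ancova_min_voxels,
                           posthoc_alpha=config.alpha,
                           posthoc_min_voxels=config.posthoc_min_voxels)
    cluster_masks: dict[str, np.ndarray] = {}
    all_tables = []
    inference_out = {}
    for net, tmpl in templates.items():
        maps = np.stack(var_maps[net]).astype(float)
        anc_table, anc_extras = permutation_cluster_threshold(
            maps, groups, covars, tmpl.mask, design.affine,
            design.voxel_size_mm, icfg, rng)
        labels = anc_table.attrs.get("labels")
        flat = anc_table.assign(network=net, analysis="ANCOVA")
        flat.attrs = {}
        all_tables.append(flat)
        anc_mask = np.zeros(tmpl.mask.shape, dtype=bool)
        post_tables = {}
        if len(anc_table):
            for cid in anc_table["cluster_id"]:
                anc_mask |= labels == cid
            for pair in CONTRASTS:
                pt, _ = posthoc_pairwise(maps, groups, pair, covars, anc_mask,
                                         design.affine, design.voxel_size_mm,
                                         icfg, rng)
                post_tables[pair] = pt
                flat = pt.assign(network=net, analysis=f"{pair[1]} vs {pair[0]}")
                flat.attrs = {}
                all_tables.append(flat)
                for _, row in pt.iterrows():
                    cid = f"{net}:{pair[1]}v{pair[0]}:c{int(row.cluster_id)}"
                    cluster_masks[cid] = cluster_voxels(pt, int(row.cluster_id))
        inference_out[net] = {"ancova": anc_table, "posthoc": post_tables,
                              "ancova_mask": anc_mask, "maps": maps}
    clusters = pd.concat(all_tables, ignore_index=True) if all_tables else pd.DataFrame()
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)

    # ---- behaviour: extracts from surviving clusters, SCD+aMCI pooled
    domains = list(design.cognitive_model)
    behavior_table = pd.DataFrame()
    extracts = pd.DataFrame()
    if cluster_masks:
        net_of = {cid: cid.split(":")[0] for cid in cluster_masks}
        extracts = pd.DataFrame({
            cid: np.stack(var_maps[net_of[cid]]).astype(float)[
                :, cluster_masks[cid]].mean(axis=1)
            for cid in cluster_masks})
        patients = groups.isin(["SCD", "aMCI"]).to_numpy()
        behavior_table = behavior_correlations(
            extracts.loc[patients].reset_index(drop=True),
            table.loc[patients, domains].reset_index(drop=True),
            covars[patients], config.alpha)
        behavior_table.to_csv(out / "behavior.tsv", sep="\t", index=False)

    # ---- classification per contrast
    features = pd.concat([extracts, table[domains]], axis=1)
    classification = {}
    for pair in CONTRASTS:
        res = classify_contrast(features, groups, pair, config.alpha)
        classification[pair] = res
    report = {
        f"{p[0]}_vs_{p[1]}": {
            "auc": r["multivariable"].auc,
            "sensitivity": r["multivariable"].sensitivity,
            "specificity": r["multivariable"].specificity,
            "predictors": r["multivariable"].predictors,
            "univariate": {k: {"lr_p": v["lr_p"], "auc": v["auc"]}
                           for k, v in r["univariate"].items()},
        } for p, r in classification.items()}
    with open(out / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1)

    manifest = {
        "package_version": tripledfc.__version__,
        "python": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_subjects": int(len(table)),
        "excluded": excluded,
        "n_windows": scheme.n_windows,
        "participants_sha256": hashlib.sha256(
            table.to_csv(index=False).encode()).hexdigest(),
        "clusters_sha256": hashlib.sha256(
            clusters.to_csv(index=False).encode()).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    if config.write_maps:
        import nibabel as nib
        for net, tmpl in templates.items():
            nib.save(nib.Nifti1Image(tmpl.mask.astype(np.uint8), design.affine),
                     str(out / f"template_{net}.nii.gz"))

    return {"design": design, "table": table, "templates": templates,
            "scheme": scheme, "inference": inference_out,
            "behavior": behavior_table, "extracts": extracts,
            "classification": classification, "manifest": manifest,
            "cluster_masks": cluster_masks}
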