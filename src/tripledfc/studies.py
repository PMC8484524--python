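"""Monte-Carlo study routines: null calibration and ground-truth recovery.

These are the simulation experiments the synthetic generator exists for:

* *Calibration* — under an exchangeable null (no group effect) the
  family-wise false-positive rate of the ANCOVA permutation-cluster path
  and of the post-hoc TFCE-FWE path must stay at or below the nominal
  alpha, within binomial tolerance.
* *Recovery* — the injected group difference in coupling-fluctuation
  amplitude must be detected (surviving cluster overlapping the designated
  region, correct sign), injected negative amplitude-cognition coupling
  must yield a negative partial correlation, and the multivariable
  classifier must discriminate every contrast.

All routines run at a deliberately reduced scale (miniature grid, 6-12
subjects per group, 99 permutations) so hundreds of repeats are feasible;
they are shared by the test suite, the analysis drivers and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from tripledfc import synth
from tripledfc.behavior import partial_correlation
from tripledfc.classify import classify_contrast
from tripledfc.dfc import make_windows, variability_map
from tripledfc.inference import (InferenceConfig, covariate_matrix,
                                 permutation_cluster_threshold,
                                 posthoc_pairwise)
from tripledfc.networks import (make_seed_mask, one_sample_template,
                                seed_timeseries, static_fc_zmap)
from tripledfc.preproc import PreprocParams, preprocess_subject

#: ECN regions whose amplitude profiles differ between SCD and aMCI; the
#: designated targets of the recovery studies.
DESIGNATED_REGIONS = ("left_IFG", "right_MFG")

#: Region -> network of the seed whose variability map carries its signal.
REGION_NETWORK = {
    "right_angular": "aDMN", "right_SFG": "aDMN", "right_MTG": "pDMN",
    "left_putamen": "SN", "left_insula": "SN",
    "left_IFG": "ECN", "right_MFG": "ECN",
}


def _smooth_null_maps(rng, n, shape, sigma=1.0):
    """Spatially smooth Gaussian null maps, unit-variance, shape (n, *shape)."""
    maps = rng.standard_normal((n, *shape))
    if sigma > 0:
        maps = np.stack([ndimage.gaussian_filter(m, sigma) for m in maps])
        maps /= maps.std()
    return maps


def _random_covariates(rng, n):
    age = rng.normal(64, 7, n)
    sex = (rng.random(n) < 0.5).astype(float)
    edu = rng.normal(12, 2.5, n)
    C = np.column_stack([age, sex, edu])
    return C - C.mean(axis=0)


def _null_groups(n_per_group):
    return pd.Series(["HC"] * n_per_group + ["SCD"] * n_per_group +
                     ["aMCI"] * n_per_group)


def null_ancova_fwe(n_repeats: int = 200, n_per_group: int = 6,
                    grid: tuple[int, int, int] = (12, 12, 12),
                    n_perm: int = 99, smooth_sigma: float = 1.0,
                    seed: int = 0) -> dict:
    """Family-wise false-positive rate of the ANCOVA cluster path under the
    exchangeable null (identical map distribution in all groups)."""
    rng = np.random.default_rng(seed)
    cfg = InferenceConfig(n_perm=n_perm)
    affine = np.eye(4) * 3.0
    affine[3, 3] = 1.0
    mask = np.ones(grid, dtype=bool)
    groups = _null_groups(n_per_group)
    n = 3 * n_per_group
    hits = 0
    for _ in range(n_repeats):
        maps = _smooth_null_maps(rng, n, grid, smooth_sigma)
        C = _random_covariates(rng, n)
        table, _ = permutation_cluster_threshold(
            maps, groups, C, mask, affine, 3.0, cfg, rng)
        hits += int(len(table) > 0)
    return _rate_summary(hits, n_repeats)


def null_posthoc_fwe(n_repeats: int = 200, n_per_group: int = 8,
                     grid: tuple[int, int, int] = (12, 12, 12),
                     n_perm: int = 99, smooth_sigma: float = 1.0,
                     seed: int = 0) -> dict:
    """Family-wise false-positive rate of the post-hoc TFCE-FWE path for a
    pair of identically distributed groups (any suprathreshold voxel)."""
    rng = np.random.default_rng(seed)
    cfg = InferenceConfig(n_perm=n_perm)
    affine = np.eye(4) * 3.0
    affine[3, 3] = 1.0
    mask = np.ones(grid, dtype=bool)
    groups = pd.Series(["HC"] * n_per_group + ["aMCI"] * n_per_group)
    n = 2 * n_per_group
    voxel_hits = 0
    cluster_hits = 0
    for _ in range(n_repeats):
        maps = _smooth_null_maps(rng, n, grid, smooth_sigma)
        C = _random_covariates(rng, n)
        table, extras = posthoc_pairwise(maps, groups, ("HC", "aMCI"), C,
                                         mask, affine, 3.0, cfg, rng)
        voxel_hits += int(extras["supra"].any())
        cluster_hits += int(len(table) > 0)
    out = _rate_summary(voxel_hits, n_repeats)
    out["cluster_rate"] = cluster_hits / n_repeats
    return out


def null_template_fwe(n_repeats: int = 200, n_subjects: int = 10,
                      grid: tuple[int, int, int] = (10, 10, 10),
                      n_perm: int = 100, seed: int = 0) -> dict:
    """FWE rate of the one-sample template inference on pure-noise maps."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_repeats):
        zmaps = rng.standard_normal((n_subjects, *grid))
        tmpl = one_sample_template(zmaps, "null", None, n_perm, 0.05, rng=rng)
        hits += int(not tmpl.is_empty)  # any surviving voxel is an FWE error
    return _rate_summary(hits, n_repeats)


def _rate_summary(hits: int, n: int) -> dict:
    rate = hits / n
    se = float(np.sqrt(max(rate, 0.05) * (1 - max(rate, 0.05)) / n))
    return {"rate": rate, "hits": hits, "n_repeats": n, "binomial_se": se}


@dataclass
class RecoveryResult:
    detection_rate: float
    sign_correct_rate: float
    partial_r_em: float
    partial_r_ef: float
    auc_rates: dict
    mean_aucs: dict
    n_repeats: int


def recovery_study(n_repeats: int = 20, n_per_group: int = 25,
                   grid: tuple[int, int, int] = (14, 14, 14),
                   n_perm: int = 99, template_n_perm: int = 100,
                   seed: int = 0, auc_threshold: float = 0.8) -> RecoveryResult:
    """Ground-truth recovery at reduced scale.

    Per repeat: simulate a compact cohort, preprocess, compute per-network
    seed variability maps, build the ECN template from the HC group, run the
    three-group ANCOVA within it, and ask whether a surviving cluster
    overlaps a designated executive region.  The sign check uses the
    strongest injected contrast: the HC-vs-aMCI post hoc must show a
    surviving cluster over the left IFG with positive t (aMCI > HC, the
    injected direction).  ROI-mean variability in the designated left IFG
    (an a-priori ROI, each region read from its own network's map) is
    partially correlated with the EM / EF composites over the pooled
    patient groups, and the ROI features plus composites feed the three
    diagnostic contrasts.
    """
    master = np.random.SeedSequence(seed)
    # extent rules scaled to the miniature grid: the full-scale 20- and
    # 10-voxel extents assume a whole-brain template; here the ground-truth
    # region itself is ~20 voxels, so extents are halved proportionally
    cfg = InferenceConfig(n_perm=n_perm, ancova_min_voxels=10,
                          posthoc_min_voxels=5)
    detections, signs = [], []
    r_em_all, r_ef_all = [], []
    aucs = {pair: [] for pair in (("HC", "SCD"), ("HC", "aMCI"), ("SCD", "aMCI"))}
    for rep_ss in master.spawn(n_repeats):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2 ** 31))
        design = synth.compact_design(
            grid_shape=grid, group_sizes={g: n_per_group for g in synth.GROUPS},
            rng_seed=rep_seed)
        rng = np.random.default_rng(rep_seed)
        tissue = synth.tissue_masks(design)
        gm = tissue["GM"]
        scheme = make_windows(design.n_volumes - design.n_discard,
                              design.window_width, 2)
        seeds = {s.network: s for s in design.seed_specs}

        records, truths = [], []
        hc_z, var_stack = [], []
        roi_masks = {r: synth.region_mask(design, r) & gm
                     for r in ("left_IFG", "right_MFG", "left_putamen",
                               "right_angular", "right_MTG")}
        roi_features = {r: [] for r in roi_masks}
        pre = PreprocParams(n_discard=design.n_discard)
        for rec, raw, motion, truth in synth.iter_subjects(design):
            img = preprocess_subject(raw, motion, tissue, pre)
            if img is None:
                continue
            records.append(rec)
            truths.append(truth)
            net_maps = {}
            for net in set(REGION_NETWORK.values()):
                net_maps[net] = variability_map(img, seeds[net], scheme, gm)
            if rec["group"] == "HC":
                smask = make_seed_mask(seeds["ECN"], img.data.shape[:3], img.affine)
                hc_z.append(static_fc_zmap(img, seed_timeseries(img, smask), gm))
            var_stack.append(net_maps["ECN"])
            for r, m in roi_masks.items():
                vm = net_maps[REGION_NETWORK[r]]
                roi_features[r].append(vm[m].mean() if m.any() else 0.0)

        table = pd.DataFrame(records).reset_index(drop=True)
        table = table.merge(synth.cognitive_scores(design, truths),
                            on="subject_id")
        groups = table["group"]
        covars = covariate_matrix(table)
        maps = np.stack(var_stack)

        tmpl = one_sample_template(np.stack(hc_z), "ECN", gm,
                                   template_n_perm, 0.05, rng=rng)
        anc_table, _ = permutation_cluster_threshold(
            maps, groups, covars, tmpl.mask, design.affine,
            design.voxel_size_mm, cfg, rng)
        labels = anc_table.attrs.get("labels")
        target_ifg = synth.region_mask(design, "left_IFG")
        target_mfg = synth.region_mask(design, "right_MFG")
        detected = False
        anc_mask = np.zeros(tmpl.mask.shape, dtype=bool)
        for cid in anc_table["cluster_id"]:
            cmask = labels == cid
            anc_mask |= cmask
            if (cmask & (target_ifg | target_mfg)).any():
                detected = True
        detections.append(detected)

        sign_ok = False
        if detected:
            pt, _ = posthoc_pairwise(maps, groups, ("HC", "aMCI"), covars,
                                     anc_mask, design.affine,
                                     design.voxel_size_mm, cfg, rng)
            plabels = pt.attrs.get("labels")
            for _, row in pt.iterrows():
                cmask = plabels == int(row.cluster_id)
                # aMCI coded as the second group: positive t = aMCI > HC,
                # the injected direction in the left IFG
                if (cmask & target_ifg).any() and row.peak_stat > 0:
                    sign_ok = True
        signs.append(sign_ok)

        patients = groups.isin(["SCD", "aMCI"]).to_numpy()
        ifg_extract = np.asarray(roi_features["left_IFG"])
        r_em, _ = partial_correlation(ifg_extract[patients],
                                      table.loc[patients, "EM"].to_numpy(),
                                      covars[patients])
        r_ef, _ = partial_correlation(ifg_extract[patients],
                                      table.loc[patients, "EF"].to_numpy(),
                                      covars[patients])
        r_em_all.append(r_em)
        r_ef_all.append(r_ef)

        features = pd.DataFrame(roi_features)
        features[list(design.cognitive_model)] = table[list(design.cognitive_model)]
        for pair in aucs:
            res = classify_contrast(features, groups, pair)
            aucs[pair].append(res["multivariable"].auc)

    return RecoveryResult(
        detection_rate=float(np.mean(detections)),
        sign_correct_rate=float(np.mean(signs)),
        partial_r_em=float(np.mean(r_em_all)),
        partial_r_ef=float(np.mean(r_ef_all)),
        auc_rates={f"{a}_vs_{b}": float(np.mean(np.asarray(v) > auc_threshold))
                   for (a, b), v in aucs.items()},
        mean_aucs={f"{a}_vs_{b}": float(np.mean(v)) for (a, b), v in aucs.items()},
        n_repeats=n_repeats,
    )
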