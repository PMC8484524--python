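# tripledfc

Seed-based **dynamic functional connectivity (DFC) variability** analysis of
the triple-network model — anterior/posterior default mode (aDMN/pDMN),
salience (SN) and executive control (ECN) networks — for three-group
resting-state fMRI studies of the preclinical Alzheimer's spectrum (healthy
controls, subjective cognitive decline, amnestic mild cognitive impairment:
HC / SCD / aMCI), together with a fully synthetic cohort generator so the
entire chain is testable without any clinical data.

## Who this is for

Researchers who want a tested, reproducible implementation of the
sliding-window DFC variability pipeline — from 4D BOLD input to group
inference, brain–behaviour correlation and diagnostic classification — and a
ground-truth simulator to validate it (or their own variant) end to end.

## The statistic

For each network seed (10-mm spheres at vmPFC (0, 52, −6), PCC (0, −53, 26),
right anterior insula (38, 22, −10), right DLPFC (48, 12, 34)), the
windowed connectivity of voxel *v* in window *k* is

    z_k(v) = atanh( corr(seed_ts[k], v_ts[k]) ),

over rectangular windows of 40 TRs slid in steps of 2 TR — 96 windows for an
8-minute run at TR = 2 s after discarding 10 volumes.  **DFC variability**
is the sample standard deviation of z₁…z_K per voxel.  Group differences in
these maps are tested inside HC-derived network templates with a
covariate-adjusted (age, sex, education) ANCOVA under Freedman–Lane
permutations and cluster-extent correction (≥ 20 voxels, 540 mm³), followed
by pairwise post-hoc tests with TFCE–FWE (p < 0.05, > 9 voxels, 243 mm³).
Surviving-cluster extracts feed partial correlations with cognitive-domain
composites (Bonferroni-corrected) and logistic-regression diagnosis with
likelihood-ratio backward elimination and ROC/AUC summaries.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(18³ grid with proportionally remapped coordinates, 20/16/18 subjects,
199 permutations; tables land in `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_and_dfc.py
python analysis/03_build_templates.py
python analysis/04_group_inference.py
python analysis/05_behavior.py
python analysis/06_classification.py
python analysis/07_validation.py
```

Driver 02 prints the window bookkeeping and preprocessing outcome:

```
windows per run: 96 (width 40 TRs, step 2)
preprocessed 54 subjects; excluded for motion: none
```

Driver 04 prints the surviving clusters (coordinates are in the miniature
grid's remapped space).  With the default generator the directional pattern
is: aMCI loses aDMN dynamics, SCD loses pDMN dynamics, both patient groups
gain SN dynamics, and executive regions carry a graded HC < SCD < aMCI
profile:

```
network    analysis  cluster_id  n_voxels  size_mm3  peak_stat  p_corrected
   aDMN      ANCOVA         8.0      25.0     675.0      9.557        0.015
   aDMN  aMCI vs HC         1.0      20.0     540.0     -4.411
   aDMN aMCI vs SCD         1.0      20.0     540.0     -4.425
   pDMN      ANCOVA         2.0      22.0     594.0      7.119        0.015
   pDMN   SCD vs HC         1.0      17.0     459.0     -4.159
     SN      ANCOVA         1.0      63.0    1701.0     13.280        0.005
     SN   SCD vs HC         1.0      47.0    1269.0      5.053
     SN  aMCI vs HC         1.0      34.0     918.0      5.015
    ECN      ANCOVA         1.0      41.0    1107.0     14.040        0.005
    ECN   SCD vs HC         1.0      23.0     621.0      3.995
    ECN  aMCI vs HC         1.0      37.0     999.0      6.390
```

A negative t means the second-named group has *lower* DFC variability.
Driver 05 relates cluster extracts to cognition in the pooled patient
groups: the executive-network clusters correlate negatively with executive
function (r ≈ −0.37, uncorrected p ≈ 0.04 at this reduced n; the full-scale
validation study below recovers the negative coupling reliably).  Driver 06
prints the diagnostic models:

```
HC_vs_SCD:   AUC 1.000, sensitivity 100.0%, specificity 100.0%
HC_vs_aMCI:  AUC 1.000, sensitivity 100.0%, specificity 100.0%
SCD_vs_aMCI: AUC 0.924, sensitivity 77.8%, specificity 93.8%
```

(In-sample AUCs at n ≈ 50 are optimistic by construction; see
`docs/methods.md`.)

A single-command equivalent of the whole chain, with a manifest and
reproducible seeding, is available as a library call or CLI:

```sh
tripledfc run --out derivatives --seed 1 --nperm 199
tripledfc simulate --out dataset --seed 1   # just write a synthetic cohort
```

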