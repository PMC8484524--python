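# Methods

## Scientific setting

The package implements a seed-based dynamic functional connectivity (DFC)
variability analysis of the triple-network model — the default mode network
(split into anterior and posterior subsystems, aDMN/pDMN), the salience
network (SN) and the executive control network (ECN) — for three-group
resting-state fMRI studies of the preclinical Alzheimer's spectrum (healthy
controls, subjective cognitive decline, amnestic mild cognitive impairment:
HC / SCD / aMCI).  The per-voxel statistic of interest is the standard
deviation across sliding windows of the Fisher-z–transformed correlation
between the voxel and a network seed: a voxel whose coupling to the seed
fluctuates over the scan has high DFC variability.

Because the cohorts such analyses run on are private clinical datasets, the
package is organised around a synthetic-cohort generator with known ground
truth.  Every downstream stage — preprocessing, template definition, DFC
variability, permutation inference, behavioural correlation, diagnostic
classification — is exercised and validated end-to-end on generated data.

## Synthetic cohort generator (`tripledfc.synth`)

**Acquisition model.** Default conditions: 58/44/49 subjects (HC/SCD/aMCI),
240 volumes at TR = 2 s (8 minutes), 3 mm isotropic grid (61×73×61 MNI-like
by default; miniature grids with proportionally remapped coordinates for
fixtures).  The first 10 volumes are treated as dummies and discarded in
preprocessing, leaving 230 time points.

**Signal model.** Each network has a latent band-limited (0.01–0.08 Hz)
unit-variance signal s(t) carried by a 10-mm spherical seed (vmPFC (0, 52,
−6) → aDMN; PCC (0, −53, 26) → pDMN; right anterior insula (38, 22, −10) →
SN; right DLPFC (48, 12, 34) → ECN).  Designated target regions (9-mm
spheres at canonical coordinates: right angular gyrus and right SFG in the
aDMN, right MTG in the pDMN, left putamen and left insula in the SN, left
IFG and right MFG in the ECN) receive

    v(t) = c(t) · s(t) + ε(t),   c(t) = μ + A · m(t),

with thermal noise ε ~ N(0, 1), static coupling μ = 0.4, and a slow
modulator m(t): a two-state ±1 Markov switch with mean dwell 40 s
(a sinusoidal mode is available).  The fluctuation amplitude A depends on
(group, region) and carries the group differences the inference stage must
recover; subject-level amplitudes jitter around the group mean (sd 0.05).
All other voxels contain pure noise.  Haemodynamic convolution is off by
default — the latent signals are already band-limited, which is what the
windowed-correlation estimator sees — and can be enabled (double-gamma HRF).

**Default amplitude profiles** (HC / SCD / aMCI): right angular & right SFG
0.30/0.30/0.12 (aMCI loses anterior-DMN dynamics); right MTG 0.30/0.12/0.25
(SCD loses posterior-DMN dynamics); left putamen 0.10/0.30/0.30 and left
insula 0.10/0.30/0.15 (patients gain salience dynamics); left IFG
0.10/0.25/0.40 and right MFG 0.10/0.30/0.10 (graded executive profile).

**Why these numbers.** The estimation noise floor of a windowed correlation
at width 40 TRs on band-limited data is ≈ 0.15–0.3 z-units (the band
0.01–0.08 Hz leaves roughly 2·BW·T ≈ 11 effective degrees of freedom per
80-s window).  With μ = 0.4 and unit noise, an amplitude step of 0.15–0.3
moves the windowed correlation by ~0.1–0.3 z-units — comparable to, up to
about twice, the noise floor.  This places group effects in the regime the
corresponding clinical studies report (pairwise t ≈ 3–6, F ≈ 6–12 at n ≈
50/group) rather than making them trivially large.

**Cognition.** Domain composites (EM episodic memory, EF executive
function, IPS processing speed, VF visuospatial function) are linear
functions of the subject's injected amplitudes plus Gaussian noise:
EM = 0.70 − 5·A(left IFG), EF = 0.58 − 4·A(left IFG) (noise sd 0.8);
IPS = −0.70 + 3·A(right angular), VF = −0.50 + 2·A(right angular) (noise
0.8/0.9).  The negative executive couplings make EM/EF decline as left-IFG
variability rises, so the behaviour stage must recover negative partial
correlations; the slopes put the attainable partial r near −0.3 to −0.5,
the range typical of such studies.  Demographics (age, sex, education) are
drawn per group from distributions matched to a memory-clinic cohort, so
demographic tables behave realistically (sex imbalance, education gradient).

**Determinism.** The whole cohort is a pure function of (design, rng_seed):
per-subject seeds derive from a `SeedSequence`, and the demographic and
cognitive draws use fixed sub-streams.  Ground truth (per-subject
amplitudes, couplings) is written next to the dataset and is never read by
any analysis stage.

**What the generator does not emulate.** Scanner artifacts (spikes, drift
beyond linear trend, physiological noise), realistic anatomy and tissue
contrast, spatial noise correlation beyond what smoothing introduces,
HRF variability, and — importantly — the possibility that real group
differences are smaller, spatially diffuse, or confounded.  Passing
recovery tests therefore demonstrates that the *pipeline* is correct and
calibrated, not that the clinical effect sizes are attainable in new data.

## Preprocessing (`tripledfc.preproc`)

Fixed order: discard (10 volumes) → linear detrend → nuisance regression →
ideal FFT band-pass 0.01–0.08 Hz → Gaussian smoothing (6 mm FWHM).  All
temporal operators are linear.  Nuisance columns: the Friston-24 expansion
of the six rigid motion parameters ([p(t), p(t−1), p(t)², p(t−1)²], lagged
terms zero-filled at the first volume) plus global/WM/CSF means from
supplied tissue masks (synthetic datasets ship GM/WM/CSF labels; with real
data the user supplies masks).  Subjects whose displacement relative to the
first retained volume exceeds 3 mm translation or 3° rotation on any axis
are excluded.  Detrending precedes the ideal filter because a rectangular
frequency mask on a trending series leaks the trend across the band; the
filter itself is the DPABI/REST-style ideal band-pass (a Butterworth option
would change edge behaviour only).  Smoothing is applied last so nuisance
estimates are not spatially mixed.

## Network templates (`tripledfc.networks`)

Per subject: the seed-mean time series is correlated with every GM voxel
and Fisher-z transformed (correlations clipped at |r| = 1 − 1e−7 so seed
self-correlations stay finite).  The HC-group z-maps enter a one-sample
t-test against zero; inference is by random sign flips (exact under the
symmetric null), TFCE enhancement of each permuted t-map, and family-wise
error control via the max-TFCE null distribution (the observed labelling is
included, so the smallest attainable p is 1/(n_perm+1)).  The template is
the set of voxels with positive t and FWE-corrected p < 0.05.  Templates
may legitimately come out empty (e.g. all-negative maps); the pipeline
treats an empty template as a hard error.

## Sliding-window DFC variability (`tripledfc.dfc`)

Rectangular (untapered) windows of 40 TRs slid in steps of 2; with 230
retained volumes this gives exactly 96 windows (K = ⌊(T−width)/step⌋ + 1;
trailing samples that do not complete a window are dropped).  Windowed
Pearson correlations are computed with prefix sums (O(TV) per subject,
independent of window count), clipped, and Fisher-z transformed; windows
with zero variance yield z = 0.  DFC variability is the sample standard
deviation (denominator K−1) of the K z-values — the convention of the
dynamic-connectivity toolboxes this field uses.  Maps are left on their raw
scale (no across-voxel standardisation); a flag exists to standardise.

## Group inference (`tripledfc.inference`)

**ANCOVA path.** Per voxel, the partial F for the group factor from a
nested GLM comparison: full model = intercept + mean-centred age/sex/
education + two group indicators; reduced = covariates only (df = 2,
N−6).  Permutation inference follows Freedman–Lane: residuals of the
reduced model are permuted and added back to the reduced-model fit, and the
F-map is recomputed per permutation.  Clusters are formed at voxel-wise
permutation p < 0.05 (per-voxel rank of the observed F within its own
permutation distribution), and cluster-level significance is assessed
against the max-cluster-size null, with an extent rule of ≥ 20 voxels
(540 mm³ at 3 mm).  A TFCE-based ANCOVA path is available behind a flag;
the extent-based path is the default.

**Post-hoc path.** Within the union of surviving ANCOVA clusters,
covariate-adjusted two-sample t-tests per pair of groups, Freedman–Lane
permutations, signed TFCE, two-sided max-|TFCE| FWE correction at p < 0.05,
and a > 9-voxel (243 mm³) extent rule.

**TFCE.** TFCE(v) = Σ_h e(v,h)^E · h^H · dh with the field-standard
defaults H = 2, E = 0.5, dh = map-max/100, 26-connectivity; negative values
are enhanced on the negated map and re-negated.  Peak coordinates break
ties toward the first voxel in lexicographic index order; cluster tables
report size in voxels and mm³ (voxels × voxel-size³, exact).

**Demographic statistics.** Pearson chi-squared without continuity
correction for count tables; one-way ANOVA reconstructed from per-group
(n, mean, sd) summary rows (SSB from group means about the grand mean,
SSW = Σ(nᵢ−1)sdᵢ²) — this reproduces published subject-table statistics
from their printed summaries.

## Behaviour (`tripledfc.behavior`)

Composites are means of per-test z-scores against a reference population
(HC by default; whole-sample optional).  Mean variability is extracted from
surviving clusters (unweighted masked mean), and partial correlations
(Pearson on residuals after regressing out age/sex/education + intercept;
two-sided t on n−k−2 df) relate extracts to composites over the pooled
SCD+aMCI subjects, Bonferroni-corrected over the full cluster × domain
family.

## Classification (`tripledfc.classify`)

Binary logistic regression per contrast (HC vs SCD, HC vs aMCI, SCD vs
aMCI), predictors standardised.  Univariately significant predictors
(likelihood-ratio p < 0.05 against the intercept-only model) enter the
multivariable model, which is pruned by likelihood-ratio backward
elimination (drop the predictor with the largest LR p while that p ≥ 0.05;
ties break to column order; an intercept-only model is a legal outcome).
Complete separation — common at small n with strong effects — is detected
via perfect prediction and handled by a weakly ridge-penalised Newton fit
rather than an error.  Discrimination is summarised in-sample (matching how
such clinical models are usually reported): ROC curve, trapezoidal AUC, and
sensitivity/specificity at the operating point maximising Youden's J (ties
broken toward higher sensitivity).  A cross-validated ROC is out of scope
by design.

## Validation studies (`tripledfc.studies`)

Run at a deliberately reduced scale so hundreds of repeats fit on one CPU:

* **Null calibration.** With identical map distributions in all groups
  (spatially smoothed Gaussian noise, random covariates), the family-wise
  false-positive rate of the ANCOVA cluster path (any retained cluster) and
  of the post-hoc TFCE-FWE path (any suprathreshold voxel) must stay at or
  below 0.05 within binomial tolerance — 200 repeats, 12³ grid, 6–8
  subjects/group, 99 permutations.  Both paths run well below the nominal
  level in practice; `scripts/acceptance.py` and `analysis/07_validation.py`
  print the measured rates for a given seed.
* **Recovery.** Fresh cohorts (14³ grid, 25 subjects/group — about half the
  full cohort — 99 permutations, 20 repeats): the ECN ANCOVA must produce a
  surviving cluster overlapping a designated executive region, the HC-vs-
  aMCI post hoc must mark the left IFG with positive t (the injected
  direction), ROI-mean left-IFG variability must correlate negatively with
  EM/EF over pooled patients, and the multivariable classifier must exceed
  AUC 0.8 for every contrast.  The designated regions are read as a-priori
  ROIs (each from its own network's seed map); ground-truth amplitudes are
  never used.

**Scaled parameters at fixture scale.** Three analysis parameters are
scaled along with the geometry of the miniature grids, because their
full-scale values are meaningless there: the extent rules (20/10 voxels on
a ~50 000-voxel brain become 10/5 on a ~1 400-voxel GM mask where a
ground-truth region is itself only ~20 voxels), and the recovery cohort
size (chosen so the per-repeat detection power is ≳95%, the power a
full-size cohort has for the injected effects; at 12–15/group the
ANCOVA-with-extent path is visibly underpowered).  The published-scale
defaults are used everywhere else and are what `InferenceConfig` ships
with.

## Numerical choices and degenerate inputs

* Correlation clip 1 − 1e−7 before atanh (bounds |z| ≈ 8.4).
* Zero-variance voxels/windows → r = 0 (flagged by construction).
* Rank-deficient designs: collinear columns dropped with a warning
  (nuisance regression) or pruned silently after QR (inference designs).
* Permutation p-values always include the observed statistic.
* Voxel-wise permutation p uses rank-within-pool, so the cluster-forming
  threshold adapts per voxel.
* Motion traces are bounded random walks (reflected at ±2 mm/°), so default
  synthetic subjects are never excluded; exclusion is tested with
  constructed traces.

## Known limitations

* In-sample AUCs at small n are optimistic (often 1.0); they demonstrate
  pipeline correctness, not expected out-of-sample accuracy.
* The generator's spatial structure is spherical and noise is white, so
  cluster shapes and smoothness-dependent corrections are exercised only in
  the regime smoothing creates.
* The ideal band-pass assumes stationarity over the run; very short series
  (< ~3 window widths) make the variability estimate itself noisy.
* Real-data use requires user-supplied tissue masks and normalised input;
  segmentation, realignment and slice timing are out of scope.
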