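# Methods

This note records the modelling choices behind each stage, what the
synthetic cohort does and does not emulate, and the numerical conventions
that a re-implementation would need to reproduce results exactly.

## Synthetic cohort generator

The generator is the package's substitute for an access-restricted
population biobank; it emulates the *structure* of such data, not the
biology of individual analytes.

**Group structure.** Each participant is drawn into one of six ground-truth
groups (HFpEF 6.7%, HFrEF 0.1%, diabetic 2.0%, obese 7.7%, non-HF control,
and a lean background remainder that phenotypes as non-HF control). Group
demographics (age, BMI, sex fraction) follow the emulated cohort's baseline
table; control groups are truncated below the BMI 30 obesity cut so that the
control definitions are satisfiable by construction.

**NT-proBNP** is log-normal: controls exp(N(4.8, 0.8²)) (median ≈ 120
pg/ml), HF cases exp(N(7.4, 0.5²)) (median ≈ 1600 pg/ml, the typical
heart-failure range). The mixture's 90th-percentile quantile is available in
closed form (`ntprobnp_theoretical_quantile`) and the generated marginal
converges to it (tested at n = 20 000 within 2% on the mean over seeds —
the single-draw order-statistic SE at that n is itself ≈ 2%). Imaging-route
HFpEF plants redraw their NT-proBNP above 1.05× that quantile so the
percentile criterion holds by construction; this affects ~1% of case draws
and leaves the marginal essentially unchanged.

**Phenotyping plants.** A configurable fraction (default 100%) of HFpEF
cases satisfies the decision tree via one of three routes (default mix
0.5/0.3/0.2): preserved-EF imaging plus elevated NT-proBNP; no imaging with
pre-test risk > 0.90 (atrial fibrillation + obesity + age > 60); no imaging
with risk in (0.70, 0.90] plus a heart-failure diagnostic code. 77.9% of
cases are asymptomatic at recruitment; their symptom onset is an exponential
delay with mean 6.3 years. The exponential choice makes the onset SD equal
its mean (6.3 y), which is wider than the dispersion a real cohort shows;
lead-time *means* are therefore comparable but onset SDs are not.

**Omics blocks.** Features are standard normal noise plus planted shifts.
Three families are disjoint by construction:

* *disease signal*: 3/10/30/40 features per modality shifted ±0.8 SD in all
  HFpEF cases — the targets of the deconfounding "deconfounded" call;
* *confound-only*: ten metabolomic features shifted −2.0 SD in users of a
  statin-like medication (46.3% of HFpEF, 7.9% of non-HF controls use it).
  The 2-SD user-level shift matches the pharmacology of cholesterol-lowering
  therapy and induces a ≈ 0.8-SD apparent disease contrast that disappears
  when stratified on use — the defining property of a planted confounder;
* *cluster signatures*: a shared per-modality feature block (10/40/180/230)
  on which each of the 6 HFpEF clusters has a ±1 SD sign-pattern centroid,
  scaled 1.0 in the cluster's dominant modality, 0.35 elsewhere (cluster 2
  is balanced at 0.7 everywhere). Shared blocks with independent sign
  patterns give expected between-cluster separation 2·s·δ² per modality and
  let 13 phenomics features carry six distinguishable centroids, which
  disjoint per-cluster blocks cannot.

**Missingness** is MCAR within modality (2%) plus whole-block proteomics
missingness (default 10%). The emulated study's proteomics subcohort rate
(~89%) would leave too few complete-modality subjects at desk scale; the
rate is a config knob. **Survival** is exponential per group (e.g. HFpEF
base hazard 0.0235/y → ≈ 28% mortality over ~14 y) scaled by cluster
multipliers (cluster 2: 3.2 → ≈ 65% mortality; cluster 6: 0.48 → ≈ 15%),
censored uniformly at 12.5–15.5 y.

What passing tests on this cohort shows: the *procedures* (labeling logic,
fusion, nested LRTs, enrichment rules, CV protocol) recover known planted
structure at realistic sizes and noise. What it does not show: performance
on real biobank data, where effects are weaker, missingness is informative,
and confounding is plural and correlated.

## Phenotyping

The percentile rule uses linear interpolation between order statistics
(NumPy's default), with missing values excluded from the reference; a
cohort with no measured NT-proBNP gets an infinite threshold (the criterion
can never fire) rather than an error. The pre-test probability is the
point-score variant of the H2FPEF score: weights obesity 2, hypertension
(≥ 2 antihypertensive classes) 1, atrial fibrillation 3, pulmonary
hypertension 1, age > 60 1, elevated filling pressure 1; the score→
probability table is an approximation of the published nomogram, monotone
and overridable — with no echocardiography in the data model the filling-
pressure component is recorded as absent in the audit trail. Control groups
are exclusive in the order HFrEF evidence > type-2 diabetes > BMI ≥ 30 >
non-HF. The stratified 80/20 split uses largest-remainder rounding per
stratum, so every stratum's train fraction is within one participant of the
target.

## Similarity network fusion

Kernel conventions are pinned in `snf.py`: scaled exponential kernel with
the three-term adaptive bandwidth; full kernels row-normalized with
self-affinity ½; sparse kernels keep the K nearest neighbours with rows
renormalized; cross-diffusion for t iterations with symmetrization and
renormalization each step; the fused network is the average of the final
kernels (its final symmetrization leaves rows stochastic to within a few
percent). Defaults K = 20, μ = 0.5, t = 20 follow common SNF practice and
are configurable. Features are z-scored per modality before distances
(scale invariance is tested); within-modality missing entries are
median-imputed *for distance computation only*; samples missing an entire
modality are dropped — only complete-modality subjects are clustered.
Spectral clustering uses the normalized Laplacian with row-normalized
eigenvector embedding and k-means (fixed seed, 10 restarts); "auto" picks k
by the largest eigengap over 2..10. Modality dominance normalizes each
affinity matrix to unit mean off-diagonal, takes each member's argmax of
mean within-cluster affinity across modalities (ties to the first modality
in sorted order), and reports per-cluster fractions; singleton clusters are
reported missing.

## Confounder-aware associations

The naive screen is a two-sided Mann–Whitney U per feature with BH
adjustment within the contrast's feature family; effect sizes are Cliff's
delta computed by the rank identity δ = 2U/(n₁n₂) − 1 (ties half-counted),
which equals the brute-force pair count. Nested LRTs fit Gaussian linear
models on rank-transformed feature values (robust to skewed omics scales; a
raw-scale option exists): disease-beyond-covariate compares
feature ~ covariate vs + disease, covariate-beyond-disease the reverse,
each referred to χ²(1) with statistic n·log(RSS₀/RSS₁). One covariate at a
time, matching a per-covariate "beyond" criterion; binary covariates with
fewer than five positives are skipped for that feature. Status logic:
naive q ≥ 0.1 → no association; disease significant beyond *every*
covariate → deconfounded; some covariate blocks disease while itself
significant → confounded (covariate recorded); otherwise ambiguous —
including the collinear case where neither nested comparison is defined.

## Enrichment

ssGSEA on one ranked profile per group (Cliff's deltas of proteomic
features vs non-HF controls): hits add |score|^α normalized by the in-set
sum (α default 0.75), misses subtract 1/(N − n_set), and the enrichment
score is the *sum* of the running-sum values (integral convention); the
leading edge is the in-set prefix up to the extreme deviation. The null
permutes gene labels (seeded); NES divides ES by the mean |null ES| of
matching sign; empirical two-sided p with the +1 correction; BH within
group. Cluster specificity requires q < 0.05, a deviation of ≥ 1 sample SD
from the pathway's cross-group mean NES, and the strict row extremum (ties
flag nothing). The redundancy filter processes flagged pathways in
descending |NES| and drops any whose leading edge overlaps a retained
pathway by more than 50% of its own size — "enriched genes" is read as
leading-edge genes, the standard GSEA meaning.

## Classifier harness

The learner is a gradient-boosted tree classifier (LightGBM) consuming
missing values natively — no imputation anywhere. Nested CV: stratified
outer folds give the metric estimates, inner folds select from a small
hyperparameter grid (kept to 1–2 configurations at desk scale; the grid is
a config field). The operating threshold maximizes Youden's J on
training-fold predictions. AUC uses the Mann–Whitney rank identity;
aggregate 95% intervals are percentile intervals over folds. DeLong's
paired test uses placement values with tie half-credit; identical score
vectors return p = 1 by convention. RFE halves the feature set by gain
importance until the target count (selection inside training folds).
Reference scores: a logistic age/BMI/atrial-fibrillation score with
representative default coefficients (intercept −9.2, age 0.05/y, BMI
0.14 per kg/m², AF 1.75 — placeholders on the published model's scale,
overridable with published values), and raw NT-proBNP as a ranking score.
SHAP summaries use the tree-path attribution built into the learner
(`pred_contrib`), whose per-sample contributions sum to the raw score; the
direction sketch is the sign of the correlation between feature value and
contribution. Lead time counts only true cases scored above the operating
threshold, with "asymptomatic at recruitment" defined as onset strictly
after day 0.

## Pipeline

One YAML config drives all stages; a single global seed is fanned out per
stage by CRC32 hashing of the stage name (keeping every derived seed below
2³¹ and streams independent). The manifest records, per stage, the
parameters, derived seed, SHA-256 content hashes of outputs, and wall time;
deterministic stages reproduce byte-identical outputs under an identical
config. A stage failure aborts the run naming the stage, retaining earlier
outputs.

## Problem sizes

Default exercises run at n = 2000 participants (≈ 134 HFpEF cases), the
all-HFpEF clustering cohort at n = 1600 with all four modalities complete,
deconfounding recovery over 5 seeds, permutation nulls at 100–1000
permutations, and CV at 5 outer × 3 inner folds with a single-configuration
grid — sizes chosen so the full suite runs on one desktop CPU in minutes
while keeping every planted-recovery margin comfortable.

## Known limitations

* Omics features are independent Gaussians apart from planted shifts; real
  omics have heavy correlation blocks, which changes BH behaviour and makes
  real deconfounding harder than the synthetic benchmark suggests.
* One confounder at a time in the default spec; joint/correlated
  confounding is expressible via multiple `ConfounderSpec` entries but the
  LRT logic remains per-covariate by design.
* The H2FPEF probability table and the age/BMI/AF reference coefficients
  are documented approximations, adequate for ordering/monotonicity
  properties but not for clinical use; both are injectable.
* Exponential symptom onset fixes SD = mean; only lead-time means are
  meaningful against real-world dispersion.
* Cluster-count selection by eigengap is reliable at the planted separation
  but is known to be fragile on weakly separated real data; k is overridable
  everywhere.
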