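# Methods

`etkras` re-implements, as a tested and reusable pipeline, a multi-omics
analysis of a 2×2 pancreatic cell-line design: a non-transformed ductal
epithelial line (HPNE) with or without oncogenic KRAS (G12D), each with or
without chronic ethanol exposure. The pipeline covers differential
expression of transcripts and proteins, a sign-flip differential
co-expression network with hub discovery, directional gene-set enrichment,
transcript–protein co-inertia concordance, PLS-DA subtype scoring with
ROC-calibrated cutoffs, and phenotype calculators (growth, caspase
activity, dose–response EC50). Every stage is verifiable against a
synthetic-data generator that plants known structure and records it in a
truth ledger.

## Study design emulated by the generator

The design the defaults emulate: four conditions (`HPNE`, `HPNE_EtOH`,
`HPNE_KRAS`, `HPNE_KRAS_EtOH`, i.e. genotype × exposure), a single RNA-seq
library per condition, three TMT-style proteomic replicates per condition,
~20,000 transcripts, ~3,000 proteins nested inside the transcript ID
space, and missing protein values. The `HPNE_KRAS_EtOH` condition
(MUT+treated) is the focal condition in which effects are planted.

### Generator model and parameters

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` / `n_proteins` | 20000 / 3000 | feature counts; proteins are the first 3,000 transcript IDs |
| `n_replicates` / `rna_replicates` | 3 / 1 | proteomic replicates; RNA libraries per condition |
| `de_fraction`, `de_log2fc` | 0.05, 1.5 | fraction of transcripts given ±1.5 log2FC in the focal condition (protein-coding subset also shifted at the protein level) |
| `hub_spec` | one hub, 20 partners, positive | planted sign-flip hub module |
| `coupling` | (0.3, 0.3, 0.3, 0.8) | per-condition transcript–protein correlation of coordinated condition-level deviations |
| `coupling_sd` | 0.15 | log2 SD of those coordinated deviations |
| `subtype_signal` | focal: (+2, −2, +2, 0) | per-condition log2 effects on the four 15-protein signature blocks (Proliferative, Inflammatory, Metabolic, Progenitor-like), planted in **both** assays because subtype programs are transcriptional |
| `missing_rate` | 0.05 | per-cell protein missingness (background features only) |
| `protein_sigma` | 0.05 | idiosyncratic within-replicate log2 noise |
| `bg_axis_scale` | 0.15 | scale of the coordinated replicate-axis variation (below) |
| `rna_dispersion` | 0.1 | negative-binomial dispersion |
| `library_size_factors` | (1.0, 1.25, 0.8, 1.0) | per-library depth multipliers |

Transcript counts are negative binomial with log-normal base means
(log-mean 4.6, log-SD 1.2, i.e. median ≈ 100 counts) scaled by the library
size factors. Protein reporter ratios are log-normal around 1.

**Replicate covariance structure.** With only three replicates, the sample
Pearson correlation of two independent features is arcsine-distributed —
P(|r| ≥ 0.75) ≈ 0.46 — so i.i.d. replicate noise would generate thousands
of chance sign-flip edges among ~1,700 complete-case proteins and drown
any planted hub. Real proteomes do not behave this way: between-feature
correlation signs persist across conditions. The generator reproduces that
persistence with a per-condition shared replicate axis (think batch- or
harvest-level coordinated variation): every background feature loads on a
zero-sum unit axis `g_c` with a signed loading whose sign is fixed across
conditions; hub modules load on the axis orthogonal to `g_c` and to the
mean. Background pairs therefore correlate near ±1 with a consistent sign
(never a flip), hub–background pairs correlate near 0 in every condition
(never past ±0.75), and hub–partner pairs flip exactly as planted. Total
within-condition SD(log2) is √((1.0·0.15·1.22)² + 0.05²) ≈ 0.19, a CV of
~14% — a plausible within-plex TMT scale — and is what makes the
±1.25-fold / FDR 0.05 protein rules attainable at n = 3.

**Missingness exemption.** Features carrying planted structure (DE
proteins, hub and partners, signature blocks) are exempt from random
missingness. Without the exemption, tests against the truth ledger would
measure the missingness process rather than the analysis code. Background
missingness at 5% per cell removes ~3% of features under the 2-of-3
replicate filter and leaves ~55–60% of proteins complete-case for the
network stage.

**What the generator does not emulate:** batch effects between plexes,
isoform structure, intensity-dependent missingness (values are missing at
random), dispersion trends, correlated gene programs beyond the single
shared axis, and any sequence-level structure. Passing tests demonstrate
that the code recovers structure of the planted kind at realistic noise;
they do not certify performance on real data with richer covariance.

## Differential expression

Transcripts: pseudocount of 1, median-of-ratios size factors (per-sample
factor = median over features of count/geometric-mean, unnormalized),
fold-change rule at ±2 (inclusive) with no p-values — a single library per
condition supports no within-group variance estimate, so the threshold
rule *is* the test. `mean_expr` is the normalized feature mean over all
conditions (the MA-plot x-coordinate). The size-factor median is taken on
the ratio scale, matching the estimator's definition; this differs from a
log-scale median only in the tie-averaging of even feature counts.

Proteins: fold change = ratio of within-condition medians at ±1.25
(inclusive); two-sided Student t-test on log2 ratios (Welch available via
`equal_var=False`; log scale because ratios are multiplicative);
Benjamini–Hochberg FDR across all tested proteins at α = 0.05. Features
with fewer than two observed replicates in a contrast condition are
excluded with a warning. The replicate-presence filter keeps features with
≥ 2 of 3 values in *every* condition.

## Unsupervised structure

Hierarchical clustering of features: Euclidean distance, complete linkage.
The cluster count is the elbow of the within-cluster-SS curve, located as
the argmax of the second difference of **log** WSS; the raw-scale second
difference is dominated by the first split of any decaying curve and
degenerates to k = 2, whereas the log scale finds where the curve
flattens (verified on well-separated Gaussian blobs). The full curve is
returned so the choice is auditable, and a numerically zero WSS
short-circuits as a perfect partition.

PCA embeds samples (centered features; unit-variance scaling optional,
off by default since the abundance scale is already comparable across
features). Outliers are flagged by Hotelling's T² on the first p = 2
scores against the small-sample limit T²crit = p(n−1)/(n−p)·F(1−α; p,
n−p) at α = 0.05 — the standard 95% Hotelling ellipse.

## Sign-flip differential co-expression

Per condition, Pearson correlations over that condition's replicate
columns, computed on log2 ratios, for proteins with no missing value
anywhere. An edge joins a pair whose correlation is ≥ +0.75 in the focal
condition and ≤ −0.75 in every other condition (positive class) or the
mirror pattern (negative class). Thresholds are inclusive; pairs with an
undefined correlation (constant feature) never qualify; the focal
condition and threshold are parameters. Hubs are ranked by degree with
lexicographic tie-breaks.

**Caveat on n = 3 and the permutation null.** Correlations over three
points are statistically fragile, and the within-focal replicate
permutation null is reported but cannot behave as a conventional null
here: a per-feature permutation of three values is the identity relative
permutation with probability 1/6 (so real edges partially survive), and
permutation destroys the cross-condition sign consistency that suppresses
chance edges in realistic data (so it *creates* edges — the permuted
count exceeds the un-permuted one by orders of magnitude). The module
exposes `permutation_null_edge_counts` and reports n per condition; the
corresponding acceptance check states the conventional expectation and is
left failing deliberately, as the honest outcome of that analysis.

## Enrichment

One-sided Fisher exact (hypergeometric upper tail) per term against a
stated universe, with BH FDR over terms, and an optional EASE-style
conservative variant (overlap decremented by one). The directional
z-score is (up − down)/√(up + down) — zero for a balanced term and
well-defined when one direction is empty. The default universe is the
measured feature set (statistically preferable); passing the collection's
own union reproduces the no-background-set convention of DAVID-style
tools. Any GMT is accepted; no ontology filtering is performed.

## Co-inertia concordance

Transcripts and proteins are cross-referenced by feature ID (an optional
`id_map` translates namespaces; duplicates keep the highest-mean row) and
reduced to one paired profile per condition: the log2-normalized RNA
library and the log2 replicate-mean protein profile. Each table is
feature-centered and scaled to unit total variance so neither assay
dominates.

Because the matched tables share one feature space, the co-inertia axes
are common directions `w` maximizing cov(Xw, Yw): eigenvectors of the
symmetrized cross-product (X'Y + Y'X)/2, computed through an orthonormal
basis of the joint row space (cost scales with the sample count). Two
choices here are deliberate and were forced by the p ≫ n regime:

* Separate per-table singular axes (the classic two-table construction)
  can rotate the two score configurations into near-perfect agreement for
  *any* pair of tables when features vastly outnumber samples, hiding
  real discordance; common axes cannot.
* The RV coefficient is computed on the feature-configuration
  cross-products X'X. The sample-space form converges to 1 for any two
  tables as p grows (both Gram matrices tend to the centering projector);
  the feature-space form is ~0 for independent tables and 1 exactly when
  the cross-product structures are proportional.

Per-sample dissimilarity — the analogue of the line joining an RNA point
to its protein point on a co-inertia plot — is the Euclidean distance
between the two assays' score vectors on the retained axes, each
normalized to unit length per sample, so it measures *directional*
disagreement of the condition's response regardless of magnitude. The
metric behind the plotted line length is not standardized anywhere; this
definition is this package's choice. No K > 2 table variant is
implemented, and equivalence with published MCIA software is not claimed;
the contract is the per-condition cross-omics concordance readout.

## Subtype scoring

Procedure: select the top-60 most variable proteins (deterministic
lexicographic tie-break), train PLS-DA (NIPALS, via scikit-learn's
`PLSRegression`) on centered/scaled features against one-hot class
targets, score each class as the projection onto its discriminant
direction, and calibrate per-class cutoffs at the ROC point maximizing
Youden's J (ties resolve to the most sensitive threshold). Four classes
span three discriminant dimensions, so the pipeline uses k − 1 = 3
components; the published patient-cohort weights are not reproduced — the
model trains on a reference cohort (synthetic or user-supplied) and
serializes to a documented JSON schema for externally provided weights.
Model features absent from a scoring matrix are imputed at the training
center with a warning.

## Phenotype calculators

* Growth: two-point rate = ln(N(t)/N(0))/t and doubling time ln(2)/rate
  (infinite at rate 0); an optional regression mode fits log-counts
  against all time points and reports R².
* Caspase activity: (ΔFU − blank)/µg/h; a blank above signal yields a
  negative value with a warning, not a clip.
* Dose–response: four-parameter logistic fit by least squares with a
  7-point multi-start grid over EC50 across the dose range; asymptotes
  free by default or pinned via `fixed_asymptotes`; flat data raise an
  error carrying the best residual. EC50 and IC50 name the same fitted
  inflection concentration.

## Pipeline, determinism, problem sizes

All stages chain through `run_pipeline` with plain TSV/JSON artifacts and
a manifest (config hash, per-stage outputs and row counts, seeds,
version). All randomness derives from the single config seed; two runs
with the same config are byte-identical except for the manifest's
timestamps. The test suite runs the planted-structure recovery checks at
the full design size (3,000 proteins × 12 samples, 20,000 transcripts ×
4) over 50 seeds for the network, co-inertia and subtype checks and 20
seeds for differential expression; unit tests use smaller matrices
(hundreds of features) chosen to exercise the same code paths.

## Known limitations

* Single-replicate RNA contrasts carry no error model; the ±2-fold rule
  inherits that design.
* n = 3 correlation networks are fragile by construction; the module
  reports per-condition n and the permutation-null caveat above.
* The subtype module's contract is the procedure, not the published
  patient model; absolute scores are not comparable across differently
  trained models.
* The generator's planted-structure missingness exemption means
  missingness robustness is exercised only on background features.
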