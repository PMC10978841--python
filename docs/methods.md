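# Methods

`proxiprof` implements the downstream quantitative analysis of ratiometric
proximity-labeling proteomics: from search-engine protein-group tables of a
catalyst-vs-no-catalyst design to a denoised, annotation-validated
subcellular proteome, orphan-protein candidates, and disease-vs-control
differential tables. This note describes the statistical model behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open.

## The ratiometric model

A proximity-labeling experiment tags proteins near a targeted photocatalyst;
enriched proteins are quantified by stable-isotope dimethyl labeling against
a no-catalyst control, giving every protein group a per-replicate
experimental/control intensity ratio ("+/− catalyst ratio"). True
compartment residents concentrate at high ratios; nonspecifically enriched
background sits near ratio 1. On the log2 scale both classes are
approximately unimodal, so the working model is a two-component Gaussian
mixture on log2 ratios. All denoising operates on this one-dimensional
statistic; proteins detected only in the (+)-catalyst channel carry no
finite ratio and are treated as infinitely ratioed — they rank above every
finite ratio in ROC sweeps and survive any finite cutoff.

### QC and replicate merging

Before any ratio analysis, decoy (reverse) hits, annotated contaminants and
groups with fewer than 2 unique peptides are removed, each with an explicit
per-reason report so that counts are conserved at every stage. Replicates
are merged per protein: a protein must be detected in at least
`min_detections` replicates (default 2 of 3); its `mean_ratio` is the
arithmetic mean of the *linear* per-replicate ratios where the control
channel gave evidence, while per-replicate log2 ratios are kept for
downstream statistics. Proteins quantified only in the control channel have
an undefined enrichment and are removed with a report entry (their ratio
denominatorless counterpart, the only-in-plus protein, is kept and
flagged).

### Annotation-guided cutoff selection

Given a compartment inventory (MitoCarta3.0/UniProt-style annotation
table), the two classes' log2-ratio distributions are profiled, separation
is summarized by a ROC sweep over the ratio (annotated proteins as
positives; trapezoidal AUC, which equals the Mann–Whitney pairwise
concordance with half credit for ties), and the cutoff is chosen as the
*smallest* observed ratio whose retained set reaches a target specificity
(fraction of retained proteins with prior annotation; default target 0.8).
Minimizing the threshold at fixed purity maximizes coverage. Retention is
boundary-inclusive (`mean_ratio >= threshold`). Fixed published cutoffs
(5.0 for cell lines, 2.0/8.0 for mouse kidney/spleen, 7.0 for primary
T cells, 1.2 for the lenient biotinylation filter of the comparative
design) are reproduced by passing a fixed `threshold` instead.

The retained proteome is summarized by its specificity, the annotated share
of summed MS intensity, sub-mitochondrial class counts (matrix* — including
matrix-facing inner-membrane subunits where the input annotation says so —
IMS, MOM, unassigned, non-mito), and coverage of the annotation DB's
matrix* inventory. If the annotation DB contains no matrix* proteins, the
coverage is reported as 0.0 rather than undefined.

### Identifier matching

Quantification tables are matched to annotations by the first accession of
a semicolon-joined majority-ID list, falling back to the gene name. Both
accession- and symbol-keyed annotation tables therefore work; accession is
preferred.

## Orphan discovery

Proteins repeatedly enriched across experiments share a quantitative
signature. Per-replicate log2 ratios from several experiments (e.g. three
cell lines) are stacked into a protein × column matrix, each column
z-scored with the population standard deviation (constant columns become
zeros), and missing entries imputed with the column mean — 0 after
standardization, a neutral value that does not distort ranks. Rows missing
everywhere are dropped with a warning. The matrix is embedded in 2D with
t-SNE (perplexity 20, PCA initialization, fixed `random_state`; the seed is
recorded in all outputs as provenance). A deterministic PCA embedding is
available as an alternative; the scoring downstream is identical.

"Surrounded by annotated proteins" is formalized as a k-nearest-neighbor
vote in the embedding: for each protein, the fraction of its k nearest
Euclidean neighbors (self excluded, distance ties broken by identifier
order) that carry compartment annotation. A protein is an orphan candidate
iff it is unannotated, lacks MAM (mitochondria-associated ER membrane)
evidence — contact-site contamination mimics residency — and its neighbor
fraction reaches `min_fraction`. Defaults k = 10, min_fraction = 0.8, both
configurable; an explicit rule replaces visual inspection because
reproducibility requires one.

## Comparative (triplex) pipeline

A triplex dimethyl design labels condition A (heavy), condition B (medium)
and a no-catalyst control (light) in one MS run. The funnel is: Filter 1 —
per condition, keep proteins with vs-control ratio ≥ 1.2
(boundary-inclusive; lenient on purpose, it only removes clearly
non-biotinylated proteins); Filter 2 — keep proteins biotinylated in both
conditions; then intersect across the (default 3) biologically independent
experiments. For each retained protein, `mean_log2fc` is the mean
per-experiment log2(A/B) and the p-value comes from an unpaired two-tailed
pooled-variance t-test of the per-experiment log2(A/ctrl) values against
the log2(B/ctrl) values (n per group = number of experiments). A one-sample
test of log2(A/B) against zero and Welch's correction are available as
options; with n = 3 per group the pooled Student form is the conventional
default. Raw p-values are reported (Benjamini–Hochberg adjusted values are
emitted as an extra column but not used for filtering). Degenerate
zero-variance cases use p = 1 when the means agree and p = 0 with a
`degenerate` flag when they do not. Proteins with fewer than two complete
experiments are flagged, not dropped. Where all three ratios are present,
H/L is checked against (H/M)·(M/L) and >2-fold inconsistencies are logged.

### Cross-dataset normalization

To place a proteome next to an external reference dataset, each sample
(column) of a proteins × samples intensity table is log2-transformed over
its present proteins and centered on their mean; proteins missing from a
sample are set to 0 on the normalized scale *before* any downstream
averaging. Optional z-scoring for heatmap display is applied per sample
afterwards (the axis is a convention choice; per-sample matches the
z-scoring used for the ratio matrix).

## Label-mass arithmetic

Dimethyl labeling converts each peptide primary amine into a dimethylamine;
per-site elemental deltas are light +C2H4, medium +C2D4, heavy
+(13C)2D6−H2. Masses are sums of count × standard monoisotopic atomic mass
(12C ≡ 12 exactly), giving 28.0313 / 32.0564 / 36.0757 Da per site, with
carbamidomethylation +57.0215 Da, methionine oxidation +15.9949 Da and
N-terminal acetylation +42.0106 Da from the same arithmetic. The probe
adduct (+509.2108 Da) is stored as an opaque named constant because its
elemental composition is not modeled here.

## Synthetic data: what it emulates and what it does not

The generator draws, per protein, a "true" log2 enrichment from its class
Gaussian — targets N(μ_mito, σ_mito²), background N(μ_bg, σ_bg²) — and
per-replicate observations as truth + N(0, σ_noise²); detection is
Bernoulli per replicate; intensities are log-normal; decoy/contaminant and
low-peptide rows exercise QC; the top-enriched slice of targets loses its
control-channel evidence (only-in-plus); the annotation DB covers the
targets (with sub-mitochondrial labels drawn from a matrix*-weighted mix)
except for an optional hidden fraction — the planted orphans — and flags
part of the background as MAM. `simulate_panel` repeats this over one
protein universe for several "cell lines", redrawing each protein's
enrichment per experiment. The triplex generator gives biotinylated
proteins a vs-control enrichment, splits a regulated fraction of targets
evenly into ±`regulated_log2fc`, and builds the three channel ratios
consistently by construction.

Defaults (`SimulationParams`): 400 targets / 1,200 background, μ_mito = 3.0,
σ_mito = 1.1, μ_bg = 0.8, σ_bg = 1.0 on log2; detection probability 0.9
per replicate, 3 replicates; 5% only-in-plus, 5% decoys; peptide counts
Poisson(6); replicate noise σ = 0.25; sub-mitochondrial mix 60/20/20
matrix*/IMS/MOM; 5% MAM background. These were set so that a linear ratio
cutoff near 5 yields a proteome of roughly 80% specificity with a quarter
of detected proteins being true targets — the regime of a well-behaved
cell-line experiment.

Not emulated: peptide-level evidence and rollup, missing-not-at-random
dropout, intensity-dependent ratio variance, correlated contaminant
structure, and annotation errors (as opposed to omissions). Passing tests
therefore show the *procedures* behave as specified under the assumed
statistical structure, not that real spectra will.

### Orphan-validation regime

Planted-orphan recovery is validated under a deliberately well-separated
configuration: 300 targets / 700 background per experiment, μ_mito = 3.5,
σ_mito = 0.8 vs μ_bg = 0.5, σ_bg = 0.8 (class separation ≈ 3.75 population
sd per experiment), three combined experiments, 5 targets hidden from the
annotation DB. Under the default ~80%-specificity regime a tangible
fraction of targets genuinely sits in the class overlap and is not
"surrounded" by annotated neighbors — such proteins are correctly not
called, so near-complete recovery is only a meaningful check when the
classes separate. The well-separated regime makes "surrounded" well
defined and recovery of ≥4/5 planted orphans the expected outcome;
kNN votes computed directly on the z-scored matrix are compared against
the embedding-based votes (Spearman ≥ 0.8) to guard against embedding
artifacts.

## Numerical conventions

- Ratio averaging is on the linear scale; binning, ROC and embeddings use
  log2.
- z-scoring uses the population (ddof = 0) standard deviation.
- ROC ties collapse to one curve point; AUC is trapezoidal.
- Cutoff retention and Filter 1 are boundary-inclusive (≥).
- Histogram bins are equal-width on the observed log2 range; a
  single-point range is widened by ±0.5 to keep nonzero width.
- t-SNE perplexity is reduced to (n−1)/3 with a warning when n ≤ 3 ×
  perplexity; fewer than 5 points is an error.
- All tabular outputs are UTF-8 TSV with deterministic column and row
  order; absent values are empty cells. Identical inputs, configuration
  and seed give byte-identical outputs (content hashes in the run
  manifest).

## Problem sizes used in validation

The test suite and the acceptance script run entirely on generated data:
default experiments of ~1,700 protein groups × 3 replicates; the
closed-form AUC check uses 5,000 proteins per class × 20 seeds; orphan
recovery uses 1,000-protein universes × 3 experiments × 20 seeds; ROC
oracle equivalence uses 200 random instances of ≤50 proteins. These sizes
give Monte-Carlo standard errors comfortably below the tolerances asserted
while keeping a full run in a few minutes.

## Known limitations

- Specificity estimates purity only as well as the annotation inventory is
  complete; hidden true residents depress it (that bias is exactly what
  the orphan stage exploits).
- The ROC positive class is "annotated", not "true resident"; reported AUC
  is therefore a lower bound on true-class separation when annotations are
  incomplete.
- The t-test on 3 vs 3 log2 ratios has little power; the volcano output is
  a screening tool, and the BH column is advisory.
- t-SNE coordinates are seed-dependent; only the kNN fractions derived
  from them, not the coordinates, should be interpreted, and the seed is
  part of every output's provenance.
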