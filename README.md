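# proxiprof

Ratiometric denoising and downstream analysis for proximity-labeling
subcellular proteomics.

Proximity labeling tags proteins near a compartment-targeted catalyst so
they can be enriched and identified by mass spectrometry — but the enriched
fraction always carries nonspecific background. When the experiment
includes a no-catalyst control quantified by stable-isotope dimethyl
labeling, every protein group gets a per-replicate +/− catalyst intensity
ratio, and background removal becomes a statistical problem: true
compartment residents concentrate at high ratios, background sits near 1.
`proxiprof` is for proteomics analysts who have MaxQuant-style
`proteinGroups` tables (or any TSV in the documented generic dialect) from
such a design — e.g. photocatalytic mitochondrial labeling in cell lines,
dissociated tissues or primary cells — and want a reproducible path from
those tables to:

- a denoised compartment proteome at a stated specificity, with ROC/AUC,
  abundance-fraction and sub-mitochondrial summaries;
- candidate "orphan" proteins: unannotated proteins whose ratio signatures
  cluster with known residents (t-SNE embedding + k-nearest-neighbor
  vote, MAM-annotated proteins excluded);
- disease-vs-control differential tables from triplex dimethyl designs
  (filter cascade, replicate intersection, unpaired two-tailed t-test);
- cross-dataset intensity normalization for comparison against external
  tissue proteomes.

## The statistic at the core

Per protein, merged over biological replicates, let r̄ be the arithmetic
mean of the linear +/− catalyst ratios (proteins detected only in the
(+)-catalyst channel are treated as r̄ = ∞). With a prior compartment
inventory A (MitoCarta3.0/UniProt-style), the retained proteome at cutoff
t is R(t) = {r̄ ≥ t}, its **specificity** is |R(t) ∩ A| / |R(t)|, and the
chosen cutoff is

  t\* = min { t ∈ observed ratios : specificity(R(t)) ≥ target } ,

i.e. the smallest threshold meeting the purity target, which maximizes
coverage. Class separation is summarized by the ROC over t (annotated
proteins as positives); the trapezoidal AUC equals the Mann–Whitney
pairwise-concordance probability with half credit for ties. A built-in
synthetic-data generator (two-class Gaussian log2-ratio mixture with
detection dropout, only-in-plus proteins, decoys and ground truth) makes
every stage testable without raw MS data. See `docs/methods.md` for the
full model and conventions.

## Worked example

Simulate a triplicate experiment, then choose the cutoff that delivers an
80%-specific proteome:

```sh
proxiprof simulate --seed 1 --out sim/
proxiprof cutoff sim/replicate_1.tsv sim/replicate_2.tsv sim/replicate_3.tsv \
    --annotations sim/annotations.tsv --target-specificity 0.8 --out-dir out/
```

which prints (and writes to `out/metrics.json`):

```json
{
  "abundance_fraction": 0.8165873138636853,
  "auc": 0.9279892291485033,
  "matrix_coverage": 0.6163265306122448,
  "n_retained": 326,
  "specificity": 0.8006134969325154,
  "submito_counts": {
    "IMS": 53,
    "MOM": 57,
    "matrix_star": 151,
    "non_mito": 65,
    "unassigned": 0
  },
  "threshold": 5.47507154023512
}
```

Read: the smallest observed ratio cutoff reaching the 80% target is ≈5.5;
326 proteins survive it, 80.1% of them carrying prior mitochondrial
annotation and accounting for 82% of the retained MS intensity; the
annotated/unannotated ratio distributions separate with AUC 0.93; 151 of
the retained annotated proteins are matrix\* residents, covering 62% of the
simulated matrix\* inventory. `out/retained_proteome.tsv` holds the
protein list and `out/ratio_histogram.tsv` the two-class log2-ratio
distribution behind the choice.

The same stages are available as a library — scikit-learn-style estimators
(`RatioCutoffSelector`, `OrphanDetector`, `TriplexDifferential`,
`ExternalIntensityNormalizer`) over pandas DataFrames, with plain
functions (`basic_filter`, `merge_replicates`, `choose_cutoff`,
`roc_curve`, …) underneath:

```python
from proxiprof import (SimulationParams, simulate_experiment,
                       basic_filter, merge_replicates, RatioCutoffSelector)

tables, ann, truth = simulate_experiment(SimulationParams(seed=1))
profiles, _ = merge_replicates([basic_filter(t)[0] for t in tables])
sel = RatioCutoffSelector(target_specificity=0.8).fit(profiles, ann)
sel.threshold_, sel.result_.specificity, sel.auc_
# (5.47507154023512, 0.8006134969325154, 0.9279892291485033)
```

Other subcommands: `filter` (QC + replicate merge), `profile` (two-class
histogram), `orphans` (embedding + candidate list), `compare` (triplex
funnel + volcano-ready table), `normalize-external`, `masses` (label and
modification mass table), `run` (full pipeline from a YAML config, with a
hash-bearing provenance manifest).

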