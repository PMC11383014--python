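# lupine

Imputation of missing values in multi-cohort TMT proteomics, with a deep
model that learns one set of protein and sample embeddings across many
datasets at once.

## The problem

Tandem-mass-tag (TMT) experiments quantify thousands of proteins per run,
but many protein-sample entries are missing — and not at random: dropout is
left-censored, hitting low-intensity measurements preferentially. Missing
values weaken differential-expression analyses and make low-abundance
biology hard to study. Naive fixes (drawing imputations from a downshifted
Gaussian, or substituting each sample's minimum) ignore the covariance
structure that the data actually carry.

## The model

Given a joint proteins × samples log-intensity matrix **X** assembled from
several cohorts, each protein *i* gets a factor vector **w**ᵢ ∈ ℝᵖ (row of
**W**) and each MS sample *j* a factor vector **h**ⱼ ∈ ℝˢ (column of
**H**). A prediction for entry (*i*, *j*) is

  X̂ᵢⱼ = MLP([**w**ᵢ ; **h**ⱼ])

where the multilayer perceptron has leaky-ReLU hidden layers (negative
slope 0.1) and a scalar linear output. **W**, **H** and the MLP are trained
jointly by Adam (learning rate 0.001, batch size 128) to minimise squared
error over training entries, with early stopping on an MCAR validation
split. Three ingredients target the left-censored regime:

* **MNAR partitioning** — each present entry is compared against a random
  threshold Tᵢⱼ ~ 𝒩(25th percentile of X, (1.1·σ_X)²); entries below their
  threshold enter the held-out test set on a Bernoulli(0.61) success, which
  puts ≈20% of present entries in a test set that is left-skewed relative
  to the training set — the same kind of values the instrument drops.
* **Biased batch selection** — training batches are resampled with the same
  threshold mechanism so the batch stream is itself left-shifted.
* **Ensembling** — several models with different hyperparameters
  (embedding sizes ∈ {64,…,1024}, 1–4 hidden layers of 512–2048 nodes;
  225 grid combinations) and different seeds/validation splits are trained
  and their prediction matrices averaged (default ensemble size 10).

The package also ships the comparison baselines (downshifted Gaussian
sampling, column minimum), accuracy metrics (test MSE per cohort,
per-protein residuals, fraction-better), downstream analyses (paired-t
differential expression with Benjamini-Hochberg control; within-complex vs
background Spearman correlations), and a seed-deterministic synthetic
generator for multi-cohort data with known ground truth.

## Worked example

```bash
python examples/01_impute_synthetic_cohorts.py
```

```
simulated joint matrix: 570 proteins x 160 samples, 63.1% missing
MNAR partition: 6855 of 33690 present entries (20.3%) held out for testing
ensemble test MSE:          0.152
Gaussian sampling test MSE: 1.269
column-min test MSE:        3.354
```

Four simulated cohorts are joined into one matrix (missingness is both
structural — proteins absent from a cohort — and intensity-dependent), 20%
of present entries are hidden under the MNAR scheme, and a three-member
ensemble is fit. Its test MSE (0.152, close to the simulation's noise
floor) is an order of magnitude below both naive baselines, which guess low
values without using the correlation structure. The other examples
demonstrate the partitioning closed form (`02`), recovery of planted
differential expression at adjusted p < 0.01 and |log2FC| > 0.5 with
recall 1.00 and zero false calls (`03`), and preservation of
protein-complex co-expression after imputation — within-complex mean
Spearman +0.27 before / +0.19 after, background ≈ 0 (`04`).

The same workflows are scriptable from the shell:

```bash
lupine simulate -o sim/ --seed 42
lupine partition sim/observed.tsv --seed 7 -o masks.tsv
lupine impute sim/observed.tsv --masks masks.tsv --n-models 3 -o imputed.tsv
lupine evaluate --pred imputed.tsv --truth sim/observed.tsv \
    --masks masks.tsv --metadata sim/metadata.tsv -o report.tsv
lupine de imputed.tsv --pre sim/observed.tsv --metadata sim/metadata.tsv -o de.tsv
```

Every artifact begins with `#` provenance lines (package version, resolved
options and their hash, seed), and identical invocations reproduce
byte-identical outputs.

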