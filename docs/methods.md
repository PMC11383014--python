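# Methods

This note documents the model and procedures implemented in `lupine`, the
assumptions behind the synthetic-data generator used for testing, and the
numerical and design choices made where the literature-standard recipe
leaves freedom.

## Data model

The unit of analysis is a proteins × samples matrix of log-scale,
reference-normalized TMT protein quantifications, assembled by joining
per-cohort tables over the union of their protein IDs (a protein absent
from a cohort is missing in all of that cohort's columns). `NaN` is the
single missing marker. Inputs are assumed already rolled up to protein
level and normalized; the reader offers an optional log2 transform but
applies nothing by default. Reference/QC columns are removed by
case-insensitive substring match against a fixed keyword list ("RefInt",
"QC", "pool", "pooled", "reference", "NCI", "NX", "ref"); because matching
is substring-based, "ref" subsumes "RefInt" — whole-token matching is not
offered. Proteins quantified in fewer than 18 samples (configurable) are
dropped after column filtering. Duplicate protein IDs are an error, not
aggregated.

## MNAR partitioning

For every present entry X_ij an independent threshold T_ij ~
Normal(c, s²) is drawn, with c the 25th percentile and s = 1.1 × the
standard deviation of present values (both computed over present entries
only). Entries with X_ij < T_ij are test-set candidates and enter the test
set on a Bernoulli(0.61) success; everything else trains. On roughly
normal data the expected test share is Φ(q₀.₂₅/√(1+1.1²))·0.61 ≈ 19.8%,
and the test set is left-skewed relative to the training set, mimicking
instrument dropout. The comparison direction (low entries as test
candidates) is the one consistent with both the ≈20% share and the
left-skew property; the opposite direction would hold out high-intensity
entries at roughly double the rate.

`calibrate_bernoulli_p` solves for the success probability analytically:
the per-entry censoring probability Φ((c − x)/s) is averaged over present
entries, and p = target / mean-probability, clipped to [0, 1]. Only this
one degree of freedom is calibrated; the threshold mean and sd stay at
their defaults.

The validation set is carved MCAR from the training entries: exactly
⌊fraction × |train|⌋ uniformly chosen entries (default 10%) move to the
validation mask, so validation loss is measured on data the optimizer
never sees and carries no intensity skew.

## Biased batch selection

Training batches of 128 entries are drawn with replacement from the
training set by rejection: a uniformly drawn candidate is accepted
outright if its value falls below a fresh threshold draw from the
partitioning distribution, and accepted with probability 0.5 otherwise.
The exact acceptance probabilities (1.0 below / 0.5 above) are this
package's choice; the contract — pooled batches are left-shifted relative
to the full training set, and revert to the training distribution when the
acceptance rule is disabled — is what the tests pin down.

## Model and training

Protein factors W (n_proteins × p) and sample factors H (s × n_samples)
are dense embeddings initialised i.i.d. Normal(0, 1/√factors); MLP weights
use uniform fan-in scaling with zero biases, keeping initial predictions
O(1) on the log-intensity scale. The MLP takes the concatenated factor
pair (p + s inputs), applies leaky-ReLU (slope 0.1) after each hidden
layer, and ends in an unclamped scalar linear output — no weight decay,
dropout or normalization layers. The forward pass, backpropagation and the
Adam optimizer (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, learning rate 0.001) are
implemented directly in NumPy; Adam is dense over the full embedding
matrices, matching the default behaviour of mainstream autodiff frameworks
for non-sparse embeddings. Computation is CPU-only.

An epoch is ⌈|train| / batch_size⌉ biased batches — with-replacement
sampling has no natural epoch boundary, so one epoch covers the training
set in expectation. After each epoch the full validation MSE is recorded
and two stopping criteria consulted:

1. **Plateau.** The signed ratio (best − current)/best is computed per
   epoch; when it stays below 0.001 for 10 successive epochs, training
   stops. The signed form means worsening epochs also qualify.
2. **Rising error** (evaluable from epoch 15). A one-sided rank-sum test
   compares the five most recent validation MSEs with the five from ten
   epochs earlier; p < 0.05 with the older window stochastically smaller
   means validation error has begun to rise, and training stops. Windows
   are five epochs each so that the extreme ordering has exact p =
   1/C(10,5) ≈ 0.004; SciPy's exact small-sample null is used when there
   are no ties and the tie-corrected normal approximation otherwise.

A hard cap (default 500 epochs) backs up both criteria. The parameters
returned are those of the best-validation epoch, not the last one — the
rank-sum criterion by construction fires only after the optimum has
passed.

## Ensembling

Member configurations are either supplied explicitly or sampled uniformly
without replacement from the hyperparameter grid (protein and sample
factors ∈ {64, 128, 256, 512, 1024}, hidden layers ∈ {1, 2, 4}, nodes per
layer ∈ {512, 1024, 2048}; 225 combinations). Member k derives seed
`seed + k` and carves its own 10% MCAR validation split from the shared
training mask. The ensemble prediction is the unweighted entrywise mean;
by convexity its MSE on any fixed target set is at most the mean of the
member MSEs, an invariant asserted in the tests. Members train
sequentially; seed isolation makes the result independent of execution
order.

## Baselines and metrics

Gaussian random sampling imputes each missing entry in column j from
Normal(μⱼ − 1.8σⱼ, (0.3σⱼ)²) using the column's observed moments — 0.3 and
1.8 are the customary width/downshift defaults and are exposed as flags.
Column-minimum substitutes each column's lowest observed value. Both are
per-column (per-MS-sample) procedures.

Accuracy is test-set MSE, overall and per cohort (a cohort without test
entries reports NaN, never 0). Per-protein residuals aggregate each
protein's test-entry errors by mean absolute value (root-mean-square and
signed-mean variants are available; the aggregation is a package choice).
`fraction_better(a, b)` restricts to proteins where either method's
residual exceeds 0.25 and reports the fraction where method a's residual
is strictly smaller; ties count as "not better".

## Downstream analyses

**Differential expression.** Proteins with pre-imputation missingness
above 50% are excluded. Per protein, a two-sided paired t-test compares
tumor against matched non-tumor samples of the same patients (patients
lacking either member are dropped); the mean paired difference is the log2
fold change, values being log2-like already. P-values are BH-adjusted
across tested proteins; calls require adjusted p < 0.01 and |log2FC| >
0.5, with the sign giving up/down. Running the analysis on a matrix that
still contains missing values drops incomplete pairs per protein
(no-imputation mode); proteins left with fewer than two pairs are excluded
from the BH family. The BH step-up procedure is implemented in-package and
cross-checked against brute-force and statsmodels oracles.

**Complex correlations.** Within a cohort (tumor columns when annotated),
proteins with pre-imputation missingness < 50% are retained; the Spearman
correlation of every unordered within-complex pair (deduplicated across
complexes) is compared against an equally sized uniform sample of pairs
internal to no complex (self-pairs excluded). The two sets have no natural
pairing, so their means are compared with a Welch two-sample t-test.
Spearman is computed by SciPy (Pearson on mid-ranks); pairs with missing
members are dropped, and fewer than three complete pairs or a constant
sequence yields an undefined (NaN) coefficient.

## Synthetic data generator

The generator emulates the joint-matrix structure the imputer is built
for: truth = low-rank signal (U V/√rank with i.i.d. normal factors) +
complex-block shared factors (loading 0.8) + cohort offsets + TMT-plex
offsets + planted tumor shifts + Gaussian noise. Matched tumor/non-tumor
columns of one patient share the patient's sample factor, so paired
differences isolate the planted effect plus noise — the correlation
structure that motivates paired testing in real cohorts. Missingness has
two layers: structural (a protein absent from a cohort's table) and
left-censoring, applied entrywise with probability sigmoid(−slope·(x − c)),
with c calibrated by bisection so the expected missing rate over
structurally present entries hits the target (default 30%) — the logistic
form is chosen for cheap calibration; the normative MNAR mechanism is the
partitioner, and the generator only needs the qualitative
intensity–missingness relationship.

Defaults are sized for desk-scale runs: 4 cohorts × 300 proteins × 40
samples, 70% of proteins shared across cohorts, rank 5, noise sd 0.25,
cohort/plex offset sds 0.3/0.2, 20 paired patients per cohort, 30 planted
up-shifted proteins (shift 1.0), 10 complexes of 5. What the generator
does **not** emulate: peptide-level effects and roll-up artifacts,
non-Gaussian heavy-tailed noise, intensity-dependent variance,
plex-by-protein interaction effects, and real CORUM-scale complex overlap.
Passing tests therefore demonstrate correct mechanics and the expected
qualitative behaviour under the stated model, not performance on any real
cohort.

## Problem sizes and fixtures

Tests and examples run the full pipeline at reduced scale as the package's
own working sizes: ensembles of 2–3 members with 16-dimensional embeddings
and one 64-node hidden layer on the default simulated matrix (570 × 160
after the union of cohorts), and a 1,000 × 200 standard-normal matrix for
partitioning statistics. The bundled acceptance script
(`scripts/acceptance.py`) reruns the partitioning measurement from scratch
for any seed. All fixtures are generated programmatically; the repository
contains no data files.

## Known limitations

* The biased-batch acceptance mechanism is a documented stand-in pinned to
  its distributional contract, not to a specific published recipe.
* Per-protein residual aggregation and the background-pair sampling scheme
  are package choices exposed as options.
* Training is single-threaded NumPy: adequate for thousands of proteins ×
  hundreds of samples, not for consortium-scale matrices with
  1024-dimensional embeddings.
* Predictions are unbounded; on data far from the training intensity range
  the model extrapolates linearly.
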