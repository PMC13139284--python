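# Methods

`mtqsar` models sparse multi-target bioactivity tables of the kind
assembled for adverse-outcome-pathway (AOP) screening: a pool of
compounds assayed, very incompletely, against a panel of molecular
initiating events and key events (e.g. AChE, CB1/CB2, MAGL, dopamine
and muscarinic receptors). This note records the models, the defaults,
the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Data model and curation

A raw export is a table of (compound, task, endpoint, potency, unit)
records. Curation follows the standard QSAR protocol:

- structures are parsed and the largest fragment is kept when it has at
  least twice the heavy atoms of the next largest (salt stripping);
  multi-fragment inputs without a dominant parent are rejected as
  mixtures. Polymers (repeat-unit dummy atoms) and organometallics
  (any element outside H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) are
  rejected with machine-readable reasons. Nitro groups are normalized
  to the charge-separated form and aromaticity is perceived (not
  kekulized); the convention is recorded in the curation report.
- potencies are mapped to the negative-log-molar scale,
  p = −log10(value · unit_factor), and IC50 and Ki streams are never
  pooled for one task.
- duplicates are grouped by (canonical structure, task, endpoint) —
  not by compound identifier, which can alias a parent structure after
  salt stripping. A group whose max−min spread on the p-scale exceeds
  0.3 log units is excluded entirely; otherwise the arithmetic mean is
  kept. Max−min is the simplest spread definition that stays
  well-defined for groups larger than two. The same rule is applied to
  Ki groups.
- the report reconciles exactly: input rows = output rows + rejections
  + discordant entries + (group size − 1) per averaged group. Output is
  sorted, so curation is idempotent and order-invariant.

## Features

Structures are encoded as 1024-bit hashed circular (Morgan) fingerprints
of radius 2 (diameter 4), chirality off. Tanimoto similarity
|A∩B|/|A∪B| (defined as 1 for two empty vectors) and the distance
1 − Tc drive both the applicability domain and the chemical-space
projections; one fingerprint serves modeling and domain analysis.
Crippen logP and average molecular weight support split-diagnostic
plots.

## Splits

Random 8:1:1 (rounding surplus to train), scaffold-disjoint, and
5-fold partitions are provided, all seeded. The scaffold split groups
compounds by Bemis–Murcko scaffold (acyclic molecules share the empty
scaffold), sorts groups by size descending with seeded tie-breaking,
and places each whole group into the partition furthest below its
target count. This guarantees zero scaffold overlap and keeps the
small partitions populated even under skewed scaffold distributions.
Repeated runs use seeds base_seed + 1 … base_seed + n_runs, and the
same Split objects are reused across learners so that deep and tree
models see identical data.

A consequence worth knowing: under a scaffold split the validation
partition is a handful of *whole* held-out chemotypes. Its masked MSE
can be dominated by one structurally remote family and is then a poor
model-selection signal — it can even move opposite to test-set
correlation. The training API therefore early-stops on validation
masked MSE by default (the stated contract), but the recommended final
model is refit on train+validation for a fixed epoch budget once the
configuration is chosen; the acceptance tests use that refit.

## Models

The multitask network is a fully connected trunk (default two hidden
layers of 512 and 256 units, ReLU) whose final linear layer provides
one output head per task — hard parameter sharing. The loss is masked
MSE: the mean over *observed* cells only, normalized by the number of
observed cells in the batch so gradient scale is stable at ~89%
sparsity; gradients are exactly zero on masked cells. Defaults follow
the selected optimum of the workflow this package reproduces: batch
size 48, Nadam, learning rate 1e-3, up to 2000 epochs with patience 10.
The random-search space spans dropout 0.1–0.6, learning rate 1e-8–1e-1
(log-uniform), batch 24–96, six activations (GELU, ELU, SELU, tanh,
ReLU, linear), L1/L2 regularization, and four optimizers (Adam, Nadam,
SGD, RMSProp). The network and its optimizers are implemented in
seeded NumPy; same-platform runs are bit-reproducible, cross-platform
reproducibility is not promised. Single-task baselines are
scikit-learn random forests and LightGBM gradient boosting, selected
by cross-validated RMSE under a random search of equal budget, plus a
single-task variant of the network. Weight decay (L2 ≈ 1e-3) matters
more here than on dense tabular data: fingerprint bits absent from the
training partition otherwise keep their random initial weights and
produce systematic offsets on scaffold-held-out chemotypes.

Evaluation reports Pearson r, RMSE and MAE per task over observed test
cells, aggregated over splitting runs as mean ± sample (n−1) SD.
Constant vectors make r undefined; it is returned as NaN with a
warning rather than a crash.

## Applicability domain

The domain is defined on the training set's mean k-nearest-neighbor
Tanimoto distances with k = 3, self-distances excluded (otherwise every
in-sample distance includes a zero and the threshold collapses). The
threshold is the 95% quantile (linear interpolation between order
statistics) of that in-sample distribution — the upper edge of the
dense core — so by construction ~95% of training compounds fall inside
their own domain, up to quantile-interpolation discreteness. A query
is inside when its mean k-NN distance is ≤ the threshold (boundary
inclusive). The k-sweep table (k = 3, 5, …, 29) shows the mean
distance increasing monotonically in k, the rationale for preferring
the smallest, most local neighborhood.

t-SNE projections of the precomputed distance matrix are validated by
a perplexity × seed sweep (defaults {10, 20, 30, 40, 50} × {0, 42,
99}): trustworthiness for neighborhood preservation, Procrustes
disparity against the lowest-seed reference run of each perplexity
group for geometric stability, and silhouette for cluster coherence.
Flags default to trustworthiness ≥ 0.99 and group-wide disparity ≤
0.01, both configurable since they are reporting conventions, not laws.
The selected configuration maximizes a rank-sum of trustworthiness,
−disparity and silhouette among trustworthy non-reference runs.
Silhouette labels are caller-supplied; the package does not impose a
clustering.

## Explainability

Kernel SHAP is implemented directly: coalitions of fingerprint bits
are scored by the model with absent bits marginalized over a background
sample (default a seeded sample of training compounds), and per-bit
contributions are solved by weighted least squares with the
local-accuracy constraint eliminated into the solve, so base value +
Σ contributions = prediction holds exactly for every emitted
explanation. Bits identical between the compound and all background
rows are provably null and set to zero. When at most 14 bits vary, all
coalitions are enumerated with exact Shapley-kernel weights (for a
linear model this reproduces w_i(x_i − E[x_i]) to numerical precision);
otherwise coalition sizes are sampled proportionally to the kernel with
antithetic complement pairing to reduce estimator variance. Each task
head of the multitask network is explained as a scalar function of the
shared input. Bit-to-substructure maps return *all* atom environments
hashing to a bit (hash collisions are many-to-one), and atom-level
contribution maps split a bit's contribution equally over its
environment atoms.

Because circular fingerprints spawn several bits per functional group,
Shapley credit for one planted pharmacophore is split across the
correlated bit set; a single canonical high-support bit per group is
the right unit for rank-based recovery checks, not every correlated
variant.

## Synthetic benchmark

The generator assembles molecules from a fragment grammar (aromatic and
aliphatic cores; decorations including tertiary amines, carboxylic
acids, carbamates, phosphate esters, a disulfide) so every molecule is
chemically valid and curation never rejects generator output for
parsing reasons. Potency is planted additively: base 5.0 on the pIC50
scale plus rule weights (±1–2.5 log units) for SMARTS-defined
substructures, Gaussian noise (default SD 0.3) on observed entries
only, covering roughly the 3–10 potency range seen in real bioassay
panels. The observed export mixes µM and nM units
(IC50[µM] = 10^(6−p)), salts a recorded fraction of entries, duplicates
a recorded fraction (half perturbed ≤ 0.3 log units to exercise
averaging, half 0.3–0.6 to exercise exclusion), and masks cells at the
default 89% sparsity. Every planted pattern must occur in 5–95% of
molecules or the pool is regenerated. The planted amine rule is
restricted to acyclic nitrogens because ring nitrogens hash to
different circular environments — a rule invisible to the
representation would be unrecoverable by construction.

Problem sizes in the test suite are chosen to keep the full run modest:
recovery uses 500 compounds × 4 tasks (sparsity 0.3 so each task
retains ~35 observed test cells for a stable correlation), the
multitask-robustness comparison 600 compounds at the realistic 0.89
sparsity over 5 seeds, networks of 256×128 or 128×64 units trained for
150–400 fixed epochs.

What passing these tests shows: the pipeline is internally consistent —
curation recovers planted truth and accounts for every removed row;
scaffold splits never leak; the masked loss ignores unobserved cells
exactly; the multitask network recovers representable planted signal
across scaffold boundaries and degrades less than single-task networks
under scaffold shift at high sparsity; attributions satisfy the SHAP
axioms and rank planted pharmacophores highly. What it does not show:
performance on real bioassay data, whose activity landscape is neither
additive nor SMARTS-definable, whose noise is assay- and
lab-structured rather than i.i.d. Gaussian, and whose scaffold
distribution is far heavier-tailed than the grammar's.

## Known limitations

- No tautomer canonicalization or stereochemistry repair; chirality is
  off in the fingerprints.
- The network trains full batches through NumPy; it is CPU-bound and
  not intended for datasets beyond ~10^4 compounds.
- Sampled kernel SHAP on ~500 varying bits retains Monte-Carlo noise at
  the per-bit level; rankings of high-signal bits are stable, small
  contributions are not.
- t-SNE stability across seeds (the stable_flag) is rarely achieved at
  small n; this mirrors the stochastic nature of the algorithm, not a
  defect of the embedding.
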