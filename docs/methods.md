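# Methods

`smokenet` re-implements, as a tested pipeline, a network-based analysis
of smoking-associated DNA methylation in peripheral blood mononuclear
cells: probe-level EWAS on 450K-style beta values with cell-mixture
surrogate correction, promoter-level gene tests, a significance-weighted
protein-interaction network, greedy sub-network discovery, and GO
over-representation. This note records the models, the defaults and why
they are what they are, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the method left room.

## Data model

Methylation is represented as beta values — methylated-probe intensity
over total intensity, a fraction in [0, 1] — in a probes × samples
matrix with a missingness mask. Values whose detection p exceeds 0.05
(strictly) are masked; probes masked in more than 20% of samples are
dropped. Probes are keyed by id only; the analysis never uses genomic
coordinates. A probe annotated to several genes contributes to all of
them, which loses no signal at the cost of mild double-counting.

## Cell-mixture surrogates

Whole-blood methylation is confounded by cell-type composition. A
purified-cell reference panel (five leukocyte types, six replicates
each) is scanned probe-by-probe with a one-way fixed-effects F-test of
beta on cell type; p-values are Benjamini–Hochberg (BH) adjusted over
all probes. The cohort's betas at the top 100 sites (ties at the
boundary included) are summarized by PCA — covariance, not correlation,
since all features share the beta scale — and the first five sample
scores enter the EWAS as covariates. PCA runs on the cohort rather than
the panel because only that yields one score per cohort sample. Sites
are ranked by p-value rather than effect size; components carry a fixed
sign convention (largest-magnitude loading positive) so results are
reproducible across runs.

## Probe-level EWAS

Each probe's beta is regressed by OLS on smoking status (1 = smoker)
with slide and plate indicator contrasts (reference level first by
lexical order) and the five surrogate scores. The reported p is the
two-sided t-test of the smoking coefficient; BH adjustment uses the
number of probes actually fitted. Covariate columns that add no rank
(plate is nested within slide when slides are converted in batches of
eight) are aliased out, as linear-model software does; a smoking column
that adds no rank is an error, not something to alias. Probes need at
least 10 complete cases and a numerically nonzero residual variance;
skipped probes are counted with reasons. Modeling is on the beta scale,
as the study design reports and interprets beta differences directly;
an M-value (logit) response is available behind a flag.

## Promoter-level tests and edge weights

Promoter probes default to the TSS1500/TSS200 manifest categories (the
definition is configurable; no standard exists). For each gene, all
unmasked promoter-probe beta values of smokers are flattened into one
vector, likewise non-smokers, and compared with a pooled-variance
unpaired t-test; BH over genes gives the gene-level adjusted p'.

Calibration caveat, measured on null simulations: the flattened test is
*conservative* when a gene's probes have different baselines — the
group-mean difference cancels between-probe variance, but the pooled
variance estimate retains it, so null p's pile toward 1 (0.6% of null
raw p's fall below 0.05). A per-sample-mean mode (probes averaged
within sample first) is exactly calibrated on batch-free nulls and is
available behind a flag; the flattened mode remains the default because
it is the method being reproduced. The conservatism costs power but
never inflates type-I error.

Edges of a protein-interaction network are weighted by

    w_ij = log(p'_i · p'_j) / log(p'_min²)

with p'_min the smallest adjusted p' in the gene table. w is 1 when
both genes sit at the minimum, 0 when both are at p' = 1, symmetric and
strictly decreasing in each p'. The logarithm base cancels; natural
logs are used, and p' is floored at 1e-300 before logs.

## Sub-network discovery

The module score is a weighted boundary-ratio local modularity

    Q(S) = W_in / (W_in + W_bnd),   W = Σ w^γ,

where W_in sums over edges inside the member set and W_bnd over edges
with exactly one end inside; Q = 1 exactly for a whole connected
component. Search grows each of the top-`max_seeds` edges (by weight)
greedily, adding the neighbor with the largest strictly positive score
increase (ties: lower p', then lexical symbol), stopping at `size_max`
(default 25) or no improvement, and discarding expansions below
`size_min` (default 5).

The exponent γ controls how much the weights, versus the topology,
drive the score. Pilot calibration experiments shaped the default
γ = 0.75: at γ = 1 with realistic BH-adjusted p' tables (bulk near 1,
bulk edge weights near 0) any neighbor of a module is absorbed for
free — its single module-facing edge outweighs all its own — so greedy
expansions overshoot dense modules with a halo; at γ near 0 the score
becomes purely topological and permutation significance collapses.
γ = 0.75 keeps the weights decisive while background edge mass is
large enough that boundary neighbors resist absorption. The score is
isolated behind `local_modularity`, so an alternative definition is a
one-function swap.

Significance is empirical: node p' values are permuted over nodes,
weights recomputed on the same topology, and the identical
seed-and-expand procedure repeated `n_null` times. Because score
distributions are strongly size-dependent, each candidate of size s is
compared with every replicate's best score among expansions of size
s ± max(2, 0.2·s); the add-one estimator is conditional on replicates
that realized that window (so rarely-realized sizes cannot become
spuriously significant, and the p has floor 1/(1+populated)).
Overlapping candidates (Jaccard > 0.5) are collapsed to the
best-scoring representative *before* testing — they are variants of one
discovery — and Holm step-down across the distinct discoveries controls
the per-run family-wise error that testing one candidate per realized
stratum otherwise inflates. A degree-preserving edge-rewiring null is
available behind `null_model="rewire"`.

## GO over-representation

One operation serves both the genome-wide mode (genes owning a
BH-significant probe, against the universe of genes owning any fitted
probe) and the per-module mode (module members against the weighted
network's genes). Per term the p is the hypergeometric upper tail of
the query/term overlap after intersecting terms with the universe; BH
across terms by default, with an optional permutation mode (equal-size
random queries, add-one FDR-style q). Gene-set input is flat GMT; GO
hierarchy propagation is out of scope.

## Synthetic-data generator

The generator is first-class, tested code and defines the study
conditions all stochastic tests run under.

* **Cohort** — 50 smokers / 61 non-smokers by default, the sizes of the
  cohort emulated. Per-probe baselines come from a bimodal Beta(0.4,
  0.4) squeezed into (0.05, 0.95), the classic two-mode shape of
  methylation fractions. Each sample is a Dirichlet-weighted mixture of
  cell-type profiles (concentration 10, 10, 8, 4, 2 — monocyte- and
  lymphocyte-dominant; fixed by convention) plus additive slide and
  plate offsets (12 slides, 8 slides per bisulfite batch, sd 0.01
  each) and probe-level Gaussian noise (sd 0.05), clipped to [0, 1].
  Effect probes are the promoter probes of a leading block of genes,
  shifted by a signed delta (default range 0.03–0.15, the scale of the
  printed top-probe group differences) in smokers only. Effects are
  additive on the beta scale because that is the scale the analysis
  models; clipping makes realized gaps at extreme baselines smaller
  than planted, which the tests account for.
* **Reference panel** — the five named leukocyte types × 6 replicates;
  the cell-type-informative probes carry a between-type spread of
  exactly `celltype_delta` (default 0.15) and sit in a block disjoint
  from promoter probes, guaranteeing effect/cell-type disjointness.
* **PPI** — planted modules are cliques with 15% edge dropout
  (connectivity restored by a spanning path) over exactly the
  `sum(sizes)` lowest-p' genes, the smallest module taking the
  strongest genes. Each member reaches the background through its own
  well-connected hub (12 background partners), the way complexes sit in
  a scale-free interactome; the background is a configuration-style
  random graph (expected degree 4, minimum degree 2), emitted as a
  single connected component. These embedding choices came out of
  calibration pilots: pendant neighbors and under-connected hubs are
  absorbed by any boundary-ratio score, and near-isolated cliques are
  rediscovered by topology alone under permutation.
* **GO** — flat terms with uniform membership; planted terms
  over-sample a target gene set at a configured odds ratio.

What the generator does **not** emulate: type I/II probe chemistry
bias, age/BMI/ancestry covariates, longitudinal waves, spatial probe
correlation along the genome, and annotation-version idiosyncrasies.
Passing tests therefore demonstrate the pipeline's statistical
machinery — calibration, recovery, ranking — under the modeled
structure, not concordance with any particular public dataset.

## Problem sizes used by the test suite and acceptance script

Calibration and recovery checks run at 20,000 probes × 111 samples
(20 seeds for null calibration); the module-search checks run on a
1,000-gene, ~3,000-edge network with planted modules of sizes 6 and 15,
100 permutation replicates, 25 seed edges, and 20 permuted-null runs.
These sizes give the checks stable behavior while keeping a full run in
minutes.

## Known limitations

* The boundary-ratio score penalizes precisely the heavy boundary edges
  that real modules of globally-minimal p' genes carry; very small
  modules (≲5 genes) are at the edge of detectability under the
  permutation null.
* The flattened promoter test's conservatism (above) is inherited from
  the method being reproduced.
* BH over a top slice of p-values is exact for the slice only when the
  step-up minimum is attained inside the slice; the bundled worked
  examples satisfy this, arbitrary slices are upper bounds.
* Counts tied to specific array manifests, interactome versions and GO
  releases (numbers of significant sites, mapped genes and edges,
  specific sub-networks) are dataset properties, not reproducible from
  synthetic data; the pipeline logs them for audit instead of asserting
  them.
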