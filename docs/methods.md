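# Methods

## The model

`rnage` treats aging as a direction in transcriptome space, estimated
per tissue from young-vs-old differential-expression (DE) studies and then
*projected* onto any new two-group comparison. Nothing is regressed on
chronological age: the output is a relative statement ("group1 is
transcriptionally older than group2 and by this margin"), which is the
quantity of interest when evaluating induced-aging or rejuvenation
protocols that have no meaningful chronological age at all.

The pipeline has three stages, each a pure function of its declared
inputs.

### Signature derivation

Inputs are K DE tables (gene, log2 fold change, p-value), one per training
dataset. Fold changes are oriented log2(old/young), so positive = up in
aging; if a user supplies the opposite orientation every downstream score
flips sign coherently.

* **Gene universe** — the intersection of gene IDs across all K tables.
  The Pan criterion (agreement in *all* datasets) is undefined for genes
  missing from any table, and upstream DE tools already drop unexpressed
  genes per dataset, so intersection is the only self-consistent choice.
* **Discretization** — three-way at ±0.1 log2-units, boundaries inclusive
  of the nonzero bins (the three bins must partition the line). 0.1 is
  deliberately permissive: the hierarchy needs direction, not effect size,
  and concordance across datasets supplies the specificity.
* **P-value combination** — Edgington's sum-of-p method: the combined p is
  the Irwin–Hall CDF of Σp, computed with the closed form
  (1/K!)·Σ<sub>j≤⌊s⌋</sub>(−1)ʲC(K,j)(s−j)ᴷ, clamped to [0,1]. The
  alternating sum is numerically safe in double precision for the small K
  (≤ tens) of meta-analysis; p-values of exactly 0 are legal (no log is
  taken, so no pseudo-count is needed). Combination always uses **all K**
  p-values, even for tissue-restricted classes — combination ranks genes
  within a class; class *membership* is decided by the discretized
  directions alone.
* **Hierarchy** — classes are claimed in order Pan → pF → Neuronal → FC →
  SN, each requiring full directional agreement over its defining dataset
  subset (|Σ L̄| = subset size; for the single-dataset SN class this is
  simply L̄ ≠ 0) and excluding genes claimed earlier. Classes are therefore
  mutually exclusive by construction, and the generalization to arbitrary
  panels is "full agreement over the subset".
* **Ranking and tie-break** — per class, ascending combined p, ties broken
  by larger mean |log2FC| over the class-defining subset, then lexicographic
  gene ID. Combined p-values from real data are continuous so ties are
  rare; the declared total order exists purely so that identical inputs
  give byte-identical signature files.
* **Marker vector** — each kept gene's shared discretized direction within
  the class-defining subset (equivalently the sign of the subset sum).

### Scoring

Per signature gene present in the test matrix, a Welch two-sample
t-statistic between the groups (sample variances, n−1 denominators);
absent genes contribute t = 0 while N<sub>k</sub> counts only present
genes. The score is the direction-weighted mean t; the percentage score is
the fraction of *strictly* positive t·direction products — products that
are exactly 0 (absent genes, exact ties) count as not agreeing. Only the
statistic is used; no degrees of freedom or p-value is ever computed from
it.

Numerical edge cases: when both groups have zero variance the statistic is
0 for equal means and a configurable sentinel ±t_cap (default 50,
logged) for unequal means — ±∞ would let a single constant-expression
gene dominate a signature mean. The scorer applies log2(x+1) to matrices
tagged `linear` (policy `auto`; `on`/`off` override): t-statistics on
heavy-tailed linear TPM-like values are dominated by outliers, while
already-log data (including L1000-style normalized intensities tagged
`log`) are used as-is.

Welch's t is shift- and scale-invariant, so the score inherits exact
invariance to adding a constant or rescaling the whole matrix, and exact
antisymmetry under swapping the two groups.

### Screening

One scoring unit per (perturbation, dose, time, plate) with ≥2 treated and
≥2 same-plate control instances (under-replicated combinations are skipped
with a logged reason; the control label, e.g. vehicle/DMSO, is data, not
code). Aggregation is two-stage — plates averaged within a condition,
conditions averaged to one value per perturbation — so that heavily
re-tested conditions do not dominate a perturbation's summary. z-values
standardize per-perturbation means within each signature class across the
run; a run is expected to cover one cell line (any cell-line restriction
is a metadata pre-filter upstream of this package), so the class stratum
is the cell-line × class stratum. Hits are |z| > k (default 3) with the
empirical mean/SD; a median/MAD option exists (`robust=True`) but is off
by default because the default rule is deliberately the plain
"SDs from the mean" convention. At least two distinct perturbations are
required — the SD of one point is undefined.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `lfc_threshold` | 0.1 | log2-units | direction call for discretization; permissive on purpose |
| `top_n` | 100 | genes | signature size; balances stability of the mean-t against dilution with weak markers |
| `t_cap` | 50 | t-units | finite sentinel for zero-variance/unequal-mean genes |
| `k_sd` | 3 | SD | screen hit threshold; under a normal null, ~0.1–0.3 false hits per 100 perturbations per tail |
| transform | `auto` | — | log2(x+1) for linear-scale matrices only |

## The synthetic generator

The generators produce every input the pipeline consumes, with planted
truth, under one seed (`numpy.random.default_rng` seeded as
`[seed, stream]` with a fixed stream per generator, so the three
generators are mutually independent and individually reproducible).

* **Training tables** — 10,000 genes, 200 planted per class, planted
  |log2FC| = 1.0 (± N(0, 0.1·noise_sd) jitter) and p ~ U(0, 10⁻⁴) in the
  class-defining datasets only; null entries have p ~ U(0,1) and fold
  changes held inside (−0.1, 0.1). Planted p-values are drawn rather than
  fixed so the combined-p ranking among planted genes is non-degenerate.
  A small escape channel (`null_escape_prob`, default 10⁻⁴) lets a null
  fold change land just over the threshold, exercising the hierarchy's
  robustness to rare artifacts. The default is deliberately near zero:
  escaped nulls enter the single-dataset SN class freely, and because
  ranking combines p-values over *all* datasets (only one of which is
  informative for SN), escaped nulls are barely separable from planted SN
  genes — at an escape rate of 2% the SN signature's attainable precision
  is analytically ≈ 0.70, a property of the method, not a bug.
* **Cohorts** — per-gene baseline ~ N(5, 1) on log2 scale, per-sample
  noise N(0, 0.25), 9 vs 9 samples (the size of the method's training
  comparisons); the designated older group is shifted by
  direction × effect on the planted genes of the chosen classes.
* **Screens** — 2 plates × (3 treated replicates per perturbation + 6
  vehicle controls), 100 null perturbations plus planted perturbations
  that shift one class's genes by sign × effect × direction; one condition
  per planted effect size.

What the generator does **not** emulate: count-level noise
(negative-binomial sampling, library-size variation), correlated gene
modules, batch effects, or compositional structure. Expression is
simulated directly on the log scale the scorer consumes. Passing tests
therefore demonstrate the *statistical machinery* — discretization,
combination, hierarchy, projection, aggregation, hit calling — under the
declared noise model; they do not certify performance on real RNA-seq with
its heavier tails and confounders.

## Problem sizes

The test suite runs the full derivation conditions (10⁴ genes, 200 planted
per class) over 20 seeds, 20 matched cohorts, a 100-permutation null, and
20 screens of 101 perturbations; unit tests use an 800-gene / 40-per-class
panel of the same structure. `scripts/acceptance.py` uses 5 derivation
seeds and one cohort/screen run.

## Known limitations

* The score is relative; two comparisons' scores are on the same scale
  only if the test matrices and group sizes are comparable (t-statistics
  grow with √n).
* Marker directions are ±1; magnitude information from the training data
  is used only as a tie-break, never as a weight.
* Signatures derived from a panel are only as tissue-specific as the panel:
  classes defined over one dataset (SN-style) inherit that dataset's
  noise and, as analyzed above, rank their genes with mostly uninformative
  combined p-values.
* The screen's normality assumption for z-values is empirical; strongly
  skewed score distributions would miscalibrate the default mean/SD rule
  (use `robust=True`).
* GCT v1.3 text matrices are supported; binary GCTX/HDF5 is not.
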