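# Methods

This note records the models, conventions and numerical choices behind
`bclr`, and what its synthetic benchmarks do and do not establish.

## Mutual information estimation

Pairwise dependence is scored by a plug-in mutual-information estimator
on soft (B-spline) bins. For `M` bins of spline order `k` (order =
degree + 1), an open-uniform knot vector with `k`-fold end knots and
unit interior spacing spans the domain `[0, M − k + 1]`; each variable
is affinely rescaled onto that domain using its own min/max. The `M`
basis functions partition unity, so each sample contributes fractional
counts to several adjacent bins instead of a single hard count — this
damps the estimator variance caused by samples sitting near bin edges,
which matters at the very small per-iteration sample sizes that
aggressive condition subsampling produces. Marginal probabilities are
sample means of the weights; the joint is the sample mean of the weight
outer product; MI is the usual plug-in sum in bits.

Defaults are `M = 10`, `k = 3` (quadratic splines). With fewer samples
than bins, `M` is clamped to the sample count (and `k` to `M`) with a
warning rather than raising: a 5% fraction of a 40-condition set is 2
conditions, and the sweep harness must be able to visit that regime.
Constant vectors have no defined rescaling and return MI 0 with a
logged warning. Order 1 reduces to hard histogram binning; only in that
case is the self-information MI(X, X) exactly the marginal entropy
H(X) — under soft binning the self-joint spreads off the diagonal and
MI(X, X) < H(X), which is why the diagonal of the MI matrix is kept
only as a diagnostic and never enters background statistics.

The all-pairs MI matrix is computed as one Gram product over stacked
weight matrices. Block summation reorders floating-point additions, so
the matrix is explicitly re-symmetrized; it agrees with per-pair calls
to ~1e-12, not bitwise.

## CLR background correction

For gene i, the background mean and *population* (divide-by-n) standard
deviation are taken over its MI values against the other n − 1 genes,
excluding the self-pair. One-sided z-scores are clamped at zero and
combined in quadrature, `score = sqrt(z_ij² + z_ji²)`; a zero background
standard deviation defines z = 0. Scores are invariant to any positive
rescaling of the MI matrix (verified to ≤ 1e-9 under ×0.5 and ×3), so
the choice of logarithm base in the MI step is immaterial. Scores are
used as generated — no rank re-normalization before or after
aggregation.

## Pearson networks

`score(i, j) = |r_ij|`. Absolute value, because consensus averaging of
signed correlations would let anticorrelated regulation cancel positive
evidence; the synthetic generator draws regulatory weights with random
sign precisely to keep this choice exercised. The implementation uses
the product-moment formula directly — cross-product over
`sqrt(ss_i · ss_j)` — rather than `np.corrcoef`, because that form
returns |r| = 1.0 *exactly* for exactly proportional gene pairs
(scaling numerator and denominator by the same factor commutes with
rounding), a property the noiseless-recovery checks rely on. Constant
genes are detected by zero range and score 0 against all partners.

## Bagging

Conditions are drawn *without replacement* within an iteration — the
random subspace method, although the field's customary name "bootstrap
aggregation" is kept. Subset size is `max(2, floor(f·n))`. The consensus
is the unweighted arithmetic mean of constituent score matrices,
maintained as a running mean (`m += (c − m)/t`), which has two useful
exactness properties: identical constituents leave the consensus
bitwise unchanged (so a fraction-1.0 ensemble equals its parent
network exactly), and the per-iteration change is bounded by
(max constituent entry)/t, giving the O(1/t) MAE decay the convergence
trace displays. Iteration substreams are spawned deterministically from
the master seed, so results do not depend on execution schedule.
Default iteration count is 200; on the default synthetic scenario the
per-iteration consensus movement at iteration 50 is already ~3% of its
iteration-2 value. If inference fails on a degenerate subsample the
iteration redraws, up to 10 times, then aborts.

## Evaluation

*MAE* is averaged over strict upper-triangle pairs, so each undirected
edge counts once. It is computed over **all** pairs, not only
standard-listed ones: stability is defined against the parent network,
not against the standard.

*Precision-recall.* Only pairs listed in the partial standard are
evaluated; masked pairs never enter. The standard is directed while the
networks are undirected, so each directed pair is scored by its
undirected edge score; if both orientations are listed they are
evaluated as two pairs with the same score. All pairs sharing a tied
score enter at a single threshold, making the curve independent of
within-tie ordering, and the area is the rectangular sum
`Σ (R_k − R_{k−1}) P_k` — no trapezoidal interpolation, which is
optimistic between sparse recall levels. Note the rectangular AUPR of a
*random* ranking sits slightly above prevalence at finite size (an
early lucky positive earns precision 1); the property tests bound this
rather than pretending the estimator is unbiased.

*FEO.* Edges with an unannotated endpoint are ignored; if no edge links
two annotated genes the ratio is explicitly undefined (`None`), never
silently 0.

*Statistics.* Welch's two-sided t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) compares replicate metric
samples; p-values are reported raw, without multiple-testing
correction. Confidence bands are Student-t intervals (default level
0.99) — replicate counts of ~10 are too small for normal intervals.
Both are thin wrappers over scipy; the test suite checks them against
hand-integrated t densities.

## Experiment harnesses

All interfaces use the **fraction of conditions remaining** (a setting
of 0.8 means 20% removed); mixing "removed" and "remaining" axes is a
reliable source of off-by-complement bugs. Replicate random streams are
keyed by (master seed, setting value, replicate index) — keyed by the
*value*, not the list position, so adding settings to a sweep never
perturbs existing replicates. Stability and accuracy for a given
(fraction, replicate) are measured on the same constituent network.

`select_fraction_by_stability` implements the selection recipe for
studies without a usable gold standard: build a parent consensus per
candidate fraction, measure each candidate's condition-removal MAE
curve against its own parent, score each curve (mean MAE by default;
max and trapezoidal area are options), and return the argmin — ties to
the smaller fraction — together with that candidate's full-data
consensus. The ensemble seed is held fixed per candidate across the
parent and all reduced runs, so the curve isolates sensitivity to the
*data*: with nothing removed every candidate reproduces its parent
exactly, and replicates differ only in which conditions were dropped.

## Synthetic generator

Linear-Gaussian: regulators are i.i.d. standard normal per condition
(conditions = independent perturbations), targets are weighted sums of
their parents plus N(0, σ) noise, parentless targets are unit noise.
Edge magnitudes are uniform in [0.5, 2] with random sign; a
single-parent edge of weight w has correlation w/√(w² + σ²) with its
parent, so recovery expectations are analytic. The default scenario is
10 regulators, 90 targets, density 0.05, 200 conditions, σ = 0.5 — a
desk-scale stand-in for a perturbation compendium with a sparse
regulatory layer. The standard labels all true edges positive and a
configurable fraction of non-edges negative, leaving the rest masked so
the masking code path is always live. Annotations give each regulator a
random category which targets inherit with probability 0.8.

What this does *not* emulate: kinetic/ODE dynamics, saturation,
combinatorial regulation, time series, batch effects, or the indirect
correlations of deep regulatory cascades. Passing benchmarks here shows
the machinery is correct and that the qualitative phenomena (stability
degrading with data removal, consensus convergence, recovery well above
prevalence) hold under a clean generative model — not that any
particular accuracy level transfers to real compendia.

## Problem sizes

The bundled benchmarks run on 20–100-gene, 40–200-condition scenarios
with 200 bagging iterations at most — sizes chosen so the whole suite
and the acceptance script complete in seconds on one core while still
exercising every code path at meaningful signal-to-noise. The
implementation itself is vectorized (one Gram product per MI matrix)
and handles thousands of genes; memory for the joint-probability block
scales as (genes × bins)².

## Known limitations

* The MI estimator is plug-in; no bias correction is applied. CLR's
  background correction absorbs most of the shared bias.
* Conflicting duplicate rows in a standard (same directed pair labelled
  0 and 1) are rejected rather than reconciled.
* `ExperimentCurve` stores one metric sample set per setting; sweeps
  run a single ensemble per fraction, so sweep points carry no
  confidence band (a band would require re-running ensembles with
  independent seeds).
* FEO depends entirely on the annotation map sharing identifiers with
  the expression matrix; no identifier mapping layer is provided.
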