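# bclr — bootstrap-aggregated co-expression network inference

Small changes to an expression compendium — dropping a handful of
conditions — can substantially rearrange the gene co-expression network
inferred from it. `bclr` implements and evaluates a remedy: *condition
bootstrap aggregation*. Conditions (individual perturbation profiles)
are repeatedly subsampled without replacement, a constituent network is
inferred from each subset, and the constituent edge weights are averaged
into a consensus network. Applied to the context likelihood of
relatedness algorithm this is **BCLR**; a bagged Pearson variant is
included as well.

The package is aimed at people doing gene regulatory / co-expression
network inference from transcriptomic compendia (DREAM5-style
tab-delimited expression tables with partial directed gold standards),
and at anyone who wants to quantify how *stable* their inferred network
is before interpreting it.

## What it computes

**Inference.** For genes X and Y, mutual information is estimated by
B-spline soft binning: each variable is rescaled onto the domain of
`M` spline basis functions of order `k` (defaults M = 10, k = 3), each
sample receives fractional bin memberships summing to 1, and

    MI(X, Y) = Σ_ab p(a,b) · log₂ p(a,b) / (p(a) p(b))      [bits]

with marginal and joint probabilities taken as sample means of the
membership weights. CLR then background-corrects the MI matrix: with
μ_i, σ_i the mean and standard deviation of gene i's MI values against
all other genes,

    z_ij = max(0, (MI_ij − μ_i)/σ_i),   score(i,j) = √(z_ij² + z_ji²).

The Pearson alternative scores each pair by |r|.

**Bagging.** Draw `f·n` conditions without replacement (hard minimum 2),
infer a constituent network, repeat `n_iter` times (default 200), and
average: the consensus is the arithmetic mean of constituent score
matrices. Per-iteration MAE between consecutive running consensus
networks (and optionally AUPR against a standard) tracks convergence.

**Evaluation.**

* *Stability* — mean absolute error over gene pairs between a network
  inferred from reduced data and the parent network inferred from the
  full condition set; lower is more stable.
* *Accuracy* — area under the precision-recall curve against a partial
  directed standard; pairs absent from the standard are masked, directed
  standard pairs are scored by the undirected edge score, and ties share
  one threshold (rectangular integration).
* *Functional edge overlap (FEO)* — among network edges whose both
  endpoints carry functional annotations, the fraction linking genes
  that share a category.
* Replicate statistics: Welch's two-sided t-test (unequal variances) and
  Student-t confidence intervals on per-setting means.

**Experiments.** Condition-removal stability curves, subsampling-
fraction sweeps against the non-bagged baseline, and a stability-driven
procedure that selects the subsampling fraction whose removal curve is
most stable and returns that fraction's full-data consensus — usable
when no gold standard exists to optimize accuracy directly.

**Synthetic data.** A linear-Gaussian generator produces ground-truth
regulator→target networks, perturbation-style expression (each condition
independent; targets = weighted parent sums + noise), partial standards
with masked pairs, and category annotations correlated with regulation —
everything needed to exercise the pipeline end to end at desk scale.

## Worked example

Simulate a 100-gene compendium (10 regulators, 90 targets, edge density
0.05, 200 conditions, noise sd 0.5), run BCLR at a 5% subsampling
fraction, and score the consensus:

```bash
bclr simulate --regulators 10 --targets 90 --density 0.05 \
     --conditions 200 --noise 0.5 --seed 7 --outdir demo
# wrote 100 genes x 200 conditions, 51 true edges, 900 labelled pairs to demo

bclr infer --method clr --expression demo/expression.tsv --out demo/clr.tsv
bclr bag --method clr --fraction 0.05 --iterations 200 --seed 17 \
     --expression demo/expression.tsv --standard demo/standard.tsv \
     --out demo/bclr.tsv --trace demo/trace.tsv
bclr evaluate --network demo/bclr.tsv --expression demo/expression.tsv \
     --parent demo/clr.tsv --standard demo/standard.tsv \
     --annotations demo/annotations.tsv --sizes 100,500 --out demo/report.tsv
cat demo/report.tsv
```

```
metric          value      parameters
mae_vs_parent   0.687475
aupr            0.917417
prevalence      0.0566667
feo_ratio       0.682927   top_n=100
feo_ratio       0.350975   top_n=500
```

Reading this: the consensus ranks true regulator–target pairs almost
perfectly (AUPR 0.917 against a prevalence floor of 0.057 — what an
uninformative ranking would score); its mean edge-weight distance from
the non-bagged CLR parent is 0.69 z-score units, reflecting that a 5%
fraction shows each iteration only 10 conditions; and 68% of its top-100
edges link genes annotated to the same functional category, falling to
35% by 500 edges as weaker edges enter. The trace file shows the
consensus settling: per-iteration MAE drops from 0.63 (iteration 1) to
0.0029 (iteration 200). For comparison, plain CLR on the full data
reaches AUPR 0.920 here — at 200 well-behaved conditions bagging has
little accuracy to add; its value shows on small or noisy condition
sets and in stability.

Every command is also available as a library call (`bclr.infer_clr`,
`bclr.bag_network`, `bclr.condition_removal_experiment`, ...), which is
the more convenient interface for the experiment harnesses.

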