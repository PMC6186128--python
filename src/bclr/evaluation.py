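"""Network evaluation: stability (MAE), accuracy (masked AUPR),
functional edge overlap, and the replicate statistics used by the
experiment harnesses.

Stability is the mean absolute error between a network inferred from
reduced data and the *parent* network inferred from the complete
condition set: low MAE = high stability. Accuracy is the area under the
precision-recall curve against a partial directed standard; pairs absent
from the standard are masked and never evaluated. The standard is
directed while the networks are undirected, so each directed standard
pair is scored by its undirected edge score (if both orientations of a
pair are listed, each is evaluated, with the same score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .containers import AnnotationMap, EdgeStandard, ScoreMatrix

__all__ = [
    "mae",
    "PRCurve",
    "pr_curve",
    "aupr",
    "feo_ratio",
    "WelchResult",
    "welch_ttest",
    "MetricSample",
    "mean_ci",
]


def upper_mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference over the strict upper triangle."""
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.mean(np.abs(a[iu] - b[iu])))


def mae(a: ScoreMatrix, b: ScoreMatrix) -> float:
    """Mean absolute error between two networks over the same genes.

    Averaged over off-diagonal upper-triangle pairs (i < j); each
    undirected edge counts once.
    """
    if a.gene_ids != b.gene_ids:
        diff = set(a.gene_ids) ^ set(b.gene_ids)
        if diff:
            raise ValueError(f"gene sets differ; symmetric difference: {sorted(diff)}")
        raise ValueError("gene identifiers are in different orders")
    return upper_mae(a.scores, b.scores)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall curve over the labelled (unmasked) pairs.

    One point per distinct score threshold, in descending threshold
    order; all pairs sharing a tied score enter together at one
    threshold, so the curve is invariant to their ordering.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_positives: int
    n_evaluated: int

    @property
    def prevalence(self) -> float:
        """Positive fraction among evaluated pairs; the AUPR of an
        uninformative (randomly ranked) network."""
        return self.n_positives / self.n_evaluated


def _standard_scores(
    scores: ScoreMatrix, standard: EdgeStandard
) -> tuple[np.ndarray, np.ndarray]:
    pairs = sorted(standard.positives) + sorted(standard.negatives)
    y = np.concatenate(
        [np.ones(standard.n_positives), np.zeros(standard.n_negatives)]
    )
    s = np.array([scores.pair_score(r, t) for r, t in pairs])
    return s, y


def pr_curve(scores: ScoreMatrix, standard: EdgeStandard) -> PRCurve:
    """Precision-recall curve of a network against a partial standard.

    Only pairs listed in the standard are evaluated; masked pairs are
    ignored entirely. Requires at least one positive and one negative.
    """
    if standard.n_positives == 0 or standard.n_negatives == 0:
        raise ValueError(
            "precision-recall needs at least one positive and one negative "
            f"(got {standard.n_positives} positives, {standard.n_negatives} negatives)"
        )
    s, y = _standard_scores(scores, standard)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # last index of each tie group = a distinct threshold
    boundaries = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([boundaries, [s.size - 1]])
    tp = np.cumsum(y)[cut]
    total = cut + 1.0
    precision = tp / total
    recall = tp / standard.n_positives
    return PRCurve(
        thresholds=s[cut],
        precision=precision,
        recall=recall,
        n_positives=standard.n_positives,
        n_evaluated=s.size,
    )


def aupr(scores: ScoreMatrix, standard: EdgeStandard) -> float:
    """Area under the precision-recall curve, in [0, 1].

    Step-wise (rectangular) summation over distinct thresholds,
    sum_k (recall_k - recall_{k-1}) * precision_k with recall_0 = 0; no
    trapezoidal interpolation, which would be optimistic between
    sparsely separated recall levels.
    """
    curve = pr_curve(scores, standard)
    dr = np.diff(np.concatenate([[0.0], curve.recall]))
    return float(np.sum(dr * curve.precision))


def feo_ratio(
    edges: Iterable[tuple[str, str]], annotations: AnnotationMap
) -> float | None:
    """Functional edge overlap ratio of an edge set.

    Among edges whose *both* endpoints carry at least one functional
    category, the fraction whose category sets intersect. Edges touching
    an unannotated gene are ignored. Returns ``None`` (undefined) when
    no edge links two annotated genes — deliberately distinct from 0,
    which means "edges link annotated genes but never within a category".
    """
    edges = list(edges)
    if not edges:
        raise ValueError("edge set is empty")
    numerator = denominator = 0
    for a, b in edges:
        cats_a = annotations.get(a, set())
        cats_b = annotations.get(b, set())
        if not cats_a or not cats_b:
            continue
        denominator += 1
        if cats_a & cats_b:
            numerator += 1
    if denominator == 0:
        return None
    return numerator / denominator


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    pvalue: float
    df: float


def welch_ttest(xs: Sequence[float], ys: Sequence[float]) -> WelchResult:
    """Two-sided t-test for equal means without assuming equal variances.

    Uses the Welch statistic with Welch-Satterthwaite degrees of
    freedom. Each sample must have at least 2 values: a sample of size 1
    has no variance estimate, so significance cannot be assessed.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError(
            "each sample needs >= 2 values to assess significance "
            f"(got {xs.size} and {ys.size})"
        )
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValueError("samples must be finite")
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return WelchResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), df=float(res.df)
    )


@dataclass(frozen=True)
class MetricSample:
    """Replicate values of one metric at one experimental setting.

    Confidence bounds are Student-t intervals on the mean; they are
    ``None`` when only a single replicate exists (an interval cannot be
    constructed from one sample).
    """

    values: np.ndarray
    mean: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    level: float | None = None

    @property
    def n(self) -> int:
        return int(np.asarray(self.values).size)

    @classmethod
    def from_values(cls, values: Sequence[float], level: float = 0.99) -> "MetricSample":
        values = np.asarray(values, dtype=float)
        if values.size >= 2:
            return mean_ci(values, level)
        return cls(values=values, mean=float(values.mean()))


def mean_ci(samples: Sequence[float], level: float = 0.99) -> MetricSample:
    """Student-t confidence interval on the mean of replicate values.

    mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n). The t construction is
    used because replicate counts here are small (typically 10), too few
    for a normal interval.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a confidence interval")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    n = samples.size
    m = float(samples.mean())
    half = float(
        stats.t.ppf((1.0 + level) / 2.0, n - 1) * samples.std(ddof=1) / np.sqrt(n)
    )
    return MetricSample(
        values=samples, mean=m, ci_lower=m - half, ci_upper=m + half, level=level
    )
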