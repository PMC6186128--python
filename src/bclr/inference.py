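"""Pairwise co-expression scoring: B-spline mutual information with CLR
background correction, or Pearson correlation.

The mutual-information estimator uses B-spline soft binning: each
variable is affinely rescaled onto the B-spline domain spanned by
``num_bins`` basis functions of order ``spline_order`` (order = degree
+ 1, so order 3 means quadratic splines). Each sample then has
fractional membership weights over the bins that sum to 1; marginal bin
probabilities are sample means of those weights, joint probabilities
sample means of weight outer products, and

    MI(X, Y) = sum_ab p(a,b) * log2( p(a,b) / (p(a) p(b)) )   [bits]

Soft binning reduces the variance that hard histogram binning suffers
from samples sitting near bin boundaries, which matters at the small
per-iteration sample sizes bagging produces. Defaults are 10 bins and
order 3.

The context likelihood of relatedness (CLR) step turns the raw MI matrix
into per-pair significance scores: for each gene the mean and standard
deviation of its MI values against all other genes form a background; a
pair's score combines the two one-sided z-scores as

    score(i, j) = sqrt( max(0, z_ij)^2 + max(0, z_ji)^2 ).

CLR scores are invariant to any positive rescaling of the MI matrix,
which in particular makes the choice of logarithm base immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.interpolate import BSpline

from .containers import ExpressionMatrix, ScoreMatrix

__all__ = [
    "CLRConfig",
    "mutual_information",
    "marginal_entropy",
    "mi_matrix",
    "clr_transform",
    "infer_clr",
    "infer_pearson",
    "make_inferencer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CLRConfig:
    """Estimator settings for the B-spline MI / CLR pipeline.

    Attributes
    ----------
    num_bins : int
        Number of B-spline basis functions ("bins"). Default 10.
    spline_order : int
        B-spline order (degree + 1). Order 1 recovers hard histogram
        binning. Default 3. Must not exceed ``num_bins``.
    """

    num_bins: int = 10
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.num_bins < 2:
            raise ValueError("num_bins must be >= 2")
        if not (1 <= self.spline_order <= self.num_bins):
            raise ValueError("spline_order must satisfy 1 <= order <= num_bins")

    def effective(self, n_samples: int) -> "CLRConfig":
        """Clamp bins (and if needed order) to the sample count.

        With fewer samples than bins the estimator is vacuously
        over-parameterized; small condition subsets (down to 2
        conditions at extreme subsampling fractions) must still run, so
        the bin count is reduced to the sample count with a warning
        rather than raising.
        """
        bins = min(self.num_bins, n_samples)
        order = min(self.spline_order, bins)
        if bins != self.num_bins or order != self.spline_order:
            logger.warning(
                "reducing B-spline binning to %d bins / order %d for %d samples",
                bins, order, n_samples,
            )
            return CLRConfig(bins, order)
        return self


def _spline_knots(num_bins: int, order: int) -> np.ndarray:
    # Open-uniform knot vector: `order` repeats at each end, unit spacing
    # inside; the basis spans [0, num_bins - order + 1] and partitions unity.
    interior = np.arange(1, num_bins - order + 1, dtype=float)
    return np.concatenate(
        [np.zeros(order), interior, np.full(order, num_bins - order + 1.0)]
    )


def spline_weights(x: np.ndarray, config: CLRConfig) -> np.ndarray | None:
    """Fractional bin-membership weights for each sample.

    Returns an (n_samples, num_bins) matrix whose rows sum to 1, or
    ``None`` for a constant vector (degenerate marginal: the affine
    rescaling to the spline domain is undefined).
    """
    x = np.asarray(x, dtype=float)
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return None
    span = config.num_bins - config.spline_order + 1
    z = (x - xmin) * (span / (xmax - xmin))
    np.clip(z, 0.0, span, out=z)
    knots = _spline_knots(config.num_bins, config.spline_order)
    w = BSpline.design_matrix(
        z, knots, config.spline_order - 1, extrapolate=False
    ).toarray()
    return w


def marginal_entropy(x: np.ndarray, config: CLRConfig = CLRConfig()) -> float:
    """Shannon entropy (bits) of one variable under the soft binning."""
    x = np.asarray(x, dtype=float)
    cfg = config.effective(x.size)
    w = spline_weights(x, cfg)
    if w is None:
        logger.warning("marginal_entropy: constant vector, returning 0")
        return 0.0
    p = w.mean(axis=0)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    x: np.ndarray, y: np.ndarray, config: CLRConfig = CLRConfig()
) -> float:
    """B-spline mutual information between two equal-length vectors, in bits.

    A constant input gives MI 0 (with a logged warning); tiny negative
    values from floating point are clamped to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"inputs must be 1-d vectors of equal length, got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    cfg = config.effective(x.size)
    wx = spline_weights(x, cfg)
    wy = spline_weights(y, cfg)
    if wx is None or wy is None:
        logger.warning("mutual_information: constant input vector, returning 0")
        return 0.0
    n = x.size
    pxy = wx.T @ wy / n
    px = wx.mean(axis=0)
    py = wy.mean(axis=0)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log2(pxy[mask] / np.outer(px, py)[mask])))
    return max(mi, 0.0)


def mi_matrix(expr: ExpressionMatrix, config: CLRConfig = CLRConfig()) -> np.ndarray:
    """All-pairs B-spline MI for the genes of an expression matrix.

    Returns a symmetric (n_genes, n_genes) array. The diagonal holds the
    estimator's self-MI (retained for diagnostics); it is excluded from
    CLR background statistics downstream. Rows of constant genes are 0.

    The computation is a single Gram product over the stacked weight
    matrices, so it matches per-pair :func:`mutual_information` calls to
    floating-point reordering (~1e-12) rather than bitwise.
    """
    n, s = expr.n_genes, expr.n_conditions
    cfg = config.effective(s)
    b = cfg.num_bins
    weights = []
    valid = np.zeros(n, dtype=bool)
    for g in range(n):
        w = spline_weights(expr.values[g], cfg)
        if w is not None:
            valid[g] = True
            weights.append(w)
        else:
            logger.warning(
                "mi_matrix: gene %r is constant; its MI values are 0",
                expr.gene_ids[g],
            )
    mi = np.zeros((n, n))
    if not weights:
        return mi
    W = np.stack(weights)               # (nv, s, b)
    nv = W.shape[0]
    p = W.mean(axis=1)                  # marginals (nv, b)
    plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    H = -plogp.sum(axis=1)              # marginal entropies (nv,)

    Wt = W.transpose(0, 2, 1).reshape(nv * b, s)
    G = (Wt @ Wt.T) / s                 # joint probabilities, all pairs
    G = (G + G.T) / 2.0                 # exact symmetry despite BLAS reordering
    glog = np.where(G > 0, G * np.log2(np.where(G > 0, G, 1.0)), 0.0)
    Hjoint = -glog.reshape(nv, b, nv, b).sum(axis=(1, 3))
    sub = H[:, None] + H[None, :] - Hjoint
    sub = (sub + sub.T) / 2.0  # block sums reorder additions; re-symmetrize
    np.clip(sub, 0.0, None, out=sub)
    idx = np.flatnonzero(valid)
    mi[np.ix_(idx, idx)] = sub
    return mi


def clr_transform(mi: np.ndarray, gene_ids: list[str]) -> ScoreMatrix:
    """Background-correct an MI matrix into CLR scores.

    For gene i the background mean and population standard deviation are
    taken over MI(i, k), k != i. z_ij = max(0, (MI(i,j) - mu_i) / sd_i)
    (z defined as 0 where sd_i = 0), and score(i, j) =
    sqrt(z_ij^2 + z_ji^2).
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if mi.ndim != 2 or mi.shape != (n, n):
        raise ValueError("MI matrix must be square")
    if n < 3:
        raise ValueError("CLR needs at least 3 genes for background statistics")
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match the MI matrix")
    if not np.allclose(mi, mi.T, rtol=0.0, atol=1e-8):
        raise ValueError("MI matrix must be symmetric")

    off_sum = mi.sum(axis=1) - np.diagonal(mi)
    mu = off_sum / (n - 1)
    off_sq = (mi**2).sum(axis=1) - np.diagonal(mi) ** 2
    var = off_sq / (n - 1) - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))

    z = np.zeros_like(mi)
    nz = sd > 0
    z[nz, :] = (mi[nz, :] - mu[nz, None]) / sd[nz, None]
    np.clip(z, 0.0, None, out=z)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix(list(gene_ids), scores)


def infer_clr(expr: ExpressionMatrix, config: CLRConfig = CLRConfig()) -> ScoreMatrix:
    """CLR network: B-spline MI on every gene pair, background-corrected.

    Deterministic for a fixed input.
    """
    if expr.n_genes < 3:
        raise ValueError("CLR needs at least 3 genes")
    return clr_transform(mi_matrix(expr, config), expr.gene_ids)


def infer_pearson(expr: ExpressionMatrix) -> ScoreMatrix:
    """Correlation network: score(i, j) = |Pearson r| across conditions.

    Absolute values are used so that anticorrelated regulation counts as
    evidence rather than cancelling during consensus averaging. Constant
    genes get score 0 against every partner (logged).
    """
    if expr.n_conditions < 2:
        raise ValueError("Pearson network needs at least 2 conditions")
    # product-moment formula on demeaned rows; dividing the cross product
    # by sqrt(ss_i * ss_j) directly keeps exactly proportional gene pairs
    # at |r| == 1.0 (np.corrcoef's row normalization loses the last ulp)
    d = expr.values - expr.values.mean(axis=1, keepdims=True)
    cross = d @ d.T
    ss = np.diagonal(cross).copy()
    # flag constants by range, not by ss: the rounded mean of a constant
    # row can leave a nonzero sum of squares
    constant = (np.ptp(expr.values, axis=1) == 0) | (ss == 0)
    if constant.any():
        logger.warning(
            "infer_pearson: constant gene(s) %s scored 0 against all partners",
            [expr.gene_ids[i] for i in np.flatnonzero(constant)],
        )
        ss[constant] = 1.0  # avoid 0/0; their rows are zeroed below
    with np.errstate(invalid="ignore"):
        r = cross / np.sqrt(np.outer(ss, ss))
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    scores = np.abs(r)
    np.clip(scores, 0.0, 1.0, out=scores)
    upper = np.triu(scores, k=1)  # mirror the upper triangle: exact symmetry
    scores = upper + upper.T
    return ScoreMatrix(list(expr.gene_ids), scores)


Method = Literal["clr", "pearson"]


def make_inferencer(
    method: Method, config: CLRConfig | None = None
) -> Callable[[ExpressionMatrix], ScoreMatrix]:
    """Bind a method name (+ CLR settings) into an expr -> network callable."""
    if method == "clr":
        cfg = config or CLRConfig()
        return lambda expr: infer_clr(expr, cfg)
    if method == "pearson":
        return infer_pearson
    raise ValueError(f"unknown inference method {method!r}")
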