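"""Condition bootstrap aggregation (random subspace ensemble).

Each iteration draws a fraction of the conditions *without replacement*
(so, strictly, a random subspace draw rather than a classical
bootstrap — the field's "bootstrap aggregation" name is kept), infers a
constituent network from the subset, and the consensus network is the
unweighted arithmetic mean of the constituent edge weights. Constituent
scores are used as generated — no per-constituent rank normalization.

Convergence is tracked by the mean absolute difference between
consecutive running consensus networks (and optionally by the AUPR of
the running consensus against a supplied standard). For a running mean
the per-iteration change is bounded by (max constituent weight) / t, so
the MAE trace decays like 1/t once constituents stop surprising the
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .containers import EdgeStandard, ExpressionMatrix, ScoreMatrix
from .evaluation import aupr, upper_mae
from .inference import CLRConfig, Method, make_inferencer

__all__ = [
    "BaggingConfig",
    "BaggingResult",
    "ConvergenceSummary",
    "subsample_conditions",
    "bag_network",
    "convergence_summary",
]

#: how many fresh subsample draws to attempt when inference fails on a
#: degenerate subset before giving up
_MAX_RETRIES = 10


@dataclass(frozen=True)
class BaggingConfig:
    """Ensemble settings.

    Attributes
    ----------
    fraction : float in (0, 1]
        Subsampling fraction: the share of conditions drawn (without
        replacement) per iteration, subject to a hard minimum of 2
        conditions.
    iterations : int
        Number of constituent networks, default 200 (enough for the
        consensus to converge; see :func:`convergence_summary`).
    seed : int
        Master seed; together with the config and input it fully
        determines the result.
    method : {"clr", "pearson"}
        Underlying inference method.
    clr : CLRConfig
        Estimator settings when method is "clr".
    """

    fraction: float
    iterations: int = 200
    seed: int = 0
    method: Method = "clr"
    clr: CLRConfig = field(default_factory=CLRConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be a positive integer")

    def with_(self, **kwargs) -> "BaggingConfig":
        return replace(self, **kwargs)


@dataclass
class BaggingResult:
    """Consensus network plus per-iteration convergence traces."""

    consensus: ScoreMatrix
    mae_trace: np.ndarray
    aupr_trace: Optional[np.ndarray]
    iterations_run: int
    config: BaggingConfig

    def __post_init__(self) -> None:
        if len(self.mae_trace) != self.iterations_run:
            raise ValueError("mae_trace length must equal iterations_run")
        if self.aupr_trace is not None and len(self.aupr_trace) != self.iterations_run:
            raise ValueError("aupr_trace length must equal iterations_run")
        if np.any(self.mae_trace < 0):
            raise ValueError("mae_trace entries must be nonnegative")


def subsample_conditions(
    expr: ExpressionMatrix, fraction: float, rng: np.random.Generator
) -> ExpressionMatrix:
    """Draw a random condition subset without replacement.

    Keeps max(2, floor(fraction * n_conditions)) distinct conditions,
    uniformly at random, preserving their original relative order; all
    genes are retained. The floor of 2 lets fraction sweeps reach down
    to 0.01 without ever producing a subset too small to correlate over.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = expr.n_conditions
    if n < 2:
        raise ValueError("need at least 2 conditions to subsample")
    k = max(2, int(np.floor(fraction * n)))
    idx = rng.choice(n, size=k, replace=False)
    return expr.subset_conditions(idx)


def bag_network(
    expr: ExpressionMatrix,
    config: BaggingConfig,
    standard: EdgeStandard | None = None,
) -> BaggingResult:
    """Bootstrap-aggregate an inference method over condition subsets.

    For t = 1..iterations: draw a subsample, infer a constituent
    network, and fold it into the running mean. The MAE between the
    running consensus at t and at t-1 is recorded (the first entry is
    the MAE against the zero matrix); if a standard is supplied, the
    AUPR of the running consensus is recorded as well. Per-iteration
    random streams are spawned deterministically from the master seed,
    so the result is independent of execution order.

    If inference fails on a degenerate subsample the iteration retries
    with a fresh draw, up to 10 times.
    """
    k = max(2, int(np.floor(config.fraction * expr.n_conditions)))
    if k > expr.n_conditions:
        raise ValueError("fraction infeasible: fewer than 2 conditions available")
    infer = make_inferencer(config.method, config.clr)
    children = np.random.SeedSequence(config.seed).spawn(config.iterations)

    consensus: np.ndarray | None = None
    mae_trace: list[float] = []
    aupr_trace: list[float] = []
    for t, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        last_err: Exception | None = None
        for _ in range(_MAX_RETRIES):
            sub = subsample_conditions(expr, config.fraction, rng)
            try:
                constituent = infer(sub)
                break
            except Exception as err:  # degenerate subset; redraw
                last_err = err
        else:
            raise RuntimeError(
                f"iteration {t}: inference failed on {_MAX_RETRIES} "
                f"consecutive subsamples"
            ) from last_err
        c = constituent.scores
        if consensus is None:
            previous = np.zeros_like(c)
            consensus = c.copy()
        else:
            previous = consensus.copy()
            # running-mean update; keeps the consensus bitwise equal to a
            # constituent when every constituent is identical
            consensus += (c - consensus) / t
        mae_trace.append(upper_mae(consensus, previous))
        if standard is not None:
            aupr_trace.append(
                aupr(ScoreMatrix(list(expr.gene_ids), consensus.copy()), standard)
            )

    assert consensus is not None
    return BaggingResult(
        consensus=ScoreMatrix(list(expr.gene_ids), consensus),
        mae_trace=np.asarray(mae_trace),
        aupr_trace=np.asarray(aupr_trace) if standard is not None else None,
        iterations_run=config.iterations,
        config=config,
    )


@dataclass(frozen=True)
class ConvergenceSummary:
    converged: bool
    tail_mean: float
    tail_slope: float
    tolerance: float
    window: int


def convergence_summary(
    result: BaggingResult, window: int, tolerance: float | None = None
) -> ConvergenceSummary:
    """Assess whether the consensus has stopped moving.

    Converged iff the mean of the last ``window`` MAE-trace entries is
    below ``tolerance`` (default: 1e-3 times the mean consensus edge
    weight, i.e. per-iteration movement is below a tenth of a percent of
    a typical edge). Also reports the least-squares slope of the trace
    tail.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > result.iterations_run:
        raise ValueError(
            f"window {window} exceeds the {result.iterations_run} iterations run"
        )
    if tolerance is None:
        tolerance = 1e-3 * float(result.consensus.triu_values().mean())
    tail = result.mae_trace[-window:]
    slope = float(np.polyfit(np.arange(window), tail, 1)[0]) if window > 1 else 0.0
    return ConvergenceSummary(
        converged=bool(tail.mean() < tolerance),
        tail_mean=float(tail.mean()),
        tail_slope=slope,
        tolerance=float(tolerance),
        window=window,
    )
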