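"""Experiment harnesses: condition-removal stability curves,
subsampling-fraction sweeps, and stability-driven fraction selection.

Axis convention: every interface speaks in terms of the *fraction of
conditions remaining* (a point at 0.8 means 20% of the conditions were
removed). Converting once at the boundary prevents off-by-complement
mistakes between "fraction removed" and "fraction kept".

Seeding: replicate random streams derive from (master seed, a key of the
setting value, replicate index), so adding or reordering settings never
perturbs the replicates of existing ones, and every curve is exactly
reproducible from (input, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .bagging import BaggingConfig, bag_network, subsample_conditions
from .containers import EdgeStandard, ExpressionMatrix, ScoreMatrix
from .evaluation import MetricSample, aupr, mae
from .inference import make_inferencer

__all__ = [
    "ExperimentCurve",
    "SelectionResult",
    "condition_removal_experiment",
    "subsample_sweep",
    "select_fraction_by_stability",
    "plot_curve",
]

logger = logging.getLogger(__name__)

InferFn = Callable[[ExpressionMatrix], ScoreMatrix]


def _setting_key(value: float) -> int:
    # stable integer key for a fraction, exact for 6 decimal places
    return int(round(value * 1_000_000))


def _derived_rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def _derived_seed(seed: int, *keys: int) -> int:
    # a plain integer seed (< 2^31) for nested BaggingConfig objects
    return int(
        np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class ExperimentCurve:
    """Per-setting replicate metrics along one experimental axis.

    ``settings`` is strictly increasing; ``metrics`` maps a metric name
    ("mae", "aupr") to one :class:`MetricSample` per setting.
    """

    settings: list[float]
    metrics: dict[str, list[MetricSample]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.settings, self.settings[1:])):
            raise ValueError("settings must be strictly increasing")
        for name, samples in self.metrics.items():
            if len(samples) != len(self.settings):
                raise ValueError(
                    f"metric {name!r} has {len(samples)} samples for "
                    f"{len(self.settings)} settings"
                )

    def means(self, metric: str) -> np.ndarray:
        return np.array([s.mean for s in self.metrics[metric]])


def condition_removal_experiment(
    expr: ExpressionMatrix,
    infer_fn: InferFn,
    fractions_remaining: Sequence[float],
    repeats: int = 10,
    standard: EdgeStandard | None = None,
    seed: int = 0,
    ci_level: float = 0.99,
) -> ExperimentCurve:
    """Stability (and optionally accuracy) under condition removal.

    The parent network is inferred from the full condition set. For each
    fraction remaining and each of ``repeats`` replicates, a random
    condition subset of that size is drawn without replacement, a
    constituent network is inferred from it, and its MAE against the
    parent — plus, if a standard is supplied, its AUPR — is recorded.
    MAE and AUPR for a given (fraction, replicate) come from the same
    constituent network.
    """
    if repeats < 1:
        raise ValueError("repeats must be positive")
    fractions = sorted(float(f) for f in fractions_remaining)
    if not fractions:
        raise ValueError("no fractions given")
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction remaining {f} outside (0, 1]")
    parent = infer_fn(expr)
    mae_samples: list[MetricSample] = []
    aupr_samples: list[MetricSample] = []
    for f in fractions:
        maes, auprs = [], []
        for r in range(repeats):
            rng = _derived_rng(seed, _setting_key(f), r)
            try:
                sub = subsample_conditions(expr, f, rng)
                net = infer_fn(sub)
            except Exception:
                logger.error(
                    "repeat failed at fraction=%s repeat=%d (seed=%s)", f, r, seed
                )
                raise
            maes.append(mae(net, parent))
            if standard is not None:
                auprs.append(aupr(net, standard))
        mae_samples.append(MetricSample.from_values(maes, ci_level))
        if standard is not None:
            aupr_samples.append(MetricSample.from_values(auprs, ci_level))
    metrics = {"mae": mae_samples}
    if standard is not None:
        metrics["aupr"] = aupr_samples
    return ExperimentCurve(
        settings=fractions,
        metrics=metrics,
        metadata={"repeats": repeats, "seed": seed, "ci_level": ci_level},
    )


def subsample_sweep(
    expr: ExpressionMatrix,
    standard: EdgeStandard,
    fractions: Sequence[float],
    config: BaggingConfig,
    seed: int | None = None,
) -> ExperimentCurve:
    """Consensus accuracy across subsampling fractions.

    Runs the bagged ensemble once per fraction and records the consensus
    AUPR; the non-bagged baseline (the same inference method on the full
    condition set) is evaluated once and stored in the curve metadata as
    ``baseline_aupr``. Each ensemble's seed derives from the master seed
    and the fraction, so fractions can be added without disturbing
    existing points.
    """
    fracs = sorted(float(f) for f in fractions)
    if not fracs:
        raise ValueError("no fractions given")
    master = config.seed if seed is None else seed
    baseline_net = make_inferencer(config.method, config.clr)(expr)
    baseline = aupr(baseline_net, standard)
    samples = []
    for f in fracs:
        cfg = config.with_(fraction=f, seed=_derived_seed(master, _setting_key(f)))
        result = bag_network(expr, cfg)
        samples.append(MetricSample.from_values([aupr(result.consensus, standard)]))
    return ExperimentCurve(
        settings=fracs,
        metrics={"aupr": samples},
        metadata={
            "baseline_aupr": baseline,
            "method": config.method,
            "iterations": config.iterations,
            "seed": master,
        },
    )


@dataclass
class SelectionResult:
    """Outcome of stability-driven subsampling-fraction selection."""

    selected_fraction: float
    stability_scores: dict[float, float]
    curves: dict[float, ExperimentCurve]
    consensus: ScoreMatrix
    parents: dict[float, ScoreMatrix]


_OBJECTIVES = ("mean", "max", "auc")


def select_fraction_by_stability(
    expr: ExpressionMatrix,
    candidate_fractions: Sequence[float],
    fractions_remaining: Sequence[float],
    repeats: int,
    config: BaggingConfig,
    seed: int | None = None,
    objective: str = "mean",
) -> SelectionResult:
    """Pick the subsampling fraction whose condition-removal curve is
    most stable, then keep its full-data consensus.

    For each candidate fraction f: (i) build the parent consensus on the
    full condition set; (ii) for each fraction remaining and replicate,
    reduce the condition set and rebuild the consensus, recording its
    MAE against that parent; (iii) score f by the ``objective`` over the
    curve (mean MAE by default; "max" and trapezoidal "auc" are
    alternatives); (iv) return the candidate with the smallest score
    (ties go to the smaller fraction) together with its full-data
    consensus.

    The ensemble seed is held fixed per candidate across the parent and
    all reduced runs, so the curve measures sensitivity to the *data*
    rather than to the bagging randomness; replicates differ only in
    which conditions are removed.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {_OBJECTIVES}")
    if repeats < 1:
        raise ValueError("repeats must be positive")
    candidates = sorted(float(f) for f in candidate_fractions)
    remaining = sorted(float(f) for f in fractions_remaining)
    if not candidates or not remaining:
        raise ValueError("candidate and remaining fraction lists must be nonempty")
    master = config.seed if seed is None else seed

    scores: dict[float, float] = {}
    curves: dict[float, ExperimentCurve] = {}
    parents: dict[float, ScoreMatrix] = {}
    for f in candidates:
        bag_seed = _derived_seed(master, _setting_key(f))
        cfg = config.with_(fraction=f, seed=bag_seed)
        parent = bag_network(expr, cfg).consensus
        parents[f] = parent
        samples = []
        all_maes = []
        per_setting_means = []
        for g in remaining:
            maes = []
            for r in range(repeats):
                rng = _derived_rng(master, _setting_key(f), _setting_key(g), r)
                reduced = subsample_conditions(expr, g, rng)
                result = bag_network(reduced, cfg)
                maes.append(mae(result.consensus, parent))
            samples.append(MetricSample.from_values(maes))
            all_maes.extend(maes)
            per_setting_means.append(float(np.mean(maes)))
        curves[f] = ExperimentCurve(
            settings=remaining,
            metrics={"mae": samples},
            metadata={"candidate_fraction": f, "repeats": repeats, "seed": master},
        )
        if objective == "mean":
            scores[f] = float(np.mean(all_maes))
        elif objective == "max":
            scores[f] = float(np.max(all_maes))
        else:
            if len(remaining) > 1:
                scores[f] = float(np.trapezoid(per_setting_means, remaining))
            else:
                scores[f] = per_setting_means[0]

    selected = min(candidates, key=lambda f: (scores[f], f))
    return SelectionResult(
        selected_fraction=selected,
        stability_scores=scores,
        curves=curves,
        consensus=parents[selected],
        parents=parents,
    )


def plot_curve(
    curve: ExperimentCurve,
    path: str | Path,
    metric: str = "mae",
    xlabel: str = "fraction of conditions remaining",
    baseline: float | None = None,
) -> None:
    """Plot a per-setting mean with its confidence band to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = curve.metrics[metric]
    x = np.asarray(curve.settings)
    mean = np.array([s.mean for s in samples])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(x, mean, marker="o", lw=1.5, label=metric.upper())
    if all(s.ci_lower is not None for s in samples):
        lo = np.array([s.ci_lower for s in samples])
        hi = np.array([s.ci_upper for s in samples])
        ax.fill_between(x, lo, hi, alpha=0.25, label=f"{samples[0].level:.0%} CI")
    if baseline is not None:
        ax.axhline(baseline, color="gray", ls="--", lw=1, label="baseline")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(metric.upper())
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
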