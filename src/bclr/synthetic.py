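"""Synthetic regulatory networks, expression compendia, partial
standards and functional annotations.

The generator emulates, at desk scale, the structure of a perturbation
compendium with a partial "silver standard": a bipartite
regulator -> target network, expression where each condition is an
independent perturbation, a directed edge standard that labels all true
edges positive plus a random subset of non-edges negative (everything
else masked), and gene -> category annotations in which targets tend to
share their regulator's category.

The expression model is linear-Gaussian: per condition each regulator
is drawn standard normal, and each target is the weighted sum of its
parents plus Gaussian observation noise (parentless targets are pure
unit-variance noise). This is deliberately far simpler than a kinetic
ODE simulator — it has no dynamics, saturation, or combinatorial logic —
but it produces exactly the statistical objects the inference and
evaluation machinery consumes, with tunable signal-to-noise. Under it a
single-parent edge of weight w and noise sd sigma has Pearson
correlation w / sqrt(w^2 + sigma^2), which makes recovery expectations
computable in closed form.

Regulatory weights have random sign so that anticorrelated true edges
exercise the |r| scoring convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import AnnotationMap, EdgeStandard, ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "generate_regulatory_network",
    "simulate_expression",
    "make_standard",
    "generate_annotations",
    "default_scenario",
    "write_truth",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth directed regulatory network.

    ``edges`` maps (regulator_id, target_id) to a nonzero real weight.
    """

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    seed: int | None = None

    def __post_init__(self) -> None:
        reg = set(self.regulators)
        tgt = set(self.targets)
        if reg & tgt:
            raise ValueError("regulator and target identifiers must be disjoint")
        for (r, t), w in self.edges.items():
            if r == t:
                raise ValueError(f"self-edge ({r}, {t}) not allowed")
            if r not in reg or t not in tgt:
                raise ValueError(f"edge ({r}, {t}) outside the declared id sets")
            if w == 0:
                raise ValueError(f"edge ({r}, {t}) has zero weight")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.regulators) + list(self.targets)

    def parents_of(self, target: str) -> dict[str, float]:
        return {r: w for (r, t), w in self.edges.items() if t == target}


def generate_regulatory_network(
    n_regulators: int,
    n_targets: int,
    density: float,
    weight_range: tuple[float, float] = (0.5, 2.0),
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Random bipartite regulator -> target network.

    Each of the n_regulators x n_targets ordered pairs is an edge
    independently with probability ``density``. Edge magnitudes are
    uniform in ``weight_range`` with a uniformly random sign. Targets
    may end up parentless (isolated); they still appear in the gene set.
    """
    if n_regulators < 1 or n_targets < 1:
        raise ValueError("need at least one regulator and one target")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    lo, hi = weight_range
    if not 0.0 < lo <= hi:
        raise ValueError("weight_range must be a positive interval")
    rng = rng if rng is not None else np.random.default_rng()
    regulators = tuple(f"TF{i + 1}" for i in range(n_regulators))
    targets = tuple(f"G{i + 1}" for i in range(n_targets))
    edges: dict[tuple[str, str], float] = {}
    for r in regulators:
        for t in targets:
            if rng.random() < density:
                w = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
                edges[(r, t)] = float(w)
    return SyntheticTruth(regulators, targets, edges)


def simulate_expression(
    truth: SyntheticTruth,
    n_conditions: int,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Linear-Gaussian expression for a truth network.

    Conditions are independent perturbations: regulators are i.i.d.
    standard normal per condition; each target is the weighted sum of
    its parents plus N(0, noise_sd) observation noise; parentless
    targets are pure N(0, 1) noise. Regulators are included as observed
    genes so regulator -> target recovery is evaluable directly.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng()
    n_reg, n_tgt = len(truth.regulators), len(truth.targets)
    reg_values = rng.standard_normal((n_reg, n_conditions))
    reg_index = {r: i for i, r in enumerate(truth.regulators)}
    tgt_values = np.zeros((n_tgt, n_conditions))
    for j, t in enumerate(truth.targets):
        parents = truth.parents_of(t)
        if parents:
            for r, w in parents.items():
                tgt_values[j] += w * reg_values[reg_index[r]]
            if noise_sd > 0:
                tgt_values[j] += rng.normal(0.0, noise_sd, n_conditions)
        else:
            tgt_values[j] = rng.standard_normal(n_conditions)
    values = np.vstack([reg_values, tgt_values])
    condition_ids = [f"C{i + 1}" for i in range(n_conditions)]
    return ExpressionMatrix(truth.gene_ids, condition_ids, values)


def make_standard(
    truth: SyntheticTruth,
    negative_fraction: float,
    rng: np.random.Generator | None = None,
) -> EdgeStandard:
    """Partial directed standard derived from the truth network.

    All true edges become positives. Each non-edge (regulator, target)
    pair independently becomes a negative with probability
    ``negative_fraction``; the remaining pairs stay masked, so the
    masking path of the evaluation code is always exercised (except at
    negative_fraction = 1, which labels every pair).
    """
    if not 0.0 < negative_fraction <= 1.0:
        raise ValueError("negative_fraction must be in (0, 1]")
    if not truth.edges:
        raise ValueError("truth network has no edges")
    rng = rng if rng is not None else np.random.default_rng()
    positives = frozenset(truth.edges)
    non_edges = [
        (r, t)
        for r in truth.regulators
        for t in truth.targets
        if (r, t) not in truth.edges
    ]
    if not non_edges:
        raise ValueError("no non-edges available to label negative")
    if negative_fraction == 1.0:
        negatives = frozenset(non_edges)
    else:
        keep = rng.random(len(non_edges)) < negative_fraction
        negatives = frozenset(p for p, k in zip(non_edges, keep) if k)
    return EdgeStandard(positives, negatives, frozenset(truth.gene_ids))


def generate_annotations(
    truth: SyntheticTruth,
    n_categories: int,
    annotated_fraction: float,
    rng: np.random.Generator | None = None,
    inherit_prob: float = 0.8,
) -> AnnotationMap:
    """Functional categories correlated with regulatory structure.

    Each regulator gets one uniformly random category. Each target
    inherits the category of a random parent with probability
    ``inherit_prob`` (default 0.8), otherwise a uniformly random
    category; parentless targets always draw at random. Finally each
    gene is kept in the map independently with probability
    ``annotated_fraction``, so unannotated-endpoint handling in the FEO
    computation is exercised.
    """
    if n_categories < 1:
        raise ValueError("need at least one category")
    if not 0.0 < annotated_fraction <= 1.0:
        raise ValueError("annotated_fraction must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    categories = [f"K{i + 1}" for i in range(n_categories)]
    assigned: dict[str, str] = {}
    for r in truth.regulators:
        assigned[r] = categories[rng.integers(n_categories)]
    for t in truth.targets:
        parents = sorted(truth.parents_of(t))
        if parents and rng.random() < inherit_prob:
            assigned[t] = assigned[parents[rng.integers(len(parents))]]
        else:
            assigned[t] = categories[rng.integers(n_categories)]
    mapping: AnnotationMap = {}
    for gene, cat in assigned.items():
        if rng.random() < annotated_fraction:
            mapping[gene] = {cat}
    return mapping


def default_scenario(
    seed: int,
    n_regulators: int = 10,
    n_targets: int = 90,
    density: float = 0.05,
    n_conditions: int = 200,
    noise_sd: float = 0.5,
    negative_fraction: float = 1.0,
    n_categories: int = 5,
    annotated_fraction: float = 0.8,
) -> tuple[SyntheticTruth, ExpressionMatrix, EdgeStandard, AnnotationMap]:
    """The standard desk-scale scenario: 100 genes (10 regulators,
    90 targets), edge density 0.05, 200 conditions, noise sd 0.5.

    Independent substreams drive network topology, expression noise,
    standard labelling and annotations, so changing one stage never
    perturbs the others.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    truth = generate_regulatory_network(
        n_regulators, n_targets, density, rng=np.random.default_rng(ss[0])
    )
    if not truth.edges:  # resample pathological empty topologies
        truth = generate_regulatory_network(
            n_regulators, n_targets, density,
            rng=np.random.default_rng(ss[0].spawn(1)[0]),
        )
    expr = simulate_expression(
        truth, n_conditions, noise_sd, rng=np.random.default_rng(ss[1])
    )
    standard = make_standard(
        truth, negative_fraction, rng=np.random.default_rng(ss[2])
    )
    annotations = generate_annotations(
        truth, n_categories, annotated_fraction, rng=np.random.default_rng(ss[3])
    )
    return truth, expr, standard, annotations


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the true weighted edges as ``regulator<TAB>target<TAB>weight``."""
    with open(path, "w", encoding="utf-8") as fh:
        for (r, t), w in sorted(truth.edges.items()):
            fh.write(f"{r}\t{t}\t{w:.6g}\n")
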