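"""Core in-memory containers shared across the package.

Axis conventions, fixed once and used everywhere:

* An :class:`ExpressionMatrix` is genes x conditions. A *condition* is one
  expression profile arising from one perturbation (growth condition,
  genotype, time point); conditions are the unit resampled by bagging.
* A :class:`ScoreMatrix` ("network") is a symmetric, nonnegative
  gene x gene edge-confidence matrix with a zero diagonal. Networks here
  are undirected: the score of (i, j) and (j, i) is the same number.
* An :class:`EdgeStandard` is a *partial* set of directed
  (regulator, target) labels. Pairs listed with label 1 are positives,
  label 0 negatives; every unlisted pair is masked and never enters an
  evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ExpressionMatrix", "ScoreMatrix", "EdgeStandard", "AnnotationMap"]

#: gene id -> set of functional-category ids; genes absent from the mapping
#: are treated as unannotated.
AnnotationMap = dict[str, set[str]]


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """Real-valued genes x conditions expression table.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    condition_ids : sequence of str
        Unique condition identifiers, one per column.
    values : ndarray, shape (n_genes, n_conditions)
        Expression values in arbitrary (assumed normalized) units.
        Every entry must be finite.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        self.values = np.asarray(self.values, dtype=float)
        for axis, ids in (("gene", self.gene_ids), ("condition", self.condition_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {axis} identifier(s): {dups}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.condition_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if len(self.gene_ids) < 2:
            raise ValueError("an expression matrix needs at least 2 genes")
        if len(self.condition_ids) < 2:
            raise ValueError("an expression matrix needs at least 2 conditions")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"condition {self.condition_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def subset_conditions(self, indices: Iterable[int]) -> "ExpressionMatrix":
        """Return a copy restricted to the given condition columns.

        Indices are sorted so the original relative condition order is
        preserved regardless of draw order.
        """
        idx = sorted(int(i) for i in indices)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            condition_ids=[self.condition_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
        )


@dataclass
class ScoreMatrix:
    """Symmetric nonnegative gene x gene edge-confidence matrix.

    Scores are in the units produced by the inference method: combined
    background-corrected z-scores for CLR, |Pearson r| for correlation
    networks, or averages thereof for bagged consensus networks.
    """

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValueError(f"duplicate gene identifier(s): {dups}")
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(f"scores shape {self.scores.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("scores matrix is not symmetric")
        if np.any(np.diagonal(self.scores) != 0.0):
            raise ValueError("scores diagonal must be zero")
        if np.any(self.scores < 0.0):
            raise ValueError("scores must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in score matrix") from None

    def pair_score(self, gene_a: str, gene_b: str) -> float:
        """Score of the undirected edge between two genes."""
        return float(self.scores[self.index_of(gene_a), self.index_of(gene_b)])

    def triu_values(self) -> np.ndarray:
        """Upper-triangle (i < j) scores as a flat vector."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.scores[iu]


@dataclass(frozen=True)
class EdgeStandard:
    """Partial directed edge standard ("silver standard").

    ``positives`` and ``negatives`` are disjoint sets of ordered
    (regulator, target) pairs; every pair in neither set is masked,
    i.e. its label is unknown and it is skipped during evaluation.
    """

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]
    gene_universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"pairs labelled both positive and negative: {sorted(overlap)[:5]}"
            )
        for pair in list(self.positives) + list(self.negatives):
            if pair[0] == pair[1]:
                raise ValueError(f"self-pair {pair} not allowed in an edge standard")
        if self.gene_universe is not None:
            universe = frozenset(self.gene_universe)
            object.__setattr__(self, "gene_universe", universe)
            for r, t in list(self.positives) + list(self.negatives):
                for g in (r, t):
                    if g not in universe:
                        raise ValueError(
                            f"identifier {g!r} not in the declared gene universe"
                        )

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_negatives(self) -> int:
        return len(self.negatives)

    @property
    def n_labelled(self) -> int:
        return len(self.positives) + len(self.negatives)
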