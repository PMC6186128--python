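"""Readers and writers for the tab-delimited file dialects.

Canonical on-disk layouts (all TSV, UTF-8):

* Expression, ``conditions-by-genes`` (the DREAM5-style dialect): one
  header row of gene identifiers, then one row of numbers per condition.
  Condition identifiers are not stored; they are synthesized as
  ``C1..Cn`` on load.
* Expression, ``genes-by-conditions``: header row is a corner label
  followed by condition identifiers; each data row starts with a gene
  identifier. Both layouts load into the same canonical in-memory
  orientation (genes x conditions).
* Standard: three columns ``regulator<TAB>target<TAB>label`` with label
  in {0, 1}. Unlisted pairs are masked.
* Annotations: two columns ``gene<TAB>category``; a gene may repeat with
  different categories.
* Network edge list: three columns ``geneA<TAB>geneB<TAB>score``, one
  undirected edge per line, scores with 6 significant digits. Networks
  are never written as dense matrix dumps: at compendium scale
  (thousands of genes, millions of pairs) a dense text dump is
  impractical and an edge list is the interoperable form.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .containers import AnnotationMap, EdgeStandard, ExpressionMatrix, ScoreMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_standard",
    "write_standard",
    "read_annotations",
    "write_annotations",
    "write_edge_list",
    "read_edge_list",
]

logger = logging.getLogger(__name__)

Orientation = Literal["conditions-by-genes", "genes-by-conditions"]

_ORIENTATIONS = ("conditions-by-genes", "genes-by-conditions")


def _read_rows(path: str | Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            rows.append(line.split("\t"))
    return rows


def _parse_cell(token: str, row: int, col: int, path: str | Path) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {token!r} at data row {row}, column {col}"
        ) from None


def read_expression(
    path: str | Path, orientation: Orientation = "conditions-by-genes"
) -> ExpressionMatrix:
    """Load a tab-delimited expression table into genes x conditions form.

    Parameters
    ----------
    path : path-like
        TSV file with a single header row of identifiers.
    orientation : {"conditions-by-genes", "genes-by-conditions"}
        On-disk layout. ``conditions-by-genes`` (default) has a gene-id
        header and one row per condition; condition ids are synthesized
        as ``C1..Cn``. ``genes-by-conditions`` has a condition-id header
        (optionally preceded by a corner label) and gene ids in the
        first column.

    Returns
    -------
    ExpressionMatrix
        Always in canonical genes x conditions orientation.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header, body = rows[0], rows[1:]

    if orientation == "conditions-by-genes":
        gene_ids = header
        n_genes = len(gene_ids)
        values = np.empty((len(body), n_genes))
        for r, row in enumerate(body, start=1):
            if len(row) != n_genes:
                raise ValueError(
                    f"{path}: data row {r} has {len(row)} fields, expected {n_genes}"
                )
            for c, tok in enumerate(row):
                values[r - 1, c] = _parse_cell(tok, r, c + 1, path)
        condition_ids = [f"C{i + 1}" for i in range(len(body))]
        return ExpressionMatrix(gene_ids, condition_ids, values.T)

    # genes-by-conditions: allow a corner label in the header
    n_fields = len(body[0])
    if len(header) == n_fields:
        condition_ids = header[1:]
    elif len(header) == n_fields - 1:
        condition_ids = header
    else:
        raise ValueError(
            f"{path}: header has {len(header)} fields but data rows have {n_fields}"
        )
    gene_ids = []
    values = np.empty((len(body), len(condition_ids)))
    for r, row in enumerate(body, start=1):
        if len(row) != len(condition_ids) + 1:
            raise ValueError(
                f"{path}: data row {r} has {len(row)} fields, "
                f"expected {len(condition_ids) + 1}"
            )
        gene_ids.append(row[0])
        for c, tok in enumerate(row[1:]):
            values[r - 1, c] = _parse_cell(tok, r, c + 2, path)
    return ExpressionMatrix(gene_ids, condition_ids, values)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    orientation: Orientation = "conditions-by-genes",
) -> None:
    """Write an expression matrix in either on-disk layout (lossless)."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    with open(path, "w", encoding="utf-8") as fh:
        if orientation == "conditions-by-genes":
            fh.write("\t".join(expr.gene_ids) + "\n")
            for c in range(expr.n_conditions):
                fh.write(
                    "\t".join(f"{v:.17g}" for v in expr.values[:, c]) + "\n"
                )
        else:
            fh.write("gene\t" + "\t".join(expr.condition_ids) + "\n")
            for g in range(expr.n_genes):
                fh.write(
                    expr.gene_ids[g]
                    + "\t"
                    + "\t".join(f"{v:.17g}" for v in expr.values[g])
                    + "\n"
                )


def read_standard(
    path: str | Path,
    gene_universe: Iterable[str],
    allow_extra: bool = False,
) -> EdgeStandard:
    """Load a partial directed edge standard.

    Rows are ``regulator<TAB>target<TAB>label`` with label in {0, 1};
    label 1 pairs become positives, label 0 negatives, and every pair
    not listed stays masked. Identifiers outside ``gene_universe`` are a
    hard error unless ``allow_extra`` is set, in which case the rows are
    dropped with a logged count (silent identifier mismatch is the
    dominant failure mode in network benchmarking).
    """
    universe = frozenset(str(g) for g in gene_universe)
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    dropped = 0
    for lineno, row in enumerate(_read_rows(path), start=1):
        if len(row) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(row)}"
            )
        reg, tgt, label = row
        if reg == tgt:
            raise ValueError(f"{path}:{lineno}: self-pair ({reg}, {tgt}) not allowed")
        try:
            lab = float(label)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: label {label!r} is not a number") from None
        if lab not in (0.0, 1.0):
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
        missing = [g for g in (reg, tgt) if g not in universe]
        if missing:
            if allow_extra:
                dropped += 1
                continue
            raise ValueError(
                f"{path}:{lineno}: identifier {missing[0]!r} not in the gene universe"
            )
        (positives if lab == 1.0 else negatives).add((reg, tgt))
    if dropped:
        logger.info("read_standard: dropped %d row(s) outside the gene universe", dropped)
    return EdgeStandard(frozenset(positives), frozenset(negatives), universe)


def write_standard(standard: EdgeStandard, path: str | Path) -> None:
    """Write a standard as sorted ``regulator<TAB>target<TAB>label`` rows."""
    rows = [(r, t, 1) for r, t in standard.positives] + [
        (r, t, 0) for r, t in standard.negatives
    ]
    with open(path, "w", encoding="utf-8") as fh:
        for r, t, lab in sorted(rows):
            fh.write(f"{r}\t{t}\t{lab}\n")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Load ``gene<TAB>category`` rows into a gene -> categories mapping.

    A gene may appear on several rows; its categories accumulate into a
    set, so the result is independent of row order and of duplicated
    rows. Genes absent from the file are simply unannotated.
    """
    mapping: AnnotationMap = {}
    for lineno, row in enumerate(_read_rows(path), start=1):
        if len(row) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(row)}"
            )
        gene, category = row
        mapping.setdefault(gene, set()).add(category)
    return mapping


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annotations):
            for category in sorted(annotations[gene]):
                fh.write(f"{gene}\t{category}\n")


def _ranked_edges(scores: ScoreMatrix) -> list[tuple[float, str, str]]:
    """All undirected edges sorted by descending score, ties broken
    lexicographically by (geneA, geneB) with geneA < geneB."""
    n = scores.n_genes
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((scores.gene_ids[i], scores.gene_ids[j]))
            edges.append((scores.scores[i, j], a, b))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return edges


def write_edge_list(
    scores: ScoreMatrix, path: str | Path, top_n: int | None = None
) -> int:
    """Write the top-n undirected edges by descending score.

    Ties are broken lexicographically by (geneA, geneB) so the output is
    deterministic. Returns the number of edges written.
    """
    n_pairs = scores.n_genes * (scores.n_genes - 1) // 2
    if top_n is None:
        top_n = n_pairs
    if top_n <= 0:
        raise ValueError("top_n must be a positive integer")
    if top_n > n_pairs:
        raise ValueError(
            f"top_n={top_n} exceeds the {n_pairs} available gene pairs"
        )
    edges = _ranked_edges(scores)[:top_n]
    with open(path, "w", encoding="utf-8") as fh:
        for score, a, b in edges:
            fh.write(f"{a}\t{b}\t{score:.6g}\n")
    return top_n


def read_edge_list(
    path: str | Path, gene_ids: Iterable[str] | None = None
) -> ScoreMatrix:
    """Load an edge list back into a (possibly sparse-in-zeros) ScoreMatrix.

    Pairs absent from the file get score 0. If ``gene_ids`` is not
    given, the gene set is the sorted union of identifiers in the file.
    """
    rows = _read_rows(path)
    parsed: list[tuple[str, str, float]] = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(row)}"
            )
        a, b, s = row
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-edge ({a}, {b}) not allowed")
        parsed.append((a, b, _parse_cell(s, lineno, 3, path)))
    if gene_ids is None:
        genes = sorted({g for a, b, _ in parsed for g in (a, b)})
    else:
        genes = [str(g) for g in gene_ids]
    index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(genes)))
    for a, b, s in parsed:
        for g in (a, b):
            if g not in index:
                raise ValueError(f"{path}: identifier {g!r} not in the gene universe")
        mat[index[a], index[b]] = s
        mat[index[b], index[a]] = s
    return ScoreMatrix(genes, mat)
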