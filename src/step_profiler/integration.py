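"""Map called targets to cell types via averaged, scaled expression.

The core assignment rule: average log-normalized expression of each target
gene within each cell type, z-score each gene's averages across cell types,
and assign the gene to the cell type holding the strict row maximum. Ties
and zero-variance rows are reported as ambiguous, never broken arbitrarily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Sentinel assignment for targets without a strict maximum cell type.
AMBIGUOUS = "AMBIGUOUS"

MIN_CELLS_WARN = 10


@dataclass
class LabeledCounts:
    """Gene x cell non-negative integer count matrix with per-cell type labels."""

    gene_ids: list[str]
    counts: sparse.spmatrix | np.ndarray
    cell_labels: list[str]

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_labels) != n_cells:
            raise ValidationError(
                f"cell_labels length {len(self.cell_labels)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        data = self.counts.data if sparse.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (not np.isfinite(data).all() or (data < 0).any()):
            raise ValidationError("counts must be finite and non-negative")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_labels))


@dataclass
class CellTypeProfile:
    """Target-gene x cell-type expression matrix at the averaged or scaled stage."""

    values: pd.DataFrame  # rows: target genes, columns: cell types
    stage: str  # "averaged" | "scaled"
    n_unmapped: int = 0
    zero_variance_genes: list[str] = field(default_factory=list)

    @property
    def target_genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.values.columns]


@dataclass
class AssignmentResult:
    """Per-target cell-type assignment and per-type tallies."""

    assignments: dict[str, str]  # gene -> cell type or AMBIGUOUS
    counts: dict[str, int]  # cell type -> number of assigned targets
    n_unmapped: int

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for v in self.assignments.values() if v == AMBIGUOUS)


def normalize_cells(
    counts: LabeledCounts, scale_total: float = 10_000.0
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Library-size normalize each cell to ``scale_total`` and log1p transform.

    Returns ``(norm, kept)`` where ``norm`` is the gene x kept-cell CSR
    matrix and ``kept`` is the boolean mask of cells with non-zero totals.
    Zero-total cells are excluded with a log message.
    """
    if scale_total <= 0:
        raise ValidationError(f"scale_total must be positive, got {scale_total}")
    mat = sparse.csr_matrix(counts.counts, dtype=float)
    totals = np.asarray(mat.sum(axis=0)).ravel()
    if totals.sum() == 0:
        raise ValidationError("count matrix is all zeros")
    kept = totals > 0
    if not kept.all():
        logger.warning("excluding %d cells with zero total counts", int((~kept).sum()))
    mat = mat[:, kept]
    scale = scale_total / totals[kept]
    norm = mat.multiply(scale[np.newaxis, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return norm, kept


def average_by_celltype(
    norm: sparse.spmatrix | np.ndarray,
    gene_ids: list[str],
    labels: list[str],
    target_genes: list[str],
) -> CellTypeProfile:
    """Average normalized expression of each target gene within each cell type.

    Targets absent from ``gene_ids`` are counted as unmapped, not dropped
    silently. Raises if no target maps into the matrix.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in target_genes if g in gene_index]
    n_unmapped = len(target_genes) - len(present)
    if not present:
        raise ValidationError(
            "no target gene found in the expression matrix; check protein-to-gene id mapping"
        )
    if n_unmapped:
        logger.info("%d target genes absent from the expression matrix", n_unmapped)

    labels_arr = np.asarray(labels)
    cell_types = sorted(set(labels))
    for ct in cell_types:
        n = int((labels_arr == ct).sum())
        if n < MIN_CELLS_WARN:
            logger.warning("cell type %r has only %d cells; means may be unstable", ct, n)

    rows = [gene_index[g] for g in present]
    sub = norm[rows, :]
    sub = sub.toarray() if sparse.issparse(sub) else np.asarray(sub, dtype=float)

    means = np.empty((len(present), len(cell_types)))
    for j, ct in enumerate(cell_types):
        means[:, j] = sub[:, labels_arr == ct].mean(axis=1)
    values = pd.DataFrame(means, index=present, columns=cell_types)
    return CellTypeProfile(values=values, stage="averaged", n_unmapped=n_unmapped)


def scale_rows(profile: CellTypeProfile) -> CellTypeProfile:
    """Z-score each row across cell types (sample SD, ddof=1).

    Zero-variance rows become all zeros and are flagged.
    """
    if profile.stage != "averaged":
        raise ValidationError(f"scale_rows expects an averaged profile, got {profile.stage!r}")
    if profile.values.shape[1] < 2:
        raise ValidationError("scaling needs >= 2 cell types")
    values = profile.values.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd.ravel() == 0
    sd[degenerate[:, np.newaxis]] = 1.0
    scaled = (values - mean) / sd
    scaled[degenerate, :] = 0.0
    out = pd.DataFrame(scaled, index=profile.values.index, columns=profile.values.columns)
    return CellTypeProfile(
        values=out,
        stage="scaled",
        n_unmapped=profile.n_unmapped,
        zero_variance_genes=[str(g) for g, d in zip(profile.values.index, degenerate) if d],
    )


def assign_targets(profile: CellTypeProfile, tie_tol: float = 1e-12) -> AssignmentResult:
    """Assign each target to the cell type holding its strict row maximum.

    A row whose top two values agree within ``tie_tol``, or that was flagged
    zero-variance during scaling, is assigned :data:`AMBIGUOUS`.
    """
    if profile.stage != "scaled":
        raise ValidationError(f"assign_targets expects a scaled profile, got {profile.stage!r}")
    cell_types = profile.cell_types
    degenerate = set(profile.zero_variance_genes)
    assignments: dict[str, str] = {}
    counts = {ct: 0 for ct in cell_types}
    values = profile.values.to_numpy(dtype=float)
    for gene, row in zip(profile.target_genes, values):
        if gene in degenerate:
            assignments[gene] = AMBIGUOUS
            continue
        order = np.argsort(row)
        best = order[-1]
        if row[best] - row[order[-2]] <= tie_tol:
            assignments[gene] = AMBIGUOUS
            continue
        assignments[gene] = cell_types[best]
        counts[cell_types[best]] += 1
    return AssignmentResult(assignments=assignments, counts=counts, n_unmapped=profile.n_unmapped)


def rank_celltypes(result: AssignmentResult) -> list[tuple[str, int]]:
    """Cell types ordered by assigned-target count, ties broken lexicographically."""
    return sorted(result.counts.items(), key=lambda kv: (-kv[1], kv[0]))
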