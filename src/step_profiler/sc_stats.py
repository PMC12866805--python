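"""Rank-sum DEG calling and per-cell gene-set scoring.

DEG gate: |log2FC| >= 0.25 and BH-adjusted p < 0.05 (note the adjusted p,
unlike the chemoproteomics gate which uses raw p).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .chemoproteomics import benjamini_hochberg
from .errors import ValidationError

#: Below this per-group size the rank-sum p is computed by exact enumeration.
EXACT_MAX_N = 8


def _exact_two_sided_p(ranks: np.ndarray, nx: int, w: float) -> float:
    # p = 2 * min(P(W <= w), P(W >= w)) over all C(n, nx) rank splits,
    # capped at 1; midranks make the enumeration valid under ties.
    n_le = 0
    n_ge = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(ranks.size), nx):
        s = ranks[list(idx)].sum()
        n_le += s <= w + eps
        n_ge += s >= w - eps
        total += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midrank tie handling.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x`` in the pooled
    sample. Exact enumeration when either group has fewer than
    :data:`EXACT_MAX_N` observations, otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 1 or y.size < 1:
        raise ValidationError("wilcoxon_rank_sum requires non-empty groups")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())

    _, tie_counts = np.unique(pooled, return_counts=True)
    if tie_counts.size == 1:  # every value identical
        return w, 1.0

    if min(nx, ny) < EXACT_MAX_N:
        return w, _exact_two_sided_p(ranks, nx, w)

    mu = nx * (n + 1) / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    d = w - mu
    d -= 0.5 * np.sign(d)  # continuity correction
    z = d / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def call_degs(
    norm: sparse.spmatrix | np.ndarray,
    gene_ids: list[str],
    labels: list[str],
    group_a: str,
    group_b: str,
    lfc_thresh: float = 0.25,
    padj_thresh: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene rank-sum DEG calling between two cell groups.

    ``log2fc = log2((mean_a + pseudocount) / (mean_b + pseudocount))`` on
    normalized expression; BH adjustment across all tested genes; a gene is
    a DEG iff ``|log2fc| >= lfc_thresh`` and ``p_adj < padj_thresh``.
    """
    labels_arr = np.asarray(labels)
    mask_a = labels_arr == group_a
    mask_b = labels_arr == group_b
    if not mask_a.any():
        raise ValidationError(f"group {group_a!r} has no cells")
    if not mask_b.any():
        raise ValidationError(f"group {group_b!r} has no cells")

    mat = norm.toarray() if sparse.issparse(norm) else np.asarray(norm, dtype=float)
    a = mat[:, mask_a]
    b = mat[:, mask_b]

    log2fc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    p_values = np.empty(len(gene_ids))
    for i in range(len(gene_ids)):
        _, p_values[i] = wilcoxon_rank_sum(a[i], b[i])
    p_adj = benjamini_hochberg(p_values)
    is_deg = (np.abs(log2fc) >= lfc_thresh) & (p_adj < padj_thresh)

    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p_values, "p_adj": p_adj, "is_deg": is_deg},
        index=pd.Index(gene_ids, name="gene"),
    )
    return out.sort_values("p_value", kind="mergesort")


def score_gene_set(
    norm: sparse.spmatrix | np.ndarray,
    gene_ids: list[str],
    gene_set: set[str] | list[str],
) -> np.ndarray:
    """Per-cell gene-set score: mean across set genes of each gene's z-score.

    Each gene is z-scored across all cells (sample SD); zero-variance genes
    contribute 0. Raises if the set shares no gene with the matrix.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rows = [gene_index[g] for g in gene_set if g in gene_index]
    if not rows:
        raise ValidationError("gene set has no overlap with the expression matrix")
    mat = norm[sorted(rows), :]
    mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat, dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd.ravel() == 0
    sd[degenerate[:, np.newaxis]] = 1.0
    z = (mat - mean) / sd
    z[degenerate, :] = 0.0
    return z.mean(axis=0)
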