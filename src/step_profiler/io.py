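"""Readers and writers for the on-disk formats.

Quant tables and sidecars are plain TSV; count matrices use the Matrix
Market exchange format with ``genes.tsv`` / ``barcodes.tsv`` /
``celltypes.tsv`` sidecars; gene sets use GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .chemoproteomics import QuantTable
from .enrichment import GeneSetCollection
from .errors import ValidationError
from .integration import AssignmentResult, CellTypeProfile, LabeledCounts


# -- quant tables -----------------------------------------------------------

def write_quant_table(table: QuantTable, quant_path: str | Path, groups_path: str | Path) -> None:
    df = table.intensities.copy()
    df.index.name = "protein_id"
    df.to_csv(quant_path, sep="\t")
    groups = pd.DataFrame(
        {"channel": list(table.channel_groups), "group": list(table.channel_groups.values())}
    )
    groups.to_csv(groups_path, sep="\t", index=False)


def read_quant_table(quant_path: str | Path, groups_path: str | Path) -> QuantTable:
    df = pd.read_csv(quant_path, sep="\t", index_col="protein_id")
    groups_df = pd.read_csv(groups_path, sep="\t")
    if not {"channel", "group"} <= set(groups_df.columns):
        raise ValidationError("groups TSV must have 'channel' and 'group' columns")
    groups = dict(zip(groups_df["channel"].astype(str), groups_df["group"].astype(str)))
    return QuantTable(df, groups)


# -- labeled count matrices -------------------------------------------------

def write_labeled_counts(counts: LabeledCounts, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(counts.counts)
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in counts.gene_ids))
    barcodes = [f"cell{i:06d}" for i in range(len(counts.cell_labels))]
    (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
    (outdir / "celltypes.tsv").write_text(
        "".join(f"{b}\t{ct}\n" for b, ct in zip(barcodes, counts.cell_labels))
    )


def read_labeled_counts(indir: str | Path) -> LabeledCounts:
    indir = Path(indir)
    mat = sparse.csr_matrix(scipy_io.mmread(str(indir / "matrix.mtx")))
    gene_ids = (indir / "genes.tsv").read_text().splitlines()
    celltypes = pd.read_csv(
        indir / "celltypes.tsv", sep="\t", header=None, names=["barcode", "cell_type"]
    )
    return LabeledCounts(
        gene_ids=gene_ids, counts=mat, cell_labels=celltypes["cell_type"].astype(str).tolist()
    )


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for set_id, (description, members) in collection.sets.items():
        lines.append("\t".join([set_id, description, *sorted(members)]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    sets: dict[str, tuple[str, set[str]]] = {}
    members_union: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line (need id, description, members): {line!r}")
        set_id, description, *members = parts
        if set_id in sets:
            raise ValidationError(f"duplicate set id in GMT: {set_id!r}")
        sets[set_id] = (description, set(members))
        members_union |= sets[set_id][1]
    return GeneSetCollection(sets=sets, universe=universe if universe is not None else members_union)


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# -- integration outputs ----------------------------------------------------

def write_profile(profile: CellTypeProfile, path: str | Path) -> None:
    df = profile.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_assignment(result: AssignmentResult, assign_path: str | Path, counts_path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene": list(result.assignments), "cell_type": list(result.assignments.values())}
    )
    df.to_csv(assign_path, sep="\t", index=False)
    payload = {
        "counts": dict(sorted(result.counts.items())),
        "n_assigned": result.n_assigned,
        "n_ambiguous": result.n_ambiguous,
        "n_unmapped": result.n_unmapped,
    }
    Path(counts_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column protein-to-gene id map, tab-separated, optional header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("id map must have two tab-separated columns")
    first_row = df.iloc[0].tolist()
    if first_row[:2] in (["protein_id", "gene"], ["protein", "gene"]):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
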