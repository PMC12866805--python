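"""Synthetic data generators with planted ground truth.

Every generator is deterministic given its config (which carries the seed):
TMT-style reporter tables with a planted probe-vs-competition effect,
multi-cell-type negative-binomial count matrices with planted per-type
enrichment, and gene-set collections with one planted enriched term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .chemoproteomics import QuantTable
from .enrichment import GeneSetCollection
from .errors import ConfigError
from .integration import LabeledCounts


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    true_target_ids: set[str] = field(default_factory=set)
    target_home_celltype: dict[str, str] = field(default_factory=dict)
    enriched_term_id: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_target_ids": sorted(self.true_target_ids),
            "target_home_celltype": dict(sorted(self.target_home_celltype.items())),
            "enriched_term_id": self.enriched_term_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_target_ids=set(payload["true_target_ids"]),
            target_home_celltype=payload["target_home_celltype"],
            enriched_term_id=payload["enriched_term_id"],
        )


@dataclass
class ChemoSimConfig:
    """Simulation design for a probe-vs-competition TMT table."""

    n_proteins: int = 1000
    n_true_targets: int = 50
    planted_log2fc: float = 2.0
    intensity_cv: float = 0.2
    n_probe_channels: int = 3
    n_comp_channels: int = 3
    baseline_log10_intensity_range: tuple[float, float] = (4.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError(f"n_proteins must be positive, got {self.n_proteins}")
        if not 0 <= self.n_true_targets <= self.n_proteins:
            raise ConfigError(
                f"n_true_targets must be in [0, n_proteins], got {self.n_true_targets}"
            )
        if self.intensity_cv <= 0:
            raise ConfigError(f"intensity_cv must be positive, got {self.intensity_cv}")
        if self.n_probe_channels < 2:
            raise ConfigError(f"n_probe_channels must be >= 2, got {self.n_probe_channels}")
        if self.n_comp_channels < 2:
            raise ConfigError(f"n_comp_channels must be >= 2, got {self.n_comp_channels}")
        lo, hi = self.baseline_log10_intensity_range
        if not lo <= hi:
            raise ConfigError(
                f"baseline_log10_intensity_range must be (lo, hi) with lo <= hi, got {lo, hi}"
            )


def simulate_chemoproteomics(cfg: ChemoSimConfig) -> tuple[QuantTable, SimTruth]:
    """Simulate reporter intensities with a planted effect on true targets.

    Per-protein baseline drawn log-uniformly, multiplicative log-normal
    noise per channel with the configured CV (unit mean), and probe-group
    channels of true targets multiplied by ``2**planted_log2fc``.
    """
    rng = np.random.default_rng(cfg.seed)
    protein_ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    target_rows = rng.choice(cfg.n_proteins, size=cfg.n_true_targets, replace=False)

    lo, hi = cfg.baseline_log10_intensity_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=cfg.n_proteins)

    n_channels = cfg.n_probe_channels + cfg.n_comp_channels
    # log-normal with unit mean and coefficient of variation = intensity_cv
    sigma = np.sqrt(np.log1p(cfg.intensity_cv**2))
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(cfg.n_proteins, n_channels))

    intensities = baseline[:, np.newaxis] * noise
    intensities[target_rows, : cfg.n_probe_channels] *= 2.0**cfg.planted_log2fc

    channels = [f"probe_{i + 1}" for i in range(cfg.n_probe_channels)] + [
        f"comp_{i + 1}" for i in range(cfg.n_comp_channels)
    ]
    groups = {c: ("probe" if c.startswith("probe_") else "competition") for c in channels}
    table = QuantTable(
        pd.DataFrame(intensities, index=pd.Index(protein_ids, name="protein_id"), columns=channels),
        groups,
    )
    truth = SimTruth(true_target_ids={protein_ids[i] for i in target_rows})
    return table, truth


@dataclass
class ScSimConfig:
    """Simulation design for a labeled negative-binomial count matrix.

    ``planted_map`` maps a gene id (or integer gene index) to
    ``(home cell type, enrichment_fold)``; the gene's NB mean is multiplied
    by the fold in cells of its home type.
    """

    cell_types: tuple[str, ...] = ("A", "B", "C", "D")
    cells_per_type: int = 100
    n_genes: int = 500
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    planted_map: dict[str | int, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) == 0:
            raise ConfigError("cell_types must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigError("cell_types must be unique")
        if self.cells_per_type <= 0:
            raise ConfigError(f"cells_per_type must be positive, got {self.cells_per_type}")
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.baseline_mean <= 0:
            raise ConfigError(f"baseline_mean must be positive, got {self.baseline_mean}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be positive, got {self.dispersion}")
        for gene, (home, fold) in self.planted_map.items():
            if home not in self.cell_types:
                raise ConfigError(f"planted_map: home cell type {home!r} not in cell_types")
            if fold < 1:
                raise ConfigError(f"planted_map: enrichment_fold must be >= 1, got {fold}")
            if isinstance(gene, int) and not 0 <= gene < self.n_genes:
                raise ConfigError(f"planted_map: gene index {gene} out of range")

    def gene_id(self, i: int) -> str:
        return f"g{i:05d}"


def simulate_scrna(cfg: ScSimConfig) -> tuple[LabeledCounts, SimTruth]:
    """Simulate a gene x cell NB count matrix with planted per-type enrichment.

    Variance follows ``mean + mean**2 / dispersion``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [cfg.gene_id(i) for i in range(cfg.n_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    labels = [ct for ct in cfg.cell_types for _ in range(cfg.cells_per_type)]
    labels_arr = np.asarray(labels)
    n_cells = len(labels)

    means = np.full((cfg.n_genes, n_cells), float(cfg.baseline_mean))
    truth = SimTruth()
    for gene, (home, fold) in cfg.planted_map.items():
        if isinstance(gene, int):
            row = gene
        else:
            if gene not in gene_index:
                raise ConfigError(f"planted_map: unknown gene id {gene!r}")
            row = gene_index[gene]
        means[row, labels_arr == home] *= fold
        truth.target_home_celltype[gene_ids[row]] = home

    theta = cfg.dispersion
    p = theta / (theta + means)
    counts = rng.negative_binomial(theta, p)
    return LabeledCounts(gene_ids=gene_ids, counts=sparse.csr_matrix(counts), cell_labels=labels), truth


def simulate_gene_sets(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: list[str],
    query: list[str],
    planted_query_overlap: int,
    seed: int = 0,
) -> tuple[GeneSetCollection, SimTruth]:
    """Random gene sets plus one set planted to overlap ``query``.

    Exactly one set shares ``planted_query_overlap`` genes with the query;
    all other sets are sampled uniformly from the universe.
    """
    lo, hi = set_size_range
    if n_sets <= 0:
        raise ConfigError(f"n_sets must be positive, got {n_sets}")
    if not 0 < lo <= hi <= len(universe):
        raise ConfigError(
            f"set_size_range must satisfy 0 < lo <= hi <= |universe|, got {set_size_range}"
        )
    if planted_query_overlap > hi:
        raise ConfigError(
            f"planted_query_overlap {planted_query_overlap} exceeds max set size {hi}"
        )
    if planted_query_overlap > len(query):
        raise ConfigError(
            f"planted_query_overlap {planted_query_overlap} exceeds query size {len(query)}"
        )

    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(sorted(universe))
    query_arr = np.asarray(sorted(set(query)))
    non_query = np.asarray(sorted(set(universe) - set(query)))

    planted_idx = int(rng.integers(n_sets))
    sets: dict[str, tuple[str, set[str]]] = {}
    planted_id = None
    for i in range(n_sets):
        set_id = f"SET{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i == planted_idx:
            size = max(size, planted_query_overlap)
            from_query = rng.choice(query_arr, size=planted_query_overlap, replace=False)
            n_rest = size - planted_query_overlap
            if n_rest > len(non_query):
                raise ConfigError(
                    "planted set cannot be filled outside the query; enlarge the universe"
                )
            rest = rng.choice(non_query, size=n_rest, replace=False)
            members = set(from_query) | set(rest)
            planted_id = set_id
            description = "planted enriched term"
        else:
            members = set(rng.choice(universe_arr, size=size, replace=False))
            description = "random set"
        sets[set_id] = (description, members)

    collection = GeneSetCollection(sets=sets, universe=set(universe))
    return collection, SimTruth(enriched_term_id=planted_id)
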