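# step-profiler

Single-cell target profiling: call drug-bound protein targets from a
competitive chemoproteomics TMT table, then map each called target to the
cell type where it is most expressed in a cell-type-labeled scRNA-seq
matrix. Supporting statistics — pooled t-test target gating, Wilcoxon
rank-sum DEG calling, per-cell gene-set scoring, and hypergeometric
over-representation with Benjamini–Hochberg correction — are included, as
is a synthetic-data module that generates every input with planted ground
truth so each stage is verifiable by parameter recovery.

## Pipeline

1. **chemoproteomics** — per-protein `log2fc = log2(mean(probe)/mean(competition))`
   on (median-normalized) reporter intensities, pooled-variance t-test on
   log2 intensities, BH adjustment; targets pass `|FC| > 1.2` and `p < 0.05`
   (both thresholds configurable, adjusted-p gating optional).
2. **celltype_integration** — library-size normalize each cell to 10,000
   counts and `log1p`; average target-gene expression per cell type; z-score
   each gene's averages across cell types (sample SD); assign each target to
   the cell type holding the strict row maximum (exact ties → `AMBIGUOUS`);
   rank cell types by assigned-target count.
3. **single_cell_stats** — rank-sum DEGs with the gate
   `|log2FC| >= 0.25 AND p_adj < 0.05`; per-cell gene-set scores (mean of
   per-gene z-scores).
4. **enrichment** — one-sided hypergeometric tail per GMT set, size filters
   5–500, BH across tested sets.

## CLI

```bash
# synthetic inputs with planted truth
step-profiler simulate chemoproteomics --config chemo.yaml --seed 1 --outdir sim/
step-profiler simulate scrna          --config scrna.yaml --seed 1 --outdir sim/counts/
step-profiler simulate genesets       --config gs.yaml    --seed 1 --outdir sim/gs/

# stage commands
step-profiler call-targets --quant sim/quant.tsv --groups sim/groups.tsv \
    --fc 1.2 --p 0.05 --out calls.tsv
step-profiler integrate --counts sim/counts --targets calls.tsv --map ids.tsv --outdir out/
step-profiler deg --counts sim/counts --group-a CDDP --group-b Sham --out degs.tsv
step-profiler score-set --counts sim/counts --gmt sets.gmt --set-id SET0001 --out scores.tsv
step-profiler enrich --query query.txt --gmt sets.gmt --universe universe.txt --out enrich.tsv

# full run from one YAML config (simulated or real inputs)
step-profiler run --config run.yaml
```

A minimal simulated `run.yaml`:

```yaml
seed: 7
outdir: out
simulate:
  chemo: {n_proteins: 1000, n_true_targets: 50, planted_log2fc: 2.0, intensity_cv: 0.1}
  scrna:
    cell_types: [PT, DCT, LOH, CD, Endothelial, Macrophage, Tcell, Bcell]
    cells_per_type: 200
    n_genes: 2000
    baseline_mean: 1.0
    dispersion: 2.0
    home_celltype: PT
    enrichment_fold: 4.0
  genesets: {n_sets: 50, set_size_range: [10, 60], planted_query_overlap: 30}
gate: {fc_thresh: 1.2, p_thresh: 0.05}
```

For real inputs replace `simulate:` with an `inputs:` section pointing at
`quant`/`groups` TSVs, a `counts_dir` (Matrix Market `matrix.mtx` +
`genes.tsv`/`barcodes.tsv`/`celltypes.tsv`), and optionally `id_map`
(protein→gene TSV) and `gmt`. The run writes stage TSVs, an assignment
counts JSON, and a deterministic `report.json` whose counts satisfy
`assigned + ambiguous + unmapped = called`.

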