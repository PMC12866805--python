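import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from step_profiler import (
    AMBIGUOUS,
    CellTypeProfile,
    LabeledCounts,
    ScSimConfig,
    ValidationError,
    assign_targets,
    average_by_celltype,
    normalize_cells,
    rank_celltypes,
    scale_rows,
    simulate_scrna,
)


def profile_from(values, stage="scaled", **kwargs):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"T{j}" for j in range(len(values[0]))],
    )
    return CellTypeProfile(values=df, stage=stage, **kwargs)


class TestNormalizeCells:
    def test_direct_formula(self):
        lc = LabeledCounts(["g0", "g1"], np.array([[2], [8]]), ["A"])
        norm, kept = normalize_cells(lc, scale_total=10_000)
        np.testing.assert_allclose(
            norm.toarray().ravel(), [np.log1p(2000.0), np.log1p(8000.0)]
        )
        assert np.log1p(2000.0) == pytest.approx(7.601402, abs=1e-6)
        assert np.log1p(8000.0) == pytest.approx(8.987322, abs=1e-6)
        assert kept.all()

    def test_zero_gene_stays_zero(self, tiny_counts):
        norm, _ = normalize_cells(tiny_counts)
        np.testing.assert_array_equal(norm.toarray()[2], 0.0)

    def test_per_cell_independence(self, tiny_counts):
        norm, _ = normalize_cells(tiny_counts)
        doubled = LabeledCounts(
            tiny_counts.gene_ids,
            sparse.hstack([tiny_counts.counts, tiny_counts.counts]).tocsr(),
            tiny_counts.cell_labels * 2,
        )
        norm2, _ = normalize_cells(doubled)
        np.testing.assert_allclose(norm2.toarray()[:, :4], norm.toarray())
        np.testing.assert_allclose(norm2.toarray()[:, 4:], norm.toarray())

    def test_zero_total_cell_excluded(self):
        lc = LabeledCounts(["g0"], np.array([[3, 0, 5]]), ["A", "A", "B"])
        norm, kept = normalize_cells(lc)
        assert kept.tolist() == [True, False, True]
        assert norm.shape == (1, 2)

    def test_all_zero_matrix(self):
        lc = LabeledCounts(["g0"], np.zeros((1, 3), dtype=int), ["A", "A", "B"])
        with pytest.raises(ValidationError, match="all zeros"):
            normalize_cells(lc)


class TestAverageByCelltype:
    def test_single_cell_per_type(self):
        norm = np.array([[1.0, 4.0], [2.0, 5.0]])
        prof = average_by_celltype(norm, ["g0", "g1"], ["A", "B"], ["g0", "g1"])
        np.testing.assert_allclose(prof.values.to_numpy(), norm)
        assert prof.stage == "averaged"

    def test_duplicate_cells_same_mean(self):
        norm = np.array([[1.0, 1.0, 4.0]])
        prof = average_by_celltype(norm, ["g0"], ["A", "A", "B"], ["g0"])
        np.testing.assert_allclose(prof.values.to_numpy(), [[1.0, 4.0]])

    def test_brute_force_oracle(self, rng):
        norm = rng.uniform(size=(3, 4))
        labels = ["A", "B", "A", "B"]
        genes = ["g0", "g1", "g2"]
        prof = average_by_celltype(norm, genes, labels, genes)
        for gi, g in enumerate(genes):
            for ct in ("A", "B"):
                expected = np.mean([norm[gi, ci] for ci in range(4) if labels[ci] == ct])
                assert prof.values.loc[g, ct] == pytest.approx(expected, abs=1e-15)

    def test_unmapped_counted(self):
        norm = np.ones((2, 2))
        prof = average_by_celltype(norm, ["g0", "g1"], ["A", "B"], ["g0", "missing1", "missing2"])
        assert prof.n_unmapped == 2
        assert prof.target_genes == ["g0"]

    def test_empty_intersection(self):
        with pytest.raises(ValidationError, match="id-mapping|mapping"):
            average_by_celltype(np.ones((1, 2)), ["g0"], ["A", "B"], ["nope"])


class TestScaleRows:
    def test_constant_row_flagged(self):
        prof = profile_from([[5.0, 5.0, 5.0]], stage="averaged")
        scaled = scale_rows(prof)
        np.testing.assert_array_equal(scaled.values.to_numpy(), [[0.0, 0.0, 0.0]])
        assert scaled.zero_variance_genes == ["g0"]

    def test_hand_zscore(self):
        prof = profile_from([[1.0, 2.0, 3.0]], stage="averaged")
        np.testing.assert_allclose(scale_rows(prof).values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_row_moments(self, rng):
        prof = profile_from(rng.uniform(size=(20, 6)), stage="averaged")
        scaled = scale_rows(prof).values.to_numpy()
        np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_needs_two_types(self):
        prof = profile_from([[1.0]], stage="averaged")
        with pytest.raises(ValidationError, match=">= 2 cell types"):
            scale_rows(prof)

    def test_wrong_stage(self):
        with pytest.raises(ValidationError, match="averaged"):
            scale_rows(profile_from([[1.0, 2.0]], stage="scaled"))


class TestAssignTargets:
    def test_unique_max(self):
        prof = profile_from([[-1.0, 2.0, -1.0]])
        prof.values.columns = ["DCT", "PT", "LOH"]
        res = assign_targets(prof)
        assert res.assignments["g0"] == "PT"
        assert res.counts["PT"] == 1

    def test_tie_is_ambiguous(self):
        res = assign_targets(profile_from([[1.0, 1.0, 0.0]]))
        assert res.assignments["g0"] == AMBIGUOUS
        assert res.n_assigned == 0 and res.n_ambiguous == 1

    def test_zero_variance_row_ambiguous(self):
        scaled = scale_rows(profile_from([[2.0, 2.0, 2.0]], stage="averaged"))
        res = assign_targets(scaled)
        assert res.assignments["g0"] == AMBIGUOUS

    def test_brute_force_oracle(self, rng):
        for _ in range(200):
            values = rng.normal(size=(5, 8))
            prof = profile_from(values)
            res = assign_targets(prof)
            for gi, gene in enumerate(prof.target_genes):
                row = values[gi]
                best = max(range(8), key=lambda j: row[j])
                strict = all(row[best] - row[j] > 1e-12 for j in range(8) if j != best)
                expected = prof.cell_types[best] if strict else AMBIGUOUS
                assert res.assignments[gene] == expected

    def test_conservation(self, rng):
        norm = rng.uniform(size=(6, 8))
        labels = ["A", "A", "B", "B", "C", "C", "D", "D"]
        genes = [f"g{i}" for i in range(6)]
        targets = genes[:4] + ["missingX", "missingY"]
        prof = scale_rows(average_by_celltype(norm, genes, labels, targets))
        res = assign_targets(prof)
        assert res.n_assigned + res.n_ambiguous + res.n_unmapped == len(targets)


class TestRankCelltypes:
    def test_descending_with_lexicographic_ties(self):
        res = assign_targets(profile_from([[-1.0, 2.0], [3.0, -1.0], [4.0, -2.0]]))
        res.counts = {"PT": 40, "Macrophage": 5, "Endothelial": 5}
        ranking = rank_celltypes(res)
        assert ranking == [("PT", 40), ("Endothelial", 5), ("Macrophage", 5)]

    def test_empty_assignments(self):
        res = assign_targets(profile_from([[1.0, 1.0]]))
        assert rank_celltypes(res) == [("T0", 0), ("T1", 0)]


class TestEndToEndRecovery:
    def _run(self, seed, fold=4.0, shuffle=False):
        types = tuple(f"T{i}" for i in range(8))
        planted = {i: ("T0", fold) for i in range(50)}
        cfg = ScSimConfig(
            cell_types=types, cells_per_type=200, n_genes=1000, baseline_mean=1.0,
            dispersion=2.0, planted_map=planted, seed=seed,
        )
        counts, truth = simulate_scrna(cfg)
        labels = list(counts.cell_labels)
        if shuffle:
            rng = np.random.default_rng(seed + 1000)
            labels = list(np.asarray(labels)[rng.permutation(len(labels))])
        norm, _ = normalize_cells(counts)
        prof = scale_rows(
            average_by_celltype(norm, counts.gene_ids, labels, sorted(truth.target_home_celltype))
        )
        res = assign_targets(prof)
        acc = np.mean([res.assignments[g] == "T0" for g in truth.target_home_celltype])
        return acc, res

    def test_planted_recovery(self):
        acc, res = self._run(seed=0)
        assert acc >= 0.95
        assert rank_celltypes(res)[0][0] == "T0"

    def test_label_permutation_destroys_recovery(self):
        accs = [self._run(seed=s, shuffle=True)[0] for s in range(3)]
        acc = float(np.mean(accs))
        chance = 1.0 / 8
        assert abs(acc - chance) <= 3 * np.sqrt(chance * (1 - chance) / (3 * 50))

    def test_cell_and_gene_order_invariance(self, rng):
        cfg = ScSimConfig(
            cell_types=("A", "B", "C"), cells_per_type=30, n_genes=40,
            planted_map={i: ("A", 3.0) for i in range(5)}, seed=7,
        )
        counts, truth = simulate_scrna(cfg)
        norm, _ = normalize_cells(counts)
        dense = norm.toarray()
        targets = sorted(truth.target_home_celltype)

        def assign(mat, genes, labels):
            return assign_targets(
                scale_rows(average_by_celltype(mat, genes, labels, targets))
            ).assignments

        base = assign(dense, counts.gene_ids, counts.cell_labels)
        cell_perm = rng.permutation(dense.shape[1])
        labels_perm = [counts.cell_labels[i] for i in cell_perm]
        assert assign(dense[:, cell_perm], counts.gene_ids, labels_perm) == base
        gene_perm = rng.permutation(dense.shape[0])
        genes_perm = [counts.gene_ids[i] for i in gene_perm]
        assert assign(dense[gene_perm, :], genes_perm, counts.cell_labels) == base
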