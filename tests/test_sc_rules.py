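"""QC filtering, the high-confidence DEG rule, and relative proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from uroscore import (
    SingleCellBundle,
    generate_single_cell_bundle,
    high_confidence_degs,
    qc_filter,
    read_bundle,
    relative_proportion,
    write_bundle,
)
from uroscore.sc_rules import flag_genes

QC = dict(min_genes=30, max_genes=135, max_mito_frac=0.25)
GEN = dict(n_clusters=2, cells_per_cluster=40, n_genes=150, seed=9,
           qc_thresholds=(30, 135, 0.25))


def _tiny_bundle(counts, clusters, samples=None, mito=()):
    counts = np.asarray(counts)
    genes = pd.Index([f"MT-{i}" if i in mito else f"g{i}" for i in range(counts.shape[0])])
    cells = pd.Index([f"c{i}" for i in range(counts.shape[1])])
    samples = samples or ["smp0"] * len(cells)
    return SingleCellBundle(
        counts=sparse.csr_matrix(counts),
        genes=genes,
        cells=cells,
        cell_cluster=pd.Series(clusters, index=cells),
        cell_sample=pd.Series(samples, index=cells),
        gene_flags=flag_genes(genes),
    )


class TestQC:
    def test_planted_violations_removed_with_attribution(self):
        bundle, _, planted = generate_single_cell_bundle(
            **GEN, planted_low_gene_cells=4, planted_high_gene_cells=3,
            planted_high_mito_cells=5,
        )
        filtered, report = qc_filter(bundle, **QC)
        removed = set(bundle.cells) - set(filtered.cells)
        assert removed == set(
            planted["low_genes"] + planted["high_genes"] + planted["high_mito"]
        )
        assert report.cells_removed_low_genes == 4
        assert report.cells_removed_high_genes == 3
        assert report.cells_removed_high_mito == 5

    def test_clean_bundle_keeps_all_cells(self):
        bundle, _, _ = generate_single_cell_bundle(**GEN)
        filtered, report = qc_filter(bundle, **QC)
        assert filtered.n_cells == bundle.n_cells
        assert report.cells_removed_low_genes == 0

    def test_boundary_semantics_strict(self):
        # cell0: exactly min_genes expressed -> removed; cell1: min_genes+1 -> kept
        # cell2: exactly max_genes -> kept; cell3: mito fraction exactly at cap -> kept
        n_genes = 6
        counts = np.zeros((n_genes, 4), dtype=int)
        counts[:3, 0] = 1          # 3 expressed genes
        counts[:4, 1] = 1          # 4 expressed genes
        counts[:6, 2] = 1          # 6 expressed genes
        counts[0, 3] = 1           # mito gene
        counts[1:4, 3] = 1         # fraction = 1/4
        bundle = _tiny_bundle(counts, ["A"] * 4, mito=(0,))
        filtered, _ = qc_filter(bundle, min_genes=3, max_genes=6,
                                max_mito_frac=0.25, min_cells_per_gene=0)
        assert list(filtered.cells) == ["c1", "c2", "c3"]

    def test_gene_filter_strictly_more_than_three_cells(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :3] = 1  # expressed in exactly 3 cells -> removed
        counts[1, :4] = 1  # expressed in 4 cells -> kept
        bundle = _tiny_bundle(counts, ["A"] * 8, mito=(1,))
        filtered, report = qc_filter(bundle, min_genes=0, max_genes=10,
                                     max_mito_frac=1.0)
        assert list(filtered.genes) == ["MT-1"]
        assert report.genes_removed == 1

    def test_idempotent(self):
        bundle, _, _ = generate_single_cell_bundle(
            **GEN, planted_high_mito_cells=3
        )
        once, _ = qc_filter(bundle, **QC)
        twice, report = qc_filter(once, **QC)
        assert list(twice.cells) == list(once.cells)
        assert list(twice.genes) == list(once.genes)
        assert report.genes_removed == 0

    def test_empty_matrix(self):
        bundle = _tiny_bundle(np.zeros((0, 0), dtype=int), [])
        filtered, report = qc_filter(bundle, **QC)
        assert filtered.n_cells == 0 and filtered.n_genes == 0
        assert report.cells_removed_high_mito == 0

    def test_requires_mito_annotation(self):
        counts = np.ones((3, 4), dtype=int)
        bundle = _tiny_bundle(counts, ["A"] * 4)  # no MT- genes
        with pytest.raises(ValueError, match="mitochondrial"):
            qc_filter(bundle, **QC)


class TestHighConfidenceDEGs:
    def _means(self, focal_fcs, other_level=1.0):
        # one gene; three focal samples offset by focal_fcs (log2), three others
        cols = ["f1", "f2", "f3", "o1", "o2", "o3"]
        vals = [[other_level + fc for fc in focal_fcs] + [other_level] * 3]
        means = pd.DataFrame(vals, index=["gene1"], columns=cols)
        subtype = pd.Series(["basal"] * 3 + ["luminal"] * 3, index=cols)
        return means, subtype

    def test_identical_means_fail_both_directions(self):
        means, subtype = self._means([0.0, 0.0, 0.0])
        recs = high_confidence_degs(means, subtype)
        assert all(not r.passed for r in recs)

    @pytest.mark.parametrize(
        "fcs,expected", [((1.1, 0.9, 0.7), False), ((1.1, 0.9, 0.85), True)]
    )
    def test_all_samples_must_clear_threshold(self, fcs, expected):
        means, subtype = self._means(list(fcs))
        recs = high_confidence_degs(means, subtype)
        basal = next(r for r in recs if r.direction == "basal")
        assert basal.passed is expected

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        cols = [f"x{i}" for i in range(6)]
        means = pd.DataFrame(rng.normal(3, 2, size=(20, 6)),
                             index=[f"g{i}" for i in range(20)], columns=cols)
        subtype = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)
        recs = high_confidence_degs(means, subtype)
        passed = {(r.gene, r.direction) for r in recs if r.passed}
        for gene, direction in passed:
            other = "B" if direction == "A" else "A"
            assert (gene, other) not in passed

    def test_requires_two_subtypes(self):
        means = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="2 subtypes"):
            high_confidence_degs(means, pd.Series({"a": "A", "b": "A"}))


class TestRelativeProportion:
    def _bundle(self, cluster_sizes: dict, sample="smp0"):
        clusters = [cl for cl, n in cluster_sizes.items() for _ in range(n)]
        n = len(clusters)
        counts = np.ones((2, n), dtype=int)
        return _tiny_bundle(counts, clusters, samples=[sample] * n, mito=(0,))

    def test_fraction_arithmetic(self):
        bundle = self._bundle({"target": 40, "other": 160})
        out = relative_proportion(bundle, "target", ["target", "other"])
        assert out.loc["smp0", "fraction"] == pytest.approx(0.20)
        assert not out.loc["smp0", "excluded"]

    def test_small_sample_excluded_flag(self):
        bundle = self._bundle({"target": 9, "other": 90})  # 99 compartment cells
        out = relative_proportion(bundle, "target", ["target", "other"])
        assert bool(out.loc["smp0", "excluded"])

    def test_compartment_equals_target(self):
        bundle = self._bundle({"target": 120})
        out = relative_proportion(bundle, "target", ["target"])
        assert out.loc["smp0", "fraction"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_over_compartment(self, sc_bundle):
        bundle, _ = sc_bundle
        comp = sorted(bundle.cell_cluster.unique())
        total = sum(
            relative_proportion(bundle, cl, comp)["fraction"] for cl in comp
        )
        np.testing.assert_allclose(total.to_numpy(), 1.0)

    def test_target_must_be_in_compartment(self, sc_bundle):
        bundle, _ = sc_bundle
        with pytest.raises(ValueError, match="not in the compartment"):
            relative_proportion(bundle, "C0", ["C1", "C2"])


def test_bundle_mtx_roundtrip(tmp_path, sc_bundle):
    bundle, _ = sc_bundle
    write_bundle(bundle, tmp_path / "b")
    back = read_bundle(tmp_path / "b")
    assert (back.counts != bundle.counts).nnz == 0
    assert list(back.genes) == list(bundle.genes)
    pd.testing.assert_series_equal(back.cell_cluster, bundle.cell_cluster,
                                   check_names=False)
    pd.testing.assert_frame_equal(back.gene_flags, bundle.gene_flags,
                                  check_names=False)
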