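"""Ligand-receptor gating, permutation significance, exhaustion screen."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from uroscore import (
    LRPair,
    generate_single_cell_bundle,
    interaction_exhaustion_screen,
    interaction_strength,
    permutation_test,
)
from uroscore.lr_screen import log_normalized_expression
from uroscore.sc_rules import SingleCellBundle, flag_genes


def _manual_bundle(counts, clusters):
    counts = np.asarray(counts)
    genes = pd.Index(["MT-0", "LIGX", "RECX"] + [f"g{i}" for i in range(counts.shape[0] - 3)])
    cells = pd.Index([f"c{i}" for i in range(counts.shape[1])])
    return SingleCellBundle(
        counts=sparse.csr_matrix(counts),
        genes=genes,
        cells=cells,
        cell_cluster=pd.Series(clusters, index=cells),
        cell_sample=pd.Series(["smp0"] * len(cells), index=cells),
        gene_flags=flag_genes(genes, ligands=["LIGX"], receptors=["RECX"]),
    )


PAIR = LRPair("LIGX", "RECX")


class TestStrength:
    def test_low_expression_fraction_gated(self):
        bundle, panel, _ = generate_single_cell_bundle(
            n_clusters=2, cells_per_cluster=40, n_genes=100, seed=2,
            lr_expr_frac={("LIG00", "C0"): 0.05},
        )
        res = interaction_strength(bundle, panel[0], "C0", "C1")
        assert res.gated and res.strength is None and res.p_value is None

    def test_arithmetic_mean_of_cluster_means(self):
        counts = np.zeros((4, 6), dtype=int)
        counts[1, :3] = 4   # ligand in sender cells
        counts[2, 3:] = 9   # receptor in receiver cells
        counts[3, :] = 10   # background keeps libraries comparable
        bundle = _manual_bundle(counts, ["S"] * 3 + ["R"] * 3)
        res = interaction_strength(bundle, PAIR, "S", "R")
        log_expr = log_normalized_expression(bundle)
        expected = 0.5 * (log_expr[1, :3].mean() + log_expr[2, 3:].mean())
        assert res.strength == pytest.approx(expected)

    def test_swap_symmetry(self, sc_bundle):
        bundle, panel = sc_bundle
        fwd = interaction_strength(bundle, panel[0], "C0", "C1")
        rev = interaction_strength(
            bundle, LRPair(panel[0].receptor, panel[0].ligand), "C1", "C0"
        )
        assert fwd.strength == pytest.approx(rev.strength)

    def test_unknown_gene_or_cluster(self, sc_bundle):
        bundle, panel = sc_bundle
        with pytest.raises(ValueError, match="not in the matrix"):
            interaction_strength(bundle, LRPair("LIG00", "MISSING"), "C0", "C1")
        with pytest.raises(ValueError, match="unknown cluster"):
            interaction_strength(bundle, panel[0], "C0", "NOPE")


class TestPermutation:
    def test_seed_reproducibility(self, sc_bundle):
        bundle, panel = sc_bundle
        a = permutation_test(bundle, panel[0], "C0", "C1", n_perm=50, seed=13)
        b = permutation_test(bundle, panel[0], "C0", "C1", n_perm=50, seed=13)
        assert a.p_value == b.p_value

    def test_p_is_add_one_multiple(self, sc_bundle):
        bundle, panel = sc_bundle
        res = permutation_test(bundle, panel[0], "C0", "C1", n_perm=99, seed=1)
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))
        assert 0 < res.p_value <= 1

    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 6, size=(5, 6))
        counts[1] = [3, 0, 2, 1, 4, 0]  # ligand
        counts[2] = [1, 2, 0, 3, 0, 2]  # receptor
        bundle = _manual_bundle(counts, ["S", "S", "S", "R", "R", "R"])
        res = permutation_test(bundle, PAIR, "S", "R", exhaustive=True)

        # independent enumeration over all C(6,3) = 20 assignments
        log_expr = log_normalized_expression(bundle)
        lig, rec = log_expr[1], log_expr[2]
        stats = []
        for sender_cells in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(sender_cells)] = True
            stats.append(0.5 * (lig[mask].mean() + rec[~mask].mean()))
        observed = 0.5 * (lig[:3].mean() + rec[3:].mean())
        expected_p = np.mean([s >= observed - 1e-12 for s in stats])
        assert res.p_value == pytest.approx(expected_p)
        assert len(stats) == 20

    def test_gated_pair_refused(self):
        bundle, panel, _ = generate_single_cell_bundle(
            n_clusters=2, cells_per_cluster=40, n_genes=100, seed=2,
            lr_expr_frac={("LIG00", "C0"): 0.05},
        )
        with pytest.raises(ValueError, match="gated"):
            permutation_test(bundle, panel[0], "C0", "C1")

    def test_invalid_n_perm(self, sc_bundle):
        bundle, panel = sc_bundle
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(bundle, panel[0], "C0", "C1", n_perm=0)

    def test_null_mean_p_near_half(self):
        # clusters differ only in label: p should be uniform-ish
        ps = []
        for seed in range(40):
            bundle, panel, _ = generate_single_cell_bundle(
                n_clusters=2, cells_per_cluster=20, n_genes=60, seed=100 + seed,
                marker_genes_per_cluster=0,
            )
            res = permutation_test(bundle, panel[0], "C0", "C1", n_perm=99,
                                   seed=seed)
            ps.append(res.p_value)
        assert 0.4 <= np.mean(ps) <= 0.6


class TestExhaustionScreen:
    def test_proportional_strength_perfect_correlation(self):
        samples = [f"p{i}" for i in range(6)]
        frac = pd.Series(np.linspace(0.1, 0.6, 6), index=samples)
        strengths = pd.DataFrame([2 * frac.to_numpy()], index=["pairA"],
                                 columns=samples)
        out = interaction_exhaustion_screen(strengths, frac)
        assert out.loc["pairA", "r"] == pytest.approx(1.0)
        assert out.loc["pairA", "sign_class"] == "positive"

    def test_constant_strength_skipped(self):
        samples = [f"p{i}" for i in range(5)]
        frac = pd.Series(np.linspace(0, 1, 5), index=samples)
        strengths = pd.DataFrame([[1.0] * 5], index=["flat"], columns=samples)
        out = interaction_exhaustion_screen(strengths, frac)
        assert out.loc["flat", "sign_class"] == "skipped"

    def test_planted_positive_pairs_recovered(self):
        # 5 planted positive pairs (r_true = 0.9) + 20 null pairs, n = 30
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 30
            frac = pd.Series(rng.uniform(0, 1, n),
                             index=[f"p{i}" for i in range(n)])
            noise_sd = np.sqrt(frac.var() * (1 / 0.9**2 - 1))
            planted = [
                frac.to_numpy() + rng.normal(0, noise_sd, n) for _ in range(5)
            ]
            nulls = [rng.normal(0, 1, n) for _ in range(20)]
            strengths = pd.DataFrame(
                planted + nulls,
                index=[f"pos{i}" for i in range(5)] + [f"null{i}" for i in range(20)],
                columns=frac.index,
            )
            out = interaction_exhaustion_screen(strengths, frac)
            hits.append(
                (out.loc[[f"pos{i}" for i in range(5)], "sign_class"] == "positive").sum()
            )
        assert np.mean([h >= 4 for h in hits]) >= 0.9

    def test_needs_three_samples(self):
        frac = pd.Series({"a": 0.1, "b": 0.2})
        strengths = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            interaction_exhaustion_screen(strengths, frac)
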