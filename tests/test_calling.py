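from math import comb

import numpy as np
import pandas as pd
import pytest

import poolscan as ps
from poolscan.io import BiallelicTable
from poolscan.stats import PairwiseStats


def synthetic_stats(design, fst_matrix, p_matrix, m=None):
    """Wrap explicit per-pair F_ST / raw-P matrices in a PairwiseStats."""
    fst = np.asarray(fst_matrix, dtype=float)
    p = np.asarray(p_matrix, dtype=float)
    n = fst.shape[0]
    sites = BiallelicTable(
        ["2L"] * n,
        np.arange(1, n + 1),
        ["A"] * n,
        ["T"] * n,
        np.full((n, design.n_lines), 50),
        np.full((n, design.n_lines), 50),
    )
    return PairwiseStats(
        design=design,
        sites=sites,
        pairs=design.all_pairs(),
        fst=fst,
        fisher_p=p,
        bonferroni_m=m if m is not None else 1,
    )


def stats_with_candidates(design, candidate_rows, n_sites=10):
    """All pairs fail except: candidate rows pass every pair."""
    fst = np.full((n_sites, 15), 0.1)
    p = np.full((n_sites, 15), 0.5)
    for r in candidate_rows:
        fst[r] = 1.0
        p[r] = 1e-30
    return synthetic_stats(design, fst, p)


class TestEnumerateSets:
    def test_full_design_count(self, design):
        sets = ps.enumerate_comparison_sets(design)
        assert len(sets) == 6435
        assert sum(s.is_true_set for s in sets) == 1
        assert len({frozenset(s.pairs) for s in sets}) == 6435

    def test_choose_all_single_set(self):
        d = ps.PoolDesign(
            ("c1", "c2", "s1", "s2"),
            ("control", "control", "selection", "selection"),
            (10,) * 4,
        )
        sets = ps.enumerate_comparison_sets(d, k=6)
        assert len(sets) == 1

    def test_binomial_count(self):
        d = ps.PoolDesign(
            ("c1", "c2", "s1", "s2"),
            ("control", "control", "selection", "selection"),
            (10,) * 4,
        )
        assert len(ps.enumerate_comparison_sets(d, k=3)) == comb(6, 3)

    def test_k_too_large_rejected(self, design):
        with pytest.raises(ValueError):
            ps.enumerate_comparison_sets(design, k=16)


class TestCallCandidates:
    def test_all_pairs_passing_is_candidate(self, design):
        stats = stats_with_candidates(design, [2])
        calls = ps.call_candidates(stats)
        assert calls["is_candidate"].sum() == 1
        assert calls.loc[2, "is_candidate"]

    def test_seven_of_eight_not_candidate(self, design):
        stats = stats_with_candidates(design, [0])
        # break one between-regime pair at SNP 0
        k = stats.pair_index(design.between_pairs()[3])
        stats.fst[0, k] = 0.85
        assert ps.call_candidates(stats)["is_candidate"].sum() == 0

    def test_threshold_boundary_strict(self, design):
        stats = stats_with_candidates(design, [0])
        stats.fst[0, :] = 0.9  # exactly at threshold
        assert ps.call_candidates(stats)["is_candidate"].sum() == 0

    def test_alpha_boundary_strict(self, design):
        stats = stats_with_candidates(design, [0])
        stats.fisher_p[0, :] = 1e-9  # p_adj == alpha exactly (m = 1)
        assert ps.call_candidates(stats)["is_candidate"].sum() == 0

    def test_undefined_pair_disqualifies(self, design):
        stats = stats_with_candidates(design, [0])
        stats.fst[0, stats.pair_index(design.between_pairs()[0])] = np.nan
        assert ps.call_candidates(stats)["is_candidate"].sum() == 0

    def test_candidate_set_monotone_in_thresholds(self, design):
        rng = np.random.default_rng(0)
        fst = rng.random((40, 15))
        p = 10.0 ** rng.uniform(-40, 0, size=(40, 15))
        stats = synthetic_stats(design, fst, p)
        base = ps.call_candidates(
            stats, fst_threshold=0.5, alpha=1e-3
        )["is_candidate"]
        stricter_fst = ps.call_candidates(
            stats, fst_threshold=0.7, alpha=1e-3
        )["is_candidate"]
        stricter_alpha = ps.call_candidates(
            stats, fst_threshold=0.5, alpha=1e-6
        )["is_candidate"]
        assert not (stricter_fst & ~base).any()
        assert not (stricter_alpha & ~base).any()

    def test_regime_relabel_invariance(self, design):
        """Swapping line labels within a regime leaves calls unchanged."""
        rng = np.random.default_rng(1)
        fst = rng.random((30, 15))
        p = 10.0 ** rng.uniform(-40, 0, size=(30, 15))
        stats = synthetic_stats(design, fst, p)
        calls = ps.call_candidates(stats, fst_threshold=0.6, alpha=1e-2)

        # permute S1<->S2 (indices 2, 3): remap the pair columns
        perm = {0: 0, 1: 1, 2: 3, 3: 2, 4: 4, 5: 5}
        remap = {}
        for k, (i, j) in enumerate(design.all_pairs()):
            remap[tuple(sorted((perm[i], perm[j])))] = k
        order = [remap[pair] for pair in design.all_pairs()]
        stats2 = synthetic_stats(design, fst[:, order], p[:, order])
        calls2 = ps.call_candidates(stats2, fst_threshold=0.6, alpha=1e-2)
        assert (
            calls["is_candidate"].to_numpy()
            == calls2["is_candidate"].to_numpy()
        ).all()


class TestCombinatorialNull:
    def test_true_set_strict_max_floor(self, design):
        stats = stats_with_candidates(design, [], n_sites=10)
        # SNP 0 passes exactly the 8 between pairs, fails within pairs
        for pair in design.between_pairs():
            k = stats.pair_index(pair)
            stats.fst[0, k] = 1.0
            stats.fisher_p[0, k] = 1e-30
        nul = ps.combinatorial_null(stats)
        assert nul.true_count == 1
        assert nul.true_is_strict_max
        assert nul.empirical_p == pytest.approx(1 / 6435, rel=1e-12)
        assert round(nul.empirical_p, 5) == pytest.approx(1.6e-4, abs=5e-6)

    def test_all_tied_p_one(self, design):
        stats = stats_with_candidates(design, [], n_sites=5)
        nul = ps.combinatorial_null(stats)
        assert nul.true_count == 0
        assert nul.empirical_p == 1.0

    def test_counts_match_call_candidates(self, small_scan):
        nul = small_scan.combinatorial_null()
        assert nul.true_count == small_scan.n_candidates
        assert 1 / 6435 <= nul.empirical_p <= 1.0

    def test_empirical_p_bounds(self, design):
        rng = np.random.default_rng(2)
        fst = rng.random((20, 15))
        p = 10.0 ** rng.uniform(-20, 0, size=(20, 15))
        stats = synthetic_stats(design, fst, p)
        nul = ps.combinatorial_null(stats, fst_threshold=0.5, alpha=0.01)
        assert 1 / 6435 <= nul.empirical_p <= 1.0


class TestAssignGenes:
    GENES = [
        ps.GeneModel("gA", "2L", 9000, 13000),
        ps.GeneModel("gB", "2L", 12500, 14000),
        ps.GeneModel("gC", "2R", 100, 200),
    ]

    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "is_candidate"]
        )

    def test_inclusive_boundaries(self):
        calls = self.frame(
            [("2L", 9000, True), ("2L", 8999, True), ("2L", 13000, True)]
        )
        gene_table, snp_table = ps.assign_snps_to_genes(calls, self.GENES)
        # 9000 and 13000 are inside gA (inclusive ends); 13000 also falls
        # in the overlapping gB; 8999 is just outside
        counts = dict(zip(gene_table.gene_id, gene_table.n_snps))
        assert counts == {"gA": 2, "gB": 1}
        assert snp_table.loc[1, "intergenic"]

    def test_overlapping_genes_multi_assignment(self):
        calls = self.frame([("2L", 12800, True)])
        gene_table, snp_table = ps.assign_snps_to_genes(calls, self.GENES)
        assert set(gene_table.gene_id) == {"gA", "gB"}
        assert snp_table.loc[0, "genes"] == "gA,gB"

    def test_only_candidates_assigned(self):
        calls = self.frame([("2R", 150, False), ("2R", 160, True)])
        gene_table, snp_table = ps.assign_snps_to_genes(calls, self.GENES)
        assert len(snp_table) == 1
        assert gene_table.n_snps.tolist() == [1]

    def test_gene_counted_once_per_snp_set(self):
        calls = self.frame(
            [("2L", 9500, True), ("2L", 9600, True), ("2L", 9700, True)]
        )
        gene_table, _ = ps.assign_snps_to_genes(calls, self.GENES)
        assert len(gene_table) == 1
        assert gene_table.n_snps.iloc[0] == 3
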