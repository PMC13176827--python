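"""Marker-discovery stages against closed forms and brute-force oracles."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbstrat import markers as mk
from tbstrat.config import SimConfig
from tbstrat import synthetic as syn


def _toy_adata(counts, mito=None, compartment=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    if compartment is not None:
        obs["compartment"] = compartment
    var = pd.DataFrame(
        {"mito": mito if mito is not None else [False] * n_genes},
        index=[f"g{j}" for j in range(n_genes)],
    )
    return ad.AnnData(X=counts.astype(np.int32), obs=obs, var=var)


class TestQcFilter:
    def test_low_gene_cell_excluded(self):
        # cell 0 detects 400 genes, cell 1 detects 600
        X = np.zeros((2, 1000), dtype=int)
        X[0, :400] = 1
        X[1, :600] = 1
        kept = mk.qc_filter(_toy_adata(X), min_genes=500, max_mito_pct=100)
        assert list(kept.obs_names) == ["c1"]

    def test_high_mito_cell_excluded(self):
        X = np.array([[30, 70], [5, 95]])
        kept = mk.qc_filter(_toy_adata(X, mito=[True, False]), 0, max_mito_pct=25)
        assert list(kept.obs_names) == ["c1"]

    def test_permissive_thresholds_identity(self, sc_dataset):
        adata, _ = sc_dataset
        kept = mk.qc_filter(adata, min_genes=0, max_mito_pct=100)
        assert kept.n_obs == adata.n_obs

    def test_idempotent(self, sc_dataset):
        adata, _ = sc_dataset
        once = mk.qc_filter(adata, 500, 25)
        twice = mk.qc_filter(once, 500, 25)
        assert list(once.obs_names) == list(twice.obs_names)

    def test_all_removed_raises_with_thresholds(self):
        X = np.ones((3, 10), dtype=int)
        with pytest.raises(ValueError, match="min_genes=500"):
            mk.qc_filter(_toy_adata(X), min_genes=500, max_mito_pct=25)


class TestLogNormalize:
    def test_closed_form_entry(self):
        X = np.zeros((1, 2), dtype=int)
        X[0] = [10, 9990]  # total 10,000
        norm = mk.log_normalize(_toy_adata(X), scale_factor=1e4)
        assert norm.X[0, 0] == pytest.approx(np.log(11), abs=1e-12)

    def test_zeros_map_to_zero_and_conservation(self, normalized_sc):
        norm, _ = normalized_sc
        X = np.asarray(norm.X)
        assert X.min() == 0.0
        np.testing.assert_allclose(np.expm1(X).sum(axis=1), 1e4, rtol=1e-9)

    def test_invariant_to_cell_and_gene_order(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 50, size=(6, 8))
        a = mk.log_normalize(_toy_adata(X))
        b = mk.log_normalize(_toy_adata(X[::-1, ::-1]))
        np.testing.assert_allclose(np.asarray(a.X)[::-1, ::-1], np.asarray(b.X))

    def test_zero_total_cell_raises(self):
        X = np.array([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="qc_filter"):
            mk.log_normalize(_toy_adata(X))


class TestComputePca:
    def test_matches_eigendecomposition_oracle(self):
        """Loadings and eigenvalues agree with a dense eigendecomposition of
        the scaled-data covariance, up to sign, at 1e-8."""
        rng = np.random.default_rng(42)
        X = rng.poisson(5.0, size=(50, 20)).astype(np.int32)
        X += 1  # no zero-total cells
        norm = mk.log_normalize(_toy_adata(X))
        res = mk.compute_pca(norm, n_hvg=20, n_pcs=5)
        # oracle: scale exactly as the implementation contract states
        M = np.asarray(norm.X)
        Z = np.minimum((M - M.mean(0)) / M.std(0, ddof=1), 10.0)
        C = np.cov(Z, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(C)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(res.explained_variance, w[:5], atol=1e-8)
        L = res.loadings.to_numpy()
        for k in range(5):
            sign = np.sign(L[:, k] @ v[:, k])
            np.testing.assert_allclose(L[:, k], sign * v[:, k], atol=1e-8)

    def test_score_variance_equals_eigenvalue(self, normalized_sc):
        norm, _ = normalized_sc
        res = mk.compute_pca(norm, n_hvg=200, n_pcs=10)
        np.testing.assert_allclose(
            res.scores.var(ddof=1).to_numpy(), res.explained_variance, rtol=1e-8
        )

    def test_single_informative_gene_dominates_pc1(self):
        rng = np.random.default_rng(1)
        X = rng.integers(5, 10, size=(40, 10))
        X[:20, 0] += 50  # one gene separates two populations
        res = mk.compute_pca(mk.log_normalize(_toy_adata(X)), n_hvg=10, n_pcs=3)
        assert res.loadings["PC1"].abs().idxmax() == "g0"

    def test_constant_matrix_raises(self):
        X = np.full((10, 5), 7)
        with pytest.raises(ValueError, match="constant"):
            mk.compute_pca(mk.log_normalize(_toy_adata(X)), n_hvg=5, n_pcs=2)


class TestRankByPc1:
    def test_sign_flip_invariance(self, normalized_sc):
        norm, _ = normalized_sc
        res = mk.compute_pca(norm, n_hvg=200, n_pcs=5)
        order = mk.rank_by_pc1(res, norm.obs)
        flipped = mk.PCAResult(
            loadings=-res.loadings, scores=-res.scores,
            explained_variance=res.explained_variance, hvg=res.hvg,
        )
        order_f = mk.rank_by_pc1(flipped, norm.obs)
        assert list(order.index) == list(order_f.index)

    def test_planted_markers_at_ranking_extremes(self, normalized_sc):
        norm, truth = normalized_sc
        res = mk.compute_pca(norm, n_hvg=500, n_pcs=20)
        order = mk.rank_by_pc1(res, norm.obs)
        decile = len(order) // 10
        ranked = list(order.index)
        basal_in = [g for g in truth.planted_markers["basal"] if g in order.index]
        assert all(ranked.index(g) < decile for g in basal_in)
        lum_in = [g for g in truth.planted_markers["luminal_ER_pos"] if g in order.index]
        assert all(ranked.index(g) >= len(order) - 3 * decile for g in lum_in)


class TestRankSumDe:
    def test_exact_p_matches_enumeration_oracle(self):
        """Exact p for {1,2,3,4} vs {5,6,7,8} equals brute-force enumeration
        of all 70 labelings (and scipy's exact method, tie-free here)."""
        x = np.array([1.0, 2, 3, 4])
        y = np.array([5.0, 6, 7, 8])
        p_impl = mk._exact_ranksum_p(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = abs(ranks[:4].sum() - 18.0)
        count = sum(
            abs(ranks[list(c)].sum() - 18.0) >= obs - 1e-12
            for c in itertools.combinations(range(8), 4)
        )
        assert p_impl == pytest.approx(count / 70)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p_impl == pytest.approx(p_scipy)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (5, 5)])
    def test_exact_p_matches_scipy_random_tie_free(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        x, y = rng.normal(size=na), rng.normal(size=nb) + 0.5
        assert mk._exact_ranksum_p(x, y) == pytest.approx(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )

    def test_identical_groups_give_p_one(self):
        x = np.array([2.0, 2, 2, 2])
        assert mk._exact_ranksum_p(x, x) == 1.0

    def test_table_invariants(self, normalized_sc):
        norm, _ = normalized_sc
        sub = norm[:, :100]
        table = mk.rank_sum_de(sub, sub.obs)
        assert ((table["p_adj"] >= table["p_value"] - 1e-15).all())
        assert table[["p_value", "p_adj"]].min().min() >= 0
        assert table[["p_value", "p_adj"]].max().max() <= 1
        assert table[["frac_basal", "frac_luminal"]].min().min() >= 0
        assert table[["frac_basal", "frac_luminal"]].max().max() <= 1

    def test_empty_group_raises(self, normalized_sc):
        norm, _ = normalized_sc
        with pytest.raises(ValueError):
            mk.rank_sum_de(norm, norm.obs, group_a="nonexistent")


class TestSelectCandidates:
    def _table(self, n=30):
        return pd.DataFrame(
            {
                "p_adj": 0.01,
                "frac_basal": 0.9,
                "frac_luminal": 0.1,
                "rank": np.arange(1, n + 1),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_first_k_by_rank(self):
        table = self._table(30)
        assert mk.select_candidates(table, k=20) == [f"g{i}" for i in range(20)]

    def test_fraction_filter_excludes(self):
        table = self._table(2)
        table.loc["g0", "frac_basal"] = 0.70
        assert mk.select_candidates(table, k=2, min_frac_basal=0.75) == ["g1"]

    def test_empty_result_warns(self):
        table = self._table(3)
        table["p_adj"] = 0.5
        with pytest.warns(UserWarning, match="0 of the requested"):
            assert mk.select_candidates(table, k=3) == []

    def test_nonpositive_k_raises(self):
        with pytest.raises(ValueError):
            mk.select_candidates(self._table(), k=0)


class TestScoreSignature:
    def test_hand_oracle_small_matrix(self):
        """3-gene set in a 10-gene cell matches a direct rank-and-sum check."""
        rng = np.random.default_rng(5)
        X = rng.integers(0, 20, size=(4, 10))
        norm = mk.log_normalize(_toy_adata(X + 1))
        genes = ["g2", "g5", "g7"]
        r_max = 8
        scores = mk.score_signature(norm, genes, r_max=r_max)
        M = np.asarray(norm.X)
        for i in range(4):
            ranks = stats.rankdata(-M[i])
            ranks = np.minimum(ranks, r_max + 1)
            U = ranks[[2, 5, 7]].sum() - 3 * 4 / 2
            expected = np.clip(1 - U / (3 * r_max), 0, 1)
            assert scores.iloc[i] == pytest.approx(expected)

    def test_top_ranked_set_scores_one(self):
        X = np.array([[50, 40, 30, 1, 1, 1]])
        norm = mk.log_normalize(_toy_adata(X))
        score = mk.score_signature(norm, ["g0", "g1", "g2"], r_max=5)
        assert score.iloc[0] == pytest.approx(1.0)

    def test_unexpressed_set_scores_near_zero(self):
        """All set genes at the rank ceiling give the minimal score
        (s+1)/(2*r_max), which vanishes as r_max grows."""
        rng = np.random.default_rng(9)
        X = np.concatenate([np.zeros((1, 3), dtype=int),
                            rng.integers(1, 30, size=(1, 97))], axis=1)
        norm = mk.log_normalize(_toy_adata(X))
        s, r_max = 3, 80
        score = mk.score_signature(norm, ["g0", "g1", "g2"], r_max=r_max)
        # ranks capped at r_max+1 for all three unexpressed genes
        expected = 1 - (s * (r_max + 1) - s * (s + 1) / 2) / (s * r_max)
        assert score.iloc[0] == pytest.approx(max(expected, 0.0))
        assert score.iloc[0] < 0.05

    def test_scores_in_unit_interval(self, normalized_sc):
        norm, truth = normalized_sc
        s = mk.score_signature(norm, truth.planted_markers["basal"], r_max=500)
        assert s.min() >= 0 and s.max() <= 1

    def test_missing_set_raises(self, normalized_sc):
        norm, _ = normalized_sc
        with pytest.raises(ValueError):
            mk.score_signature(norm, ["not_a_gene"])


@pytest.fixture(scope="module")
def species_pair():
    """Mouse data with 25 planted basal markers; human with the shared
    first 20, so 5 candidates are mouse-only."""
    mcfg = SimConfig(seed=11, n_marker_genes=25, species="mouse")
    hcfg = SimConfig(seed=12, n_marker_genes=20, species="human")
    tables = {}
    truths = {}
    for name, cfg in [("mouse", mcfg), ("human", hcfg)]:
        adata, truth = syn.gen_sc_dataset(cfg)
        norm = mk.log_normalize(mk.qc_filter(adata))
        tables[name] = mk.build_marker_table(norm, n_hvg=500)
        truths[name] = truth
    return tables, truths


class TestCrossSpecies:
    def test_top_n_survivors_are_all_shared(self, species_pair):
        tables, truths = species_pair
        candidates = truths["mouse"].planted_markers["basal"]  # 25 genes
        kept = mk.cross_species_consistency(
            tables["mouse"], tables["human"], candidates, top_n=10
        )
        assert len(kept) == 10
        human_symbols = {g.upper() for g in truths["human"].planted_markers["basal"]}
        assert all(g.upper() in human_symbols for g in kept)

    def test_luminal_shifted_marker_dropped(self, species_pair):
        tables, truths = species_pair
        g = truths["mouse"].planted_markers["basal"][0]
        human = tables["human"].copy()
        hg = g.upper()
        human.loc[hg, "mean_luminal_ER_pos"] = human.loc[hg, "mean_basal"] + 1
        kept = mk.cross_species_consistency(tables["mouse"], human, [g], top_n=10)
        assert kept == []

    def test_disjoint_namespaces_raise(self, species_pair):
        tables, _ = species_pair
        renamed = tables["human"].copy()
        renamed.index = ["x" + g for g in renamed.index]
        with pytest.raises(ValueError, match="shared"):
            mk.cross_species_consistency(tables["mouse"], renamed, [], top_n=5)
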