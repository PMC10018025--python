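"""Step 3: CpG aggregation, Laplacian scores, CCA and its inference."""

import numpy as np
import pandas as pd
import pytest

from cortexlink import cca
from cortexlink.errors import ConfigError, DataError
from cortexlink.synthetic import gen_methylation_panss

from _oracles import bh_oracle, cca_corr_oracle, laplacian_score_oracle
from conftest import small_config


class TestAggregation:
    @staticmethod
    def _beta(values, cpgs, subjects):
        return pd.DataFrame(values, index=pd.Index(cpgs, name="cpg_id"),
                            columns=subjects)

    def test_single_cpg_gene_is_identity(self):
        beta = self._beta([[0.1, 0.9]], ["cg1"], ["s1", "s2"])
        manifest = pd.DataFrame({"cpg_id": ["cg1"], "gene": ["GA"]})
        out = cca.aggregate_cpg_to_gene(beta, manifest, ["GA"])
        assert np.allclose(out["GA"], [0.1, 0.9])

    def test_mean_of_three_cpgs(self):
        beta = self._beta([[0.2], [0.4], [0.6]], ["cg1", "cg2", "cg3"], ["s1"])
        manifest = pd.DataFrame({"cpg_id": ["cg1", "cg2", "cg3"],
                                 "gene": ["GA"] * 3})
        out = cca.aggregate_cpg_to_gene(beta, manifest, ["GA"])
        assert out.loc["s1", "GA"] == pytest.approx(0.4)

    def test_cpg_shared_between_genes_contributes_to_both(self):
        beta = self._beta([[0.2], [0.4], [0.8], [0.6]],
                          ["cg1", "cg2", "cg3", "cg4"], ["s1"])
        manifest = pd.DataFrame({
            "cpg_id": ["cg1", "cg2", "cg2", "cg3", "cg4"],
            "gene": ["GA", "GA", "GB", "GB", "GB"],
        })
        out = cca.aggregate_cpg_to_gene(beta, manifest, ["GA", "GB"])
        assert out.loc["s1", "GA"] == pytest.approx((0.2 + 0.4) / 2)
        assert out.loc["s1", "GB"] == pytest.approx((0.4 + 0.8 + 0.6) / 3)

    def test_uncovered_gene_dropped_with_warning(self):
        beta = self._beta([[0.5]], ["cg1"], ["s1"])
        manifest = pd.DataFrame({"cpg_id": ["cg1"], "gene": ["GA"]})
        with pytest.warns(UserWarning, match="without CpG"):
            out = cca.aggregate_cpg_to_gene(beta, manifest, ["GA", "GB"])
        assert list(out.columns) == ["GA"]

    def test_missing_betas_averaged_over_observed(self):
        beta = self._beta([[0.2], [np.nan]], ["cg1", "cg2"], ["s1"])
        manifest = pd.DataFrame({"cpg_id": ["cg1", "cg2"], "gene": ["GA"] * 2})
        out = cca.aggregate_cpg_to_gene(beta, manifest, ["GA"])
        assert out.loc["s1", "GA"] == pytest.approx(0.2)


class TestDelta:
    def test_no_change_gives_zeros(self, rng):
        m = pd.DataFrame(rng.uniform(size=(4, 3)), index=list("abcd"),
                         columns=["g1", "g2", "g3"])
        assert np.allclose(cca.compute_delta(m, m.copy()), 0.0)

    def test_orientation_baseline_minus_followup(self):
        m0 = pd.DataFrame({"g": [0.6]}, index=["s1"])
        m8 = pd.DataFrame({"g": [0.5]}, index=["s1"])
        assert cca.compute_delta(m0, m8).loc["s1", "g"] == pytest.approx(0.1)

    def test_random_pair_matches_subtraction(self, rng):
        m0 = pd.DataFrame(rng.uniform(size=(5, 4)), index=list("abcde"))
        m8 = pd.DataFrame(rng.uniform(size=(5, 4)), index=list("abcde"))
        assert np.allclose(cca.compute_delta(m0, m8),
                           m0.to_numpy() - m8.to_numpy())

    def test_subject_mismatch_restricted_with_warning(self, rng):
        m0 = pd.DataFrame(rng.uniform(size=(4, 2)), index=list("abcd"))
        m8 = pd.DataFrame(rng.uniform(size=(3, 2)), index=list("abc"))
        with pytest.warns(UserWarning, match="restricted"):
            d = cca.compute_delta(m0, m8)
        assert list(d.index) == list("abc")


class TestLaplacianScore:
    def test_matches_brute_force_oracle_on_small_cohorts(self, rng):
        for n, m, k in ((5, 1, 2), (6, 4, 3), (8, 5, 5), (7, 3, 2)):
            X = pd.DataFrame(rng.standard_normal((n, m)))
            out = cca.laplacian_scores(X, k=k)
            expected = laplacian_score_oracle(X.to_numpy(), k)
            assert np.allclose(out["score"], expected, atol=1e-12)

    def test_subject_permutation_invariant(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 4)),
                         index=[f"s{i}" for i in range(12)])
        a = cca.laplacian_scores(X, k=4)
        b = cca.laplacian_scores(X.iloc[rng.permutation(12)], k=4)
        assert np.allclose(a["score"], b["score"], atol=1e-12)

    def test_constant_feature_flagged_and_ranked_last(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 3)),
                         columns=["a", "b", "flat"])
        X["flat"] = 1.0
        out = cca.laplacian_scores(X, k=3)
        assert out.loc["flat", "constant"]
        assert np.isnan(out.loc["flat", "score"])
        assert out.loc["flat", "rank"] == 3

    def test_k_too_large_is_error(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 2)))
        with pytest.raises(ConfigError, match="k < n"):
            cca.laplacian_scores(X, k=4)


class TestSelectFeatures:
    def test_select_all_is_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 4)),
                         columns=["a", "b", "c", "d"])
        tbl = cca.laplacian_scores(X, k=3)
        assert set(cca.select_features(tbl, 4)) == {"a", "b", "c", "d"}

    def test_smallest_scores_selected(self):
        tbl = pd.DataFrame({"score": [0.1, 0.5, 0.3],
                            "constant": [False] * 3, "rank": [1, 3, 2]},
                           index=["f1", "f2", "f3"])
        assert cca.select_features(tbl, 2) == ["f1", "f3"]

    def test_requesting_too_many_is_error(self):
        tbl = pd.DataFrame({"score": [0.1], "constant": [False], "rank": [1]},
                           index=["f1"])
        with pytest.raises(ConfigError, match="only 1"):
            cca.select_features(tbl, 2)

    def test_factor_driven_features_outrank_noise(self):
        """Features sharing a latent factor vary smoothly over the subject
        graph and should be preferred to white-noise features."""
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            rr = np.random.default_rng(2000 + rep)
            z = rr.standard_normal(40)
            smooth = z[:, None] + 0.3 * rr.standard_normal((40, 5))
            noise = rr.standard_normal((40, 15))
            X = pd.DataFrame(np.hstack([smooth, noise]),
                             columns=[f"sm{j}" for j in range(5)]
                             + [f"nz{j}" for j in range(15)])
            chosen = cca.select_features(cca.laplacian_scores(X, k=5), 5)
            wins += sum(c.startswith("sm") for c in chosen) >= 4
        assert wins >= int(0.90 * n_rep)


class TestFitCCA:
    def test_linear_dependence_gives_unit_correlations(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        Y = pd.DataFrame(X.to_numpy() @ A)
        res = cca.fit_cca(X, Y)
        assert np.allclose(res.canonical_correlations, 1.0, atol=1e-8)

    def test_univariate_blocks_reduce_to_pearson(self, rng):
        x = rng.standard_normal(25)
        y = 0.6 * x + 0.8 * rng.standard_normal(25)
        res = cca.fit_cca(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        assert res.canonical_correlations[0] == pytest.approx(
            abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        for _ in range(20):
            X = pd.DataFrame(rng.standard_normal((20, 3)))
            Y = pd.DataFrame(rng.standard_normal((20, 2)))
            res = cca.fit_cca(X, Y)
            expected = cca_corr_oracle(X.to_numpy(), Y.to_numpy())
            assert np.allclose(res.canonical_correlations, expected,
                               atol=1e-10)

    def test_variates_unit_variance_and_within_block_uncorrelated(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        Y = pd.DataFrame(rng.standard_normal((30, 3)))
        res = cca.fit_cca(X, Y)
        U = res.x_variates.to_numpy()
        V = res.y_variates.to_numpy()
        assert np.allclose(U.var(axis=0, ddof=1), 1.0, atol=1e-10)
        assert np.allclose(V.var(axis=0, ddof=1), 1.0, atol=1e-10)
        assert np.allclose(np.corrcoef(U.T) - np.eye(3), 0.0, atol=1e-8)
        for i in range(3):
            assert np.corrcoef(U[:, i], V[:, i])[0, 1] == pytest.approx(
                res.canonical_correlations[i], abs=1e-8)

    def test_invariant_to_invertible_recombination(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 4)))
        Y = pd.DataFrame(rng.standard_normal((25, 3)))
        base = cca.fit_cca(X, Y).canonical_correlations
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        B = rng.standard_normal((3, 3)) + 4 * np.eye(3)
        mixed = cca.fit_cca(pd.DataFrame(X.to_numpy() @ A),
                            pd.DataFrame(Y.to_numpy() @ B))
        assert np.allclose(base, mixed.canonical_correlations, atol=1e-8)

    def test_singular_block_reports_guidance(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)))
        X["dup"] = X[0]
        Y = pd.DataFrame(rng.standard_normal((10, 2)))
        with pytest.raises(Exception, match="reduce the number"):
            cca.fit_cca(X, Y)


class TestPermutationFWE:
    def test_bounds_and_monotone_across_modes(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 4)))
        Y = pd.DataFrame(rng.standard_normal((25, 3)))
        p = cca.permutation_fwe(X, Y, n_perm=199, seed=3)
        assert np.all(p >= 1 / 200) and np.all(p <= 1.0)
        assert np.all(np.diff(p) >= -1e-12)

    def test_power_on_strong_planted_mode(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rr = np.random.default_rng(3000 + rep)
            z = rr.standard_normal(60)
            X = pd.DataFrame(z[:, None] + 0.35 * rr.standard_normal((60, 4)))
            Y = pd.DataFrame(z[:, None] + 0.35 * rr.standard_normal((60, 3)))
            p = cca.permutation_fwe(X, Y, n_perm=199, seed=rep)
            hits += p[0] < 0.05
        assert hits >= int(0.95 * n_rep)

    def test_seed_reproducible(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)))
        Y = pd.DataFrame(rng.standard_normal((20, 2)))
        assert np.array_equal(cca.permutation_fwe(X, Y, n_perm=150, seed=7),
                              cca.permutation_fwe(X, Y, n_perm=150, seed=7))


class TestLoadings:
    def test_feature_equal_to_variate_has_unit_loading(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)),
                         columns=["a", "b", "c"])
        Y = pd.DataFrame({"y": X["a"].to_numpy()})
        res = cca.fit_cca(X, Y)
        tab = res.loadings(mode=1)
        assert abs(tab.loc["a", "r"]) == pytest.approx(1.0, abs=1e-8)
        assert tab.loc["a", "q"] == tab["q"].min()

    def test_orthogonal_feature_has_zero_loading(self):
        n = 16
        v = np.sin(np.linspace(0, 3 * np.pi, n))
        orth = np.cos(np.linspace(0, 3 * np.pi, n))
        orth -= orth.mean()
        orth -= (orth @ (v - v.mean())) / ((v - v.mean()) @ (v - v.mean())) \
            * (v - v.mean())
        X = pd.DataFrame({"match": v, "orth": orth})
        Y = pd.DataFrame({"y": v})
        res = cca.fit_cca(X, Y)
        tab = res.loadings(mode=1)
        assert abs(tab.loc["orth", "r"]) < 1e-10
        assert not tab.loc["orth", "significant"]

    def test_bh_matches_oracle_on_ten_features(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 10)),
                         columns=[f"g{j}" for j in range(10)])
        Y = pd.DataFrame(rng.standard_normal((30, 2)))
        res = cca.fit_cca(X, Y)
        tab = res.loadings(mode=1).sort_index()
        assert np.allclose(tab["q"], bh_oracle(tab["p"]), atol=1e-12)

    def test_significance_invariant_under_variate_sign_flip(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 5)))
        Y = pd.DataFrame(rng.standard_normal((25, 3)))
        res = cca.fit_cca(X, Y)
        tab = res.loadings(mode=1)
        flipped = cca.SymptomCCAResults(
            model=res.model,
            canonical_correlations=res.canonical_correlations,
            x_weights=-res.x_weights, y_weights=-res.y_weights,
            x_variates=-res.x_variates, y_variates=-res.y_variates,
            p_fwe=res.p_fwe)
        tab2 = flipped.loadings(mode=1)
        assert np.allclose(tab["r"], -tab2["r"], atol=1e-12)
        assert np.allclose(tab["q"], tab2["q"], atol=1e-12)
        assert (tab["significant"] == tab2["significant"]).all()

    def test_nonsignificant_mode_warns(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)))
        Y = pd.DataFrame(rng.standard_normal((20, 2)))
        res = cca.SymptomCCA(X, Y).fit(n_perm=199, seed=0)
        if res.p_fwe[0] >= 0.05:
            with pytest.warns(UserWarning, match="exploratory"):
                res.loadings(mode=1)


class TestRunStep3:
    def test_planted_longitudinal_mode_recovered_baseline_null(self):
        from cortexlink.synthetic import SyntheticConfig

        cfg = SyntheticConfig(seed=5)  # reference cohort: 38 treated subjects
        b0, b8, man, p0, p8, truth = gen_methylation_panss(
            cfg, cfg.gene_symbols)
        rep = cca.run_step3(b0, b8, man, p0, p8, cfg.gene_symbols,
                            s=15, n_perm=499, seed=2)
        assert rep.n_subjects == 38
        assert rep.longitudinal.p_fwe[0] < 0.05
        assert rep.baseline.p_fwe[0] >= 0.05
        # the selected longitudinal features should be mostly driven genes
        driven = set(truth["driven_genes"])
        assert len(driven & set(rep.selected_longitudinal)) >= 8

    def test_consistent_subject_permutation_leaves_fit_unchanged(self):
        cfg = small_config(n_patients=20, n_dropout=0, n_genes=30, seed=9)
        b0, b8, man, p0, p8, _ = gen_methylation_panss(cfg, cfg.gene_symbols)
        rep = cca.run_step3(b0, b8, man, p0, p8, cfg.gene_symbols,
                            s=8, n_perm=0, seed=0)
        perm = np.random.default_rng(4).permutation(b0.shape[1])
        cols = [b0.columns[i] for i in perm]
        rep2 = cca.run_step3(b0[cols], b8[cols], man,
                             p0.iloc[::-1].reset_index(drop=True), p8,
                             cfg.gene_symbols, s=8, n_perm=0, seed=0)
        assert np.allclose(rep.longitudinal.canonical_correlations,
                           rep2.longitudinal.canonical_correlations,
                           atol=1e-10)
        assert set(rep.selected_longitudinal) == set(rep2.selected_longitudinal)

    def test_subjects_missing_followup_dropped(self):
        cfg = small_config(n_patients=24, n_dropout=4, n_genes=30, seed=3)
        b0, b8, man, p0, p8, _ = gen_methylation_panss(cfg, cfg.gene_symbols)
        rep = cca.run_step3(b0, b8, man, p0, p8, cfg.gene_symbols,
                            s=8, n_perm=0, seed=0)
        assert rep.n_subjects == 20
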