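"""PGLS fits, phylogenetic correlations and independent contrasts."""
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phyloles.evomodels import bm_fit
from phyloles.pgls import design_matrix, pgls_correlation, pgls_fit, pgls_group_table, pic
from phyloles.phylo import PhyloCovariance, parse_newick, tree_vcv
from phyloles.simulate import FixtureConfig, simulate_les_dataset, simulate_trait, simulate_yule_tree
from phyloles.traits import log10_table

from conftest import random_yule_trees


def star_cov(n, labels=None):
    labels = labels or tuple(f"s{i}" for i in range(n))
    return PhyloCovariance(labels=tuple(labels), C=np.eye(n),
                           tip_depths=np.ones(n))


class TestPglsFit:
    def test_identity_covariance_equals_ols(self):
        """On a star phylogeny PGLS is OLS, coefficient by coefficient
        (statsmodels oracle)."""
        rng = np.random.default_rng(0)
        n = 40
        cov = star_cov(n)
        x = rng.standard_normal(n)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.3, n)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x},
                         index=list(cov.labels))
        fit = pgls_fit(pd.Series(y, index=list(cov.labels)), X, cov)
        ols = sm.OLS(y, X.to_numpy()).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-10)
        assert np.allclose(fit.bse.to_numpy(), ols.bse, atol=1e-10)
        assert np.allclose(fit.tvalues.to_numpy(), ols.tvalues, atol=1e-10)
        assert np.allclose(fit.pvalues.to_numpy(), ols.pvalues, atol=1e-10)
        assert fit.fvalue == pytest.approx(ols.fvalue, rel=1e-9)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)

    def test_slope_equals_pic_through_origin_regression(self):
        """Under fixed BM the PGLS slope equals the through-origin
        regression of y-contrasts on x-contrasts (Felsenstein identity),
        checked on 100 random trees/datasets."""
        rng = np.random.default_rng(1)
        for tree in random_yule_trees(100, 12, seed=2):
            cov = tree_vcv(tree)
            x = simulate_trait(cov, model="BM", seed=rng)
            y = 0.7 * x + simulate_trait(cov, model="BM", sigma2=0.5, seed=rng)
            X = pd.DataFrame(
                {"Intercept": np.ones(cov.n), "x": x.loc[list(cov.labels)]},
                index=list(cov.labels),
            )
            fit = pgls_fit(y, X, cov)
            cx = pic(tree, x).contrasts
            cy = pic(tree, y).contrasts
            slope_pic = float(cx @ cy / (cx @ cx))
            assert fit.params["x"] == pytest.approx(slope_pic, abs=1e-8)

    def test_habit_effect_recovery(self, balanced_cov_128):
        """A habit shift of 1.0 added to a lambda=0.9 trait is recovered
        with mean coefficient in [0.9, 1.1] over 200 replicates."""
        rng = np.random.default_rng(3)
        labels = list(balanced_cov_128.labels)
        habit = pd.Series(
            ["evergreen" if i < 64 else "deciduous" for i in range(128)],
            index=labels, name="habit",
        )
        data = pd.DataFrame({"habit": habit})
        X = design_matrix(data, ["habit"])
        est = []
        for _ in range(200):
            x = simulate_trait(balanced_cov_128, model="lambda", lam=0.9,
                               seed=rng)
            y = x + (habit == "deciduous") * 1.0
            fit = pgls_fit(y, X, balanced_cov_128)
            est.append(fit.params["habit[deciduous]"])
        assert 0.9 <= np.mean(est) <= 1.1

    def test_rank_deficiency_names_columns(self):
        cov = star_cov(10)
        X = pd.DataFrame(
            {"Intercept": np.ones(10), "a": np.arange(10.0),
             "b": 2 * np.arange(10.0)},
            index=list(cov.labels),
        )
        y = pd.Series(np.random.default_rng(4).standard_normal(10),
                      index=list(cov.labels))
        with pytest.raises(ValueError, match="aliased"):
            pgls_fit(y, X, cov)

    def test_type_one_error_of_habit_f_test(self):
        """No-effect BM simulation: the habit F-test rejects at ~5%."""
        tree = simulate_yule_tree(64, seed=5, depth=1.0)
        cov = tree_vcv(tree)
        labels = list(cov.labels)
        rng = np.random.default_rng(6)
        habit = pd.Series((["evergreen", "deciduous"] * 32)[:64], index=labels)
        X = design_matrix(pd.DataFrame({"habit": habit}), ["habit"])
        rejections = 0
        reps = 500
        for _ in range(reps):
            y = simulate_trait(cov, model="BM", seed=rng)
            if pgls_fit(y, X, cov).f_pvalue < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07


class TestPglsCorrelation:
    def test_perfect_linear_relation(self):
        cov = star_cov(20)
        rng = np.random.default_rng(7)
        x = pd.Series(rng.standard_normal(20), index=list(cov.labels))
        y = 2 * x + 3
        assert pgls_correlation(x, y, cov) == pytest.approx(1.0)

    def test_identity_covariance_equals_pearson(self):
        cov = star_cov(50)
        rng = np.random.default_rng(8)
        x = pd.Series(rng.standard_normal(50), index=list(cov.labels))
        y = pd.Series(0.5 * x + rng.normal(0, 1, 50), index=list(cov.labels))
        from scipy.stats import pearsonr

        assert pgls_correlation(x, y, cov) == pytest.approx(
            pearsonr(x, y)[0], abs=1e-10
        )

    def test_symmetry_and_affine_invariance(self):
        for tree in random_yule_trees(20, 10, seed=9):
            cov = tree_vcv(tree)
            rng = np.random.default_rng(10)
            x = simulate_trait(cov, model="BM", seed=rng)
            y = simulate_trait(cov, model="BM", seed=rng)
            r_xy = pgls_correlation(x, y, cov)
            r_yx = pgls_correlation(y, x, cov)
            assert r_xy == pytest.approx(r_yx, abs=1e-10)
            r_aff = pgls_correlation(2 * x + 1, -1 * y + 5, cov)
            assert r_aff == pytest.approx(-r_xy, abs=1e-10)

    def test_evolutionary_correlation_recovery(self):
        """Correlated BM (true r = 0.8): mean estimate within [0.75, 0.85]
        over 200 replicates at n = 128."""
        tree = simulate_yule_tree(128, seed=11, depth=1.0)
        cov = tree_vcv(tree)
        L = np.linalg.cholesky(cov.C)
        rng = np.random.default_rng(12)
        rho = 0.8
        est = []
        labels = list(cov.labels)
        for _ in range(200):
            z1 = rng.standard_normal(128)
            z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(128)
            x = pd.Series(L @ z1, index=labels)
            y = pd.Series(L @ z2, index=labels)
            est.append(pgls_correlation(x, y, cov))
        assert 0.75 <= np.mean(est) <= 0.85


class TestGroupTable:
    def test_strong_habit_separation(self):
        """A generator fixture with a large habit gap gives habit p <
        0.001 at every elevation for the latent-aligned traits."""
        cfg = FixtureConfig(seed=99, delta_habit=8.0, latent_sigma2=0.02,
                            communality=0.98, habit_assignment="iid")
        table, _, tree = simulate_les_dataset(cfg)
        cov = tree_vcv(tree).subset(list(table.species))
        out = pgls_group_table(table, cov)
        for e in ("low", "middle", "high"):
            assert out.loc["LMA", f"p_habit_{e}"] < 0.001

    def test_subset_covariance_equals_pruned_tree(self, default_fixture):
        """Dropping rows/columns of the covariance equals recomputing the
        VCV on the pruned subtree (prune-vs-subset oracle, via dendropy
        pruning)."""
        import dendropy

        from phyloles.phylo import parse_newick as pn, write_newick

        tree = default_fixture.tree
        cov = tree_vcv(tree)
        keep = list(cov.labels[:10])
        sub = cov.subset(keep)
        dt = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        dt.retain_taxa_with_labels(keep)
        pruned = pn(dt.as_string(schema="newick"))
        cov2 = tree_vcv(pruned)
        order = [cov2.labels.index(l) for l in keep]
        assert np.allclose(sub.C, cov2.C[np.ix_(order, order)], atol=1e-9)

    def test_small_subset_flagged_not_computed(self):
        cfg = FixtureConfig(seed=100)
        table, _, tree = simulate_les_dataset(cfg)
        # restrict to too few species at one elevation by dropping rows
        cov = tree_vcv(tree).subset(list(table.species))
        out = pgls_group_table(table, cov)
        assert set(c for c in out.columns if c.startswith("p_habit_")) == {
            "p_habit_low", "p_habit_middle", "p_habit_high"
        }


class TestPic:
    def test_two_tip_hand_pruning(self):
        tree = parse_newick("(A:1,B:1);")
        cs = pic(tree, pd.Series({"A": 0.0, "B": 2.0}))
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(math.sqrt(2.0))

    def test_equal_values_zero_contrasts(self):
        tree = parse_newick("((A:1,B:1):1,(C:2,D:0.5):1);")
        cs = pic(tree, pd.Series({"A": 3.0, "B": 3.0, "C": 3.0, "D": 3.0}))
        assert np.allclose(cs.contrasts, 0.0)

    def test_sum_of_squares_equals_n_times_ml_rate(self):
        """Sum of squared standardized contrasts = n * sigma2_ML (the
        identity linking PIC and the BM GLS quadratic form)."""
        for tree in random_yule_trees(10, 16, seed=13):
            cov = tree_vcv(tree)
            x = simulate_trait(cov, model="BM", seed=14)
            cs = pic(tree, x)
            fit = bm_fit(cov, x)
            assert (cs.contrasts**2).sum() == pytest.approx(
                cov.n * fit.sigma2, rel=1e-8
            )

    def test_zero_combined_branch_length_rejected(self):
        tree = parse_newick("(A:0,B:0);")
        with pytest.raises(ValueError, match="zero combined"):
            pic(tree, pd.Series({"A": 0.0, "B": 1.0}))

    def test_polytomy_resolved(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        cs = pic(tree, pd.Series({"A": 0.0, "B": 1.0, "C": 2.0}))
        assert len(cs.contrasts) == 2
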