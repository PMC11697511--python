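import numpy as np
import pandas as pd
import pytest

import phylosym as ps
from phylosym.comparative import MODEL_ORDER


class TestTransforms:
    @pytest.fixture
    def V(self):
        return ps.simulate_yule_tree(16, seed=2).vcv()[1]

    @pytest.mark.parametrize("param", ["lambda", "delta"])
    def test_value_one_is_identity_on_vcv(self, V, param):
        np.testing.assert_allclose(ps.transform_vcv(V, param, 1.0), V, atol=1e-12)

    def test_kappa_one_identity_on_tree(self):
        t = ps.simulate_yule_tree(12, seed=3)
        tk = ps.transform_tree(t, "kappa", 1.0)
        np.testing.assert_allclose(tk.vcv()[1], t.vcv()[1], atol=1e-12)

    def test_lambda_zero_diagonalizes(self, V):
        out = ps.transform_vcv(V, "lambda", 0.0)
        np.testing.assert_allclose(out, np.diag(np.diag(V)), atol=1e-15)

    def test_kappa_zero_unit_branches(self):
        t = ps.simulate_yule_tree(12, seed=4)
        tk = ps.transform_tree(t, "kappa", 0.0)
        lengths = [
            e.length
            for e in tk.dendropy_tree.preorder_edge_iter()
            if e.length is not None
        ]
        np.testing.assert_allclose(lengths, 1.0)

    def test_delta_preserves_total_depth(self):
        t = ps.simulate_yule_tree(12, seed=5)
        td = ps.transform_tree(t, "delta", 2.5)
        assert td.max_depth() == pytest.approx(t.max_depth(), rel=1e-9)

    def test_out_of_bounds_rejected(self, V):
        with pytest.raises(ValueError):
            ps.transform_vcv(V, "lambda", 1.5)


class TestPic:
    def test_cherry_contrast(self, cherry):
        c = ps.pic(cherry, pd.Series({"A": 3.0, "B": 1.0}))
        assert c.values[0] == pytest.approx(2 / np.sqrt(2), abs=1e-9)

    def test_three_tip_recursion_by_hand(self, three_tip, three_tip_traits):
        c = ps.pic(three_tip, three_tip_traits)
        np.testing.assert_allclose(c.values, [-1.41421356, 1.06904497], atol=1e-6)
        # node AB takes value 3 with stem branch augmented to 1.5
        assert c.table["node_value"].iloc[0] == pytest.approx(3.0)
        assert c.table["augmented_length"].iloc[0] == pytest.approx(1.5)

    def test_constant_trait_zero_contrasts(self, three_tip):
        c = ps.pic(three_tip, pd.Series({"A": 5.0, "B": 5.0, "C": 5.0}))
        np.testing.assert_allclose(c.values, 0.0, atol=1e-12)

    def test_contrast_count_on_bifurcating_tree(self):
        t = ps.simulate_yule_tree(25, seed=6)
        x = ps.simulate_bm(t, seed=1)
        assert len(ps.pic(t, x).values) == 24

    def test_polytomy_resolved(self):
        t = ps.parse_newick("(A:1,B:1,C:1,D:1);")
        x = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert len(ps.pic(t, x).values) == 3

    def test_missing_value_rejected(self, three_tip):
        with pytest.raises(ValueError, match="C"):
            ps.pic(three_tip, pd.Series({"A": 1.0, "B": 2.0}))


class TestPgls:
    def test_star_tree_reduces_to_ols(self):
        t = ps.parse_newick("(A:1,B:1,C:1,D:1);")
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        fit = ps.pgls_fit(t, y, y.rename("x"))
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_pic_pgls_equivalence(self, seed):
        """Fixed-tree PGLS slope equals the through-origin PIC regression slope."""
        t = ps.simulate_yule_tree(32, seed=seed)
        x = ps.simulate_bm(t, seed=seed * 2 + 1)
        y = 0.5 * x + ps.simulate_bm(t, seed=seed * 2 + 2)
        fit = ps.pgls_fit(t, y, x.rename("x"))
        cx, cy = ps.pic(t, x), ps.pic(t, y)
        slope_pic = float(np.sum(cx.values * cy.values) / np.sum(cx.values**2))
        assert fit.slope == pytest.approx(slope_pic, abs=1e-8)

    def test_lambda_zero_equals_ols_on_unit_depth_tree(self):
        """At λ = 0 an ultrametric unit-depth tree gives V = I, i.e. plain OLS."""
        t = ps.simulate_yule_tree(24, seed=7)  # unit height by construction
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=24), index=t.tip_labels, name="x")
        y = pd.Series(2.0 + 0.8 * x + rng.normal(size=24) * 0.3, index=t.tip_labels)
        taxa, _ = t.vcv()
        ols = np.polyfit(x[taxa], y[taxa], 1)
        fit = ps.pgls_fit(t, y, x, model="lambda", transform_value=0.0)
        assert fit.slope == pytest.approx(ols[0], abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(ols[1], abs=1e-10)

    def test_aicc_small_sample_formula(self):
        # logLik −5, k = 3, n = 10 → AIC 16, AICc 16 + 24/6 = 20
        aic = -2 * -5 + 2 * 3
        assert aic == 16
        assert aic + 2 * 3 * 4 / (10 - 3 - 1) == 20
        t = ps.simulate_yule_tree(10, seed=8)
        y = ps.simulate_bm(t, seed=3)
        x = ps.simulate_bm(t, seed=4)
        fit = ps.pgls_fit(t, y, x.rename("x"))  # k = 3: slope, intercept, σ²
        assert fit.k == 3
        assert fit.aicc == pytest.approx(fit.aic + 24 / 6, abs=1e-10)

    def test_complete_case_dropping_reported(self):
        t = ps.simulate_yule_tree(12, seed=9)
        y = ps.simulate_bm(t, seed=5)
        x = ps.simulate_bm(t, seed=6).rename("x")
        y.iloc[3] = np.nan
        fit = ps.pgls_fit(t, y, x)
        assert fit.n == 11
        assert len(fit.dropped) == 1

    def test_singular_design_rejected(self):
        t = ps.simulate_yule_tree(8, seed=10)
        y = ps.simulate_bm(t, seed=7)
        x = pd.DataFrame({"a": np.ones(8), "b": np.ones(8)}, index=t.tip_labels)
        with pytest.raises(ValueError, match="singular"):
            ps.pgls_fit(t, y, x)

    def test_transform_estimate_within_bounds(self):
        t = ps.simulate_yule_tree(20, seed=11)
        y = ps.simulate_bm(t, seed=8)
        x = ps.simulate_bm(t, seed=9).rename("x")
        for model, (lo, hi) in (("lambda", (0, 1)), ("delta", (0, 3)), ("kappa", (0, 3))):
            fit = ps.pgls_fit(t, y, x, model=model)
            assert lo <= fit.transform_value <= hi

    def test_multiple_predictors(self):
        t = ps.simulate_yule_tree(20, seed=12)
        x1 = ps.simulate_bm(t, seed=10).rename("x1")
        x2 = ps.simulate_bm(t, seed=11).rename("x2")
        y = 0.5 * x1 - 0.3 * x2 + 0.1 * ps.simulate_bm(t, seed=12)
        fit = ps.pgls_fit(t, y, pd.concat([x1, x2], axis=1))
        assert fit.params["x1"] == pytest.approx(0.5, abs=0.15)
        assert fit.params["x2"] == pytest.approx(-0.3, abs=0.15)


class TestModelSelect:
    def _fits(self, n=20, seed=13):
        t = ps.simulate_yule_tree(n, seed=seed)
        y = ps.simulate_bm(t, seed=20)
        x = ps.simulate_bm(t, seed=21).rename("x")
        return ps.fit_all_models(t, y, x)

    def test_minimum_aicc_wins(self):
        fits = self._fits()
        best = ps.model_select(fits)
        assert best.aicc == min(f.aicc for f in fits)

    def test_single_candidate(self):
        fits = self._fits()
        assert ps.model_select([fits[2]]) is fits[2]

    def test_tie_breaks_toward_fixed_model(self):
        fits = self._fits()
        for f in fits:
            f.aicc = 10.0  # forced tie: fewer parameters, then model order
        assert ps.model_select(fits).model == "fixed"
        assert [m for m in MODEL_ORDER] == ["fixed", "lambda", "delta", "kappa"]


def brute_force_bh(p):
    """Step-up definition applied literally: q(i) = min_{j≥i} p(j)·m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestFdrBh:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            ps.fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert ps.fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(14)
        p = rng.random(50)
        q = ps.fdr_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(ps.fdr_bh(p), brute_force_bh(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ps.fdr_bh([0.5, 1.2])


class TestAncestralStates:
    def test_symmetric_cherry_root(self, cherry):
        anc = ps.ancestral_states(cherry, pd.Series({"A": 0.0, "B": 2.0}))
        assert anc.root_estimate == pytest.approx(1.0, abs=1e-9)

    def test_three_tip_root_by_hand(self, three_tip, three_tip_traits):
        # root = (3/1.5 + 1/2) / (1/1.5 + 1/2) = 2.14286
        anc = ps.ancestral_states(three_tip, three_tip_traits)
        assert anc.root_estimate == pytest.approx(2.142857142857, abs=1e-9)

    def test_constant_trait(self, three_tip):
        anc = ps.ancestral_states(three_tip, pd.Series({"A": 7.0, "B": 7.0, "C": 7.0}))
        np.testing.assert_allclose(anc.table["estimate"], 7.0, atol=1e-9)

    def test_root_equals_pic_root(self):
        t = ps.simulate_yule_tree(30, seed=15)
        x = ps.simulate_bm(t, seed=30)
        anc = ps.ancestral_states(t, x)
        assert anc.root_estimate == pytest.approx(ps.pic(t, x).root_value, abs=1e-8)

    def test_variances_positive(self, three_tip, three_tip_traits):
        anc = ps.ancestral_states(three_tip, three_tip_traits)
        assert (anc.table["variance"] > 0).all()
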