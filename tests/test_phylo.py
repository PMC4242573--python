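"""Phylogenetic covariance, PGLS, contrasts, ANCOVA, bootstrap."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubne import phylo, simulate
from cubne.phylo import (
    ancestral_states,
    bootstrap_median_ci,
    compartment_ancova,
    contrast_sign_test,
    independent_contrasts,
    order_robustness,
    pgls,
    phylo_covariance,
)


def get_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestCovariance:
    def test_star_tree_diagonal_any_lambda(self):
        tree = get_tree("(a:2,b:2,c:2,d:2);")
        for lam in (0.0, 0.5, 1.0):
            _, C = phylo_covariance(tree, lam)
            assert np.allclose(C, np.diag([2.0] * 4))

    def test_lambda_zero_diagonal_regardless_of_topology(self):
        tree = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
        _, C = phylo_covariance(tree, 0.0)
        assert np.allclose(C, np.diag([2.0] * 4))

    def test_balanced_tree_shared_paths(self):
        tree = get_tree("((a:1,b:1):1,(c:1,d:1):1);")
        labels, C = phylo_covariance(tree, 1.0)
        expect = {("a", "b"): 1.0, ("c", "d"): 1.0}
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    assert C[i, j] == 2.0
                else:
                    assert C[i, j] == expect.get(tuple(sorted((x, y))), 0.0)

    def test_negative_branch_length_rejected(self):
        tree = get_tree("((a:1,b:-1):1,c:2);")
        with pytest.raises(ValueError):
            phylo_covariance(tree, 1.0)


class TestPGLS:
    def test_identity_regression(self):
        cfg = simulate.SimulationConfig(seed=3, n_tips=10)
        tt = simulate.gen_trait_tree(cfg)
        res = pgls(tt.tree, tt.traits["x"], tt.traits["x"])
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_reduces_to_ols_at_lambda_zero(self):
        rng = np.random.default_rng(0)
        tips = [f"t{i}" for i in range(15)]
        tree = get_tree("(" + ",".join(f"{t}:1" for t in tips) + ");")
        x = pd.Series(rng.normal(0, 1, 15), index=tips)
        y = pd.Series(1 + 0.4 * x.to_numpy() + rng.normal(0, 0.3, 15), index=tips)
        res = pgls(tree, x, y, lam=0.0)
        import statsmodels.api as sm

        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert res.slope == pytest.approx(ols.params[1], abs=1e-6)
        assert res.t == pytest.approx(ols.tvalues[1], abs=1e-6)
        assert res.p == pytest.approx(ols.pvalues[1], abs=1e-6)

    def test_slope_recovery_and_type_i(self):
        slopes, null_p = [], []
        for rep in range(150):
            cfg = simulate.SimulationConfig(seed=60_000 + rep, n_tips=41,
                                            trait_slope=-0.5, noise_sigma2=0.25)
            tt = simulate.gen_trait_tree(cfg)
            slopes.append(pgls(tt.tree, tt.traits["x"], tt.traits["y"]).slope)
            cfg0 = simulate.SimulationConfig(seed=70_000 + rep, n_tips=41,
                                             trait_slope=0.0)
            tt0 = simulate.gen_trait_tree(cfg0)
            null_p.append(pgls(tt0.tree, tt0.traits["x"], tt0.traits["y"]).p)
        assert np.mean(slopes) == pytest.approx(-0.5, abs=0.05)
        rej = np.mean(np.asarray(null_p) < 0.05)
        assert 0.01 <= rej <= 0.11  # binomial band around 5% at 150 reps

    def test_lambda_recovery(self):
        for lam_true, band in ((0.0, 0.15), (1.0, 0.15)):
            est = [
                pgls(
                    (tt := simulate.gen_trait_tree(
                        simulate.SimulationConfig(
                            seed=80_000 + rep, n_tips=41, lambda_y=lam_true)
                    )).tree, tt.traits["x"], tt.traits["y"],
                ).lam
                for rep in range(40)
            ]
            assert abs(float(np.median(est)) - lam_true) <= band

    def test_constant_predictor_rejected(self):
        cfg = simulate.SimulationConfig(seed=3, n_tips=8)
        tt = simulate.gen_trait_tree(cfg)
        const = pd.Series(1.0, index=tt.traits.index)
        with pytest.raises(ValueError):
            pgls(tt.tree, const, tt.traits["y"])


class TestOrderRobustness:
    def test_all_orders_agree_for_well_conditioned_fit(self):
        cfg = simulate.SimulationConfig(seed=9, n_tips=6, trait_slope=-0.5)
        tt = simulate.gen_trait_tree(cfg)
        rob = order_robustness(tt.tree, tt.traits["x"], tt.traits["y"])
        assert rob["n_orders"] == 720
        assert rob["spread_t"] < 1e-6

    def test_single_order_equals_plain_pgls(self):
        cfg = simulate.SimulationConfig(seed=10, n_tips=8, trait_slope=0.3)
        tt = simulate.gen_trait_tree(cfg)
        rob = order_robustness(tt.tree, tt.traits["x"], tt.traits["y"], n_orders=1)
        res = pgls(tt.tree, tt.traits["x"], tt.traits["y"])
        assert rob["median_t"] == pytest.approx(res.t)


def brute_force_contrasts(tree, trait):
    """Independent recursive implementation of Felsenstein's algorithm."""
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)

    out = []

    def recurse(node):
        if node.is_leaf():
            return float(trait[node.taxon.label]), node.edge.length or 0.0
        (x1, v1), (x2, v2) = (recurse(ch) for ch in node.child_nodes())
        out.append((x1 - x2) / math.sqrt(v1 + v2))
        xk = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        vk = (node.edge.length or 0.0) + v1 * v2 / (v1 + v2)
        return xk, vk

    recurse(tree.seed_node)
    return out


class TestContrasts:
    def test_two_tip_textbook_value(self):
        tree = get_tree("(a:1,b:1);")
        c = independent_contrasts(tree, pd.Series({"a": 3.0, "b": 1.0}))
        assert c["contrast"].iloc[0] == pytest.approx(2.0 / math.sqrt(2.0))

    def test_equal_values_give_zero_contrasts(self):
        cfg = simulate.SimulationConfig(seed=4, n_tips=10)
        tt = simulate.gen_trait_tree(cfg)
        trait = pd.Series(5.0, index=tt.traits.index)
        c = independent_contrasts(tt.tree, trait)
        assert np.allclose(c["contrast"], 0.0)
        assert len(c) == 9  # n - 1 contrasts

    def test_matches_brute_force_oracle(self):
        cfg = simulate.SimulationConfig(seed=5, n_tips=17)
        tt = simulate.gen_trait_tree(cfg)
        mine = sorted(independent_contrasts(tt.tree, tt.traits["x"])["contrast"])
        oracle = sorted(brute_force_contrasts(tt.tree, tt.traits["x"]))
        assert np.allclose(mine, oracle)

    def test_polytomy_resolved_with_zero_length(self):
        tree = get_tree("((m1:0.35,m2:0.35,m3:0.35):1,r:1.35);")
        c = independent_contrasts(tree, pd.Series(
            {"m1": 1.0, "m2": 2.0, "m3": 3.0, "r": 0.0}))
        assert len(c) == 3

    def test_zero_branch_cherry_errors_with_node_name(self):
        tree = get_tree("((a:0,b:0):1,c:2);")
        with pytest.raises(ValueError, match="zero summed branch length"):
            independent_contrasts(tree, pd.Series({"a": 1.0, "b": 2.0, "c": 0.0}))

    def test_brownian_contrast_variance_standardized(self):
        """Standardized contrasts of a Brownian simulation have mean square
        close to the Brownian rate (2-SE band)."""
        all_c = []
        for rep in range(30):
            cfg = simulate.SimulationConfig(seed=90_000 + rep, n_tips=20,
                                            brownian_sigma2=2.0)
            tt = simulate.gen_trait_tree(cfg)
            all_c.extend(independent_contrasts(tt.tree, tt.traits["x"])["contrast"])
        msq = np.mean(np.square(all_c))
        se = np.std(np.square(all_c)) / math.sqrt(len(all_c))
        assert abs(msq - 2.0) < 2 * se + 0.05


class TestSignTest:
    def test_perfect_agreement(self):
        c = np.array([1.0, -2.0, 3.0, -4.0])
        n_agree, n_total, p = contrast_sign_test(c, c)
        assert (n_agree, n_total) == (4, 4)

    def test_perfect_disagreement(self):
        c = np.array([1.0, -2.0, 3.0])
        n_agree, _, _ = contrast_sign_test(c, -c)
        assert n_agree == 0

    def test_exact_binomial_by_enumeration(self):
        """22 agreements of 40 reproduces the fully enumerated two-sided
        binomial tail probability."""
        cx = np.ones(40)
        cy = np.concatenate([np.ones(22), -np.ones(18)])
        _, _, p = contrast_sign_test(cx, cy)
        pmf = [math.comb(40, k) * 0.5 ** 40 for k in range(41)]
        expected = sum(q for q in pmf if q <= pmf[22] * (1 + 1e-12))
        assert p == pytest.approx(expected, rel=1e-9)
        assert p > 0.5  # a 22/40 split is consistent with the null

    def test_zero_x_contrasts_dropped(self):
        cx = np.array([0.0, 1.0, -1.0])
        cy = np.array([5.0, 1.0, -1.0])
        _, n_total, _ = contrast_sign_test(cx, cy)
        assert n_total == 2


def oracle_ancestral(tree, trait):
    """GLS reconstruction oracle using explicit root-path sets."""
    trait = pd.Series(trait, dtype=float)

    def path(node):
        out = []
        while node.parent_node is not None:
            out.append(node)
            node = node.parent_node
        return out

    leaves = list(tree.leaf_node_iter())
    internal = [n for n in tree.preorder_internal_node_iter()]
    blen = lambda n: n.edge.length or 0.0  # noqa: E731

    def shared(u, v):
        pu, pv = set(path(u)), path(v)
        return sum(blen(n) for n in pv if n in pu)

    n = len(leaves)
    C = np.array([[shared(a, b) for b in leaves] for a in leaves])
    y = trait.loc[[lf.taxon.label for lf in leaves]].to_numpy()
    ones = np.ones(n)
    mu = (ones @ np.linalg.solve(C, y)) / (ones @ np.linalg.solve(C, ones))
    est = []
    for node in internal:
        c = np.array([shared(node, lf) for lf in leaves])
        est.append(mu + c @ np.linalg.solve(C, y - mu * ones))
    return np.array(est)


class TestAncestralStates:
    def test_two_tips_equal_lengths_root_is_mean(self):
        tree = get_tree("(a:1,b:1);")
        anc = ancestral_states(tree, pd.Series({"a": 4.0, "b": 2.0}))
        assert anc.iloc[0] == pytest.approx(3.0)

    def test_constant_trait_constant_reconstruction(self):
        cfg = simulate.SimulationConfig(seed=6, n_tips=9)
        tt = simulate.gen_trait_tree(cfg)
        anc = ancestral_states(tt.tree, pd.Series(7.0, index=tt.traits.index))
        assert np.allclose(anc, 7.0)

    def test_matches_gls_oracle_on_8_tip_tree(self):
        cfg = simulate.SimulationConfig(seed=8, n_tips=8)
        tt = simulate.gen_trait_tree(cfg)
        mine = ancestral_states(tt.tree, tt.traits["x"]).to_numpy()
        oracle = oracle_ancestral(tt.tree, tt.traits["x"])
        assert np.allclose(mine, oracle, atol=1e-8)


def _gene_table(rng, n=2000, shift=0.0, confound=False):
    group = np.where(rng.random(n) < 0.5, "A", "X")
    exon_len = rng.lognormal(7, 0.5, n)
    intron_len = rng.lognormal(8, 0.8, n)
    value = 50 + 0.3 * rng.standard_normal(n)
    if confound:
        value = 50 + 0.001 * exon_len + 0.3 * rng.standard_normal(n)
    value = value + shift * (group == "X")
    return pd.DataFrame({
        "value": value, "group": group,
        "exon_length": exon_len, "intron_length": intron_len,
    })


class TestAncova:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [compartment_ancova(_gene_table(rng, n=400), value="value").p
              for _ in range(60)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_group_shift(self):
        rng = np.random.default_rng(2)
        hits = sum(
            compartment_ancova(_gene_table(rng, shift=0.5), value="value").p < 0.05
            for _ in range(25)
        )
        assert hits >= 24

    def test_length_confounded_shift_attributed_to_covariate(self):
        rng = np.random.default_rng(3)
        res = compartment_ancova(_gene_table(rng, n=4000, confound=True),
                                 value="value")
        assert abs(res.effect) < 0.1 and res.p > 0.01

    def test_single_group_rejected(self):
        rng = np.random.default_rng(4)
        table = _gene_table(rng, n=50)
        table["group"] = "A"
        with pytest.raises(ValueError):
            compartment_ancova(table, value="value")


class TestBootstrapMedian:
    def test_constant_vector_zero_width(self):
        med, lo, hi = bootstrap_median_ci([5.0] * 10, reps=200, seed=0)
        assert med == lo == hi == 5.0

    def test_interval_contains_median(self):
        med, lo, hi = bootstrap_median_ci(np.arange(1, 1002), reps=2000, seed=1)
        assert med == 501
        assert lo <= 501 <= hi

    def test_reproducible_under_seed(self):
        v = np.random.default_rng(7).normal(0, 1, 200)
        assert bootstrap_median_ci(v, reps=500, seed=3) == bootstrap_median_ci(
            v, reps=500, seed=3)

    def test_coverage_near_nominal(self):
        """Across repeated normal samples the 95% interval covers the true
        median at close to the nominal rate."""
        rng = np.random.default_rng(5)
        cover = 0
        outer = 150
        for _ in range(outer):
            v = rng.normal(0, 1, 100)
            _, lo, hi = bootstrap_median_ci(v, reps=600, seed=int(rng.integers(2**31)))
            cover += lo <= 0.0 <= hi
        assert 0.88 <= cover / outer <= 1.0
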