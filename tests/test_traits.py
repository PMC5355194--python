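import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from reefshift.traits import (
    akaike_weights,
    all_subsets_averaging,
    graft_missing_tips,
    pgls_fit,
    phylo_covariance,
    quantile_slopes,
    trait_design,
    validate_trait_table,
)


def make_traits(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "size_cm": np.exp(rng.uniform(np.log(4), np.log(200), n)),
            "mobility": rng.choice(
                ["sedentary", "mobile_within_reef", "mobile_between_reefs"], n
            ),
            "habitat_specialization": rng.choice(
                ["coral_specialized", "other_specialized", "not_specialized"], n
            ),
        },
        index=[f"sp{i}" for i in range(n)],
    )


class TestAkaikeWeights:
    def test_equal_aic_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-3)
        assert w[1] == pytest.approx(0.2689, abs=1e-3)

    def test_sum_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(1)
        aics = rng.uniform(100, 120, 8)
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, akaike_weights(aics + 57.3), atol=1e-12)

    def test_duplicate_model_halves_weights(self):
        base = np.array([0.0, 3.0])
        w2 = akaike_weights(base)
        w3 = akaike_weights(np.array([0.0, 0.0, 3.0]))
        assert w3[0] == pytest.approx(w2[0] / (1 + w2[0]))


class TestAllSubsets:
    def test_weights_sum_and_importance_range(self):
        traits = make_traits(120)
        rng = np.random.default_rng(2)
        y = pd.Series(
            -0.002 * traits["size_cm"] + rng.normal(0, 0.05, 120), index=traits.index
        )
        ms = all_subsets_averaging(y, traits)
        assert len(ms.table) == 8
        assert ms.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ((ms.importance >= 0) & (ms.importance <= 1)).all()
        # a strong size effect should dominate the candidate set
        assert ms.importance["size"] > 0.95
        assert ms.averaged.loc["size", "estimate"] < 0

    def test_reference_levels_give_table_rows(self):
        traits = make_traits(80)
        y = pd.Series(np.random.default_rng(3).normal(size=80), index=traits.index)
        ms = all_subsets_averaging(y, traits)
        for name in ("mobility_sedentary", "mobility_very_mobile",
                     "specialization_not", "specialization_other"):
            assert name in ms.averaged.index

    def test_size_transform_option(self):
        traits = make_traits(60)
        design = trait_design(traits, size_transform="log10")
        np.testing.assert_allclose(design["size"], np.log10(traits["size_cm"]))
        with pytest.raises(ValueError):
            trait_design(traits, size_transform="sqrt")

    def test_category_validation(self):
        traits = make_traits(30)
        traits.loc["sp0", "mobility"] = "teleporting"
        with pytest.raises(ValueError, match="mobility"):
            validate_trait_table(traits)


class TestGrafting:
    @staticmethod
    def cherry_tree():
        return dendropy.Tree.get(data="((A_one:10,A_two:10):5,B_one:15);", schema="newick",
                                  preserve_underscores=True)

    def test_existing_species_is_noop(self):
        tree = self.cherry_tree()
        before = tree.as_string(schema="newick")
        out, unplaced = graft_missing_tips(tree, ["A_one"], seed=0)
        assert unplaced == []
        assert out.as_string(schema="newick") == before

    def test_midpoint_cherry_arithmetic(self):
        tree = dendropy.Tree.get(data="(A_one:10,B_one:10);", schema="newick",
                                 preserve_underscores=True)
        out, _ = graft_missing_tips(tree, ["A_new"], seed=0)
        leaf = next(l for l in out.leaf_node_iter() if l.taxon.label == "A_new")
        host = next(l for l in out.leaf_node_iter() if l.taxon.label == "A_one")
        assert leaf.edge.length == pytest.approx(5.0)
        assert host.edge.length == pytest.approx(5.0)
        assert leaf.parent_node.edge.length == pytest.approx(5.0)
        # ultrametricity preserved
        depths = [l.distance_from_root() for l in out.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_seeded_determinism(self):
        tree = self.cherry_tree()
        a, _ = graft_missing_tips(tree, ["A_x", "A_y"], seed=3)
        b, _ = graft_missing_tips(tree, ["A_x", "A_y"], seed=3)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_unplaceable_species_listed(self):
        tree = self.cherry_tree()
        out, unplaced = graft_missing_tips(tree, ["Zeta_sp"], seed=0)
        assert unplaced == ["Zeta_sp"]
        assert all(l.taxon.label != "Zeta_sp" for l in out.leaf_node_iter())


class TestPgls:
    @staticmethod
    def balanced_tree(n=16, depth=4.0):
        import random

        from dendropy.simulate import treesim

        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=random.Random(9), repeat_until_success=True,
        )
        for i, l in enumerate(tree.leaf_node_iter()):
            l.taxon.label = f"t{i}"
        return tree

    def test_lambda_zero_equals_ols(self):
        tree = self.balanced_tree()
        rng = np.random.default_rng(4)
        sp = [f"t{i}" for i in range(16)]
        y = pd.Series(rng.normal(size=16), index=sp)
        X = pd.DataFrame({"x": rng.normal(size=16)}, index=sp)
        res = pgls_fit(y, X, tree, lam=0.0)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params, atol=1e-8)

    def test_star_phylogeny_equals_ols(self):
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(12)])
        tree = dendropy.Tree(taxon_namespace=taxa)
        for t in taxa:
            tree.seed_node.new_child(taxon=t, edge_length=1.0)
        rng = np.random.default_rng(5)
        sp = [t.label for t in taxa]
        y = pd.Series(rng.normal(size=12), index=sp)
        X = pd.DataFrame({"x": rng.normal(size=12)}, index=sp)
        res = pgls_fit(y, X, tree)  # ML lambda; off-diagonal covariance is 0
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params, atol=1e-6)

    def test_brownian_data_high_lambda(self):
        import random

        from dendropy.simulate import treesim

        lams = []
        for rep in range(5):
            tree = treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.2, num_extant_tips=48,
                rng=random.Random(100 + rep), repeat_until_success=True,
            )
            for i, l in enumerate(tree.leaf_node_iter()):
                l.taxon.label = f"t{i}"
            sp = [f"t{i}" for i in range(48)]
            C = phylo_covariance(tree, sp)
            rng = np.random.default_rng(rep)
            y = pd.Series(rng.multivariate_normal(np.zeros(48), C), index=sp)
            X = pd.DataFrame({"x": rng.normal(size=48)}, index=sp)
            lams.append(pgls_fit(y, X, tree).lam)
        assert np.mean(lams) >= 0.8

    def test_non_ultrametric_rejected(self):
        tree = dendropy.Tree.get(data="(t0:1,t1:9);", schema="newick")
        y = pd.Series([0.0, 1.0], index=["t0", "t1"])
        X = pd.DataFrame({"x": [0.0, 1.0]}, index=["t0", "t1"])
        with pytest.raises(ValueError, match="ultrametric"):
            pgls_fit(y, X, tree)


class TestQuantileSlopes:
    def test_exact_line_recovered_at_all_quantiles(self):
        x = pd.Series(np.linspace(5, 100, 40), index=[f"s{i}" for i in range(40)])
        y = 0.5 - 0.003 * x
        qs = quantile_slopes(y, x)
        for q in (0.75, 0.9):
            assert qs.loc[q, "slope"] == pytest.approx(-0.003, abs=1e-8)

    def test_triangular_cloud_upper_quantile_steeper_than_mean(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.uniform(5, 100, n)
        envelope = 0.4 * (1 - x / 110)
        y = envelope * rng.uniform(0, 1, n)  # floor at 0, declining ceiling
        xs = pd.Series(x, index=[f"s{i}" for i in range(n)])
        ys = pd.Series(y, index=xs.index)
        qs = quantile_slopes(ys, xs)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert qs.loc[0.9, "slope"] < 0
        assert ols.params[1] < 0
        assert qs.loc[0.9, "slope"] < ols.params[1]  # envelope steeper than mean

    def test_degenerate_inputs(self):
        x = pd.Series(np.ones(25), index=[f"s{i}" for i in range(25)])
        y = pd.Series(np.linspace(0, 1, 25), index=x.index)
        with pytest.raises(ValueError, match="size variance"):
            quantile_slopes(y, x)
        with pytest.raises(ValueError, match="at least 20"):
            quantile_slopes(y.iloc[:5], pd.Series(np.arange(5.0), index=y.index[:5]))
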