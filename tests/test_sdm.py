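import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from reefshift.sdm import (
    auc_repeated_split,
    auc_score,
    filter_species,
    fit_glm_logit,
    fit_predictor_sets,
    morans_i,
    partition_deviance,
    quadratic_design,
    standardize,
)


def occ_matrix(rows):
    return pd.DataFrame(rows, index=[f"sp{i}" for i in range(len(rows))])


class TestFilterSpecies:
    def test_presence_floor(self):
        rows = [[1] * 9 + [0] * 91, [1] * 10 + [0] * 90]
        kept, removed = filter_species(occ_matrix(rows))
        assert list(kept.index) == ["sp1"]  # 10 presences is retained, 9 is not
        assert removed.iloc[0]["reason"] == "too_few_presences"

    def test_ubiquitous_species_removed(self):
        rows = [[1] * 100, [1] * 50 + [0] * 50]
        kept, removed = filter_species(occ_matrix(rows))
        assert "sp0" not in kept.index
        assert removed.iloc[0]["reason"] == "too_few_absences"

    def test_empty_result_errors_with_counts(self):
        with pytest.raises(ValueError, match="presence-poor"):
            filter_species(occ_matrix([[1, 0, 0, 0]]))


class TestFitGlmLogit:
    def test_null_truth_gives_small_d2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=4000)})
        y = rng.integers(0, 2, 4000)
        fit = fit_glm_logit(y, X)
        assert fit.converged
        assert fit.d2 == pytest.approx(0.0, abs=0.01)
        assert abs(fit.params["x"]) < 0.1

    def test_known_coefficients_recovered_within_3se(self):
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.normal(size=n)
        true = {"const": -0.3, "x": 0.8, "x^2": -0.4}
        eta = true["const"] + true["x"] * x + true["x^2"] * x**2
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_glm_logit(y, pd.DataFrame({"x": x}))
        assert fit.converged
        # x was drawn standard normal so the z-scored design is ~ the raw one
        for name in ("x", "x^2"):
            assert abs(fit.params[name] - true[name]) < 3 * fit.bse[name]
        # cross-check the optimizer against an independent implementation
        from sklearn.linear_model import LogisticRegression

        design = quadratic_design(pd.DataFrame({"x": x}))
        skl = LogisticRegression(C=1e8, tol=1e-10, max_iter=1000).fit(design, y)
        np.testing.assert_allclose(
            fit.params[["x", "x^2"]].to_numpy(), skl.coef_.ravel(), atol=2e-3
        )

    def test_intercept_only_d2_is_zero(self):
        y = np.array([0, 1, 1, 0, 1], dtype=float)
        fit = fit_glm_logit(y, pd.DataFrame(index=range(5)))
        assert fit.d2 == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_glm_logit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_separation_flagged(self):
        x = np.arange(20, dtype=float)
        y = (x >= 10).astype(float)
        fit = fit_glm_logit(y, pd.DataFrame({"x": x}))
        assert not fit.converged

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant predictor"):
            standardize(pd.DataFrame({"x": np.ones(5)}))


class TestPartition:
    def test_arithmetic_identities(self):
        # D2_full=.53, D2_contemp=.48, D2_hist=.14 -> a=.39, b=.09, c=.05, d=.47
        def fake(d2, label):
            from reefshift.sdm import SdmFit

            return SdmFit(
                species_id="s", predictor_set=label, params=pd.Series(dtype=float),
                bse=pd.Series(dtype=float), residual_deviance=(1 - d2) * 100.0,
                null_deviance=100.0, d2=d2, converged=True,
            )

        fits = {"full": fake(0.53, "full"), "contemporary": fake(0.48, "contemporary"),
                "historical": fake(0.14, "historical")}
        part = partition_deviance(fits)
        assert part.pure_contemporary == pytest.approx(0.39)
        assert part.shared == pytest.approx(0.09)
        assert part.pure_historical == pytest.approx(0.05)
        assert part.unexplained == pytest.approx(0.47)
        assert sum(part.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_predictors_zero_shared_linear_gaussian_oracle(self):
        # In OLS with exactly orthogonal predictor blocks the shared
        # fraction vanishes; mirror the GLM partition identities on R^2.
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exact orthogonalization (centered)
        y = 1.0 * x1 + 0.5 * x2 + rng.normal(size=n)

        def r2(*cols):
            X = sm.add_constant(np.column_stack(cols))
            return sm.OLS(y, X).fit().rsquared

        shared = r2(x1) + r2(x2) - r2(x1, x2)
        assert shared == pytest.approx(0.0, abs=1e-10)

    def test_identical_data_required(self, small_world):
        from reefshift.sdm import ALL_PREDICTORS

        pred = small_world.predictors[list(ALL_PREDICTORS)]
        y = small_world.occurrences.iloc[0].to_numpy(float)
        fits = fit_predictor_sets(y, pred)
        y2 = small_world.occurrences.iloc[1].to_numpy(float)
        fits["contemporary"] = fit_predictor_sets(y2, pred)["contemporary"]
        if abs(fits["contemporary"].null_deviance - fits["full"].null_deviance) > 1e-4:
            with pytest.raises(ValueError, match="identical data"):
                partition_deviance(fits)


class TestAuc:
    def test_hand_example(self):
        # presences {0.9, 0.4}, absences {0.6, 0.1}: 3 of 4 pairs concordant
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.1])
        assert auc_score(y, s) == pytest.approx(0.75)

    def test_ties_give_half(self):
        y = np.array([1, 0, 1, 0])
        assert auc_score(y, np.ones(4)) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)
        assert auc_score(y, s) == pytest.approx(auc_score(y, np.exp(3 * s)))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.normal(size=200) + y
        assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_separable_species_scores_one(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-3, 0.3, 40), rng.normal(3, 0.3, 40)])
        y = (x > 0).astype(float)
        # train scores separate perfectly, so every test split ranks perfectly
        mean, sd = auc_repeated_split(y, pd.DataFrame({"x": x}), n_repeats=10, seed=0)
        assert mean == pytest.approx(1.0)

    def test_stratification_guard(self):
        y = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError, match="stratify"):
            auc_repeated_split(y, pd.DataFrame({"x": np.arange(4.0)}), n_repeats=2, seed=0)


class TestMoransI:
    @staticmethod
    def grid_coords(n):
        rows, cols = np.meshgrid(range(n), range(n), indexing="ij")
        return pd.DataFrame({"lon": cols.ravel().astype(float), "lat": -rows.ravel().astype(float)})

    def test_checkerboard_negative(self):
        n = 4
        coords = self.grid_coords(n)
        rows, cols = np.meshgrid(range(n), range(n), indexing="ij")
        z = ((rows + cols) % 2).ravel().astype(float)
        i_stat, expected = morans_i(z, coords, cellsize=1.0)
        assert i_stat < expected  # strong negative autocorrelation

    def test_two_block_field_positive(self):
        n = 4
        coords = self.grid_coords(n)
        z = np.repeat([0.0, 1.0], n * n // 2)
        i_stat, _ = morans_i(z, coords, cellsize=1.0)
        assert i_stat > 0.3

    def test_permutation_null_expectation(self):
        rng = np.random.default_rng(6)
        n = 6
        coords = self.grid_coords(n)
        base = rng.normal(size=n * n)
        stats = [morans_i(rng.permutation(base), coords, cellsize=1.0)[0] for _ in range(300)]
        assert np.mean(stats) == pytest.approx(-1.0 / (n * n - 1), abs=0.01)

    def test_guards(self):
        coords = self.grid_coords(2)
        with pytest.raises(ValueError, match="zero-variance"):
            morans_i(np.ones(4), coords, cellsize=1.0)
        with pytest.raises(ValueError, match="at least 3"):
            morans_i(np.array([1.0, 2.0]), coords.iloc[:2], cellsize=1.0)


class TestNestingInvariant:
    def test_full_model_dominates_on_synthetic_species(self, small_sdm_results):
        res = small_sdm_results
        assert len(res) >= 40
        assert np.all(
            res["d2_full"] + 1e-9 >= res[["d2_contemporary", "d2_historical"]].max(axis=1)
        )

    def test_partition_closure(self, small_sdm_results):
        total = small_sdm_results[
            ["pure_contemporary", "shared", "pure_historical", "unexplained"]
        ].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
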