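import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridspread.inference import (
    ModelSpec,
    TermSpec,
    aic_backward,
    collinearity_screen,
    ols_fit,
    partial_residuals,
    spearman,
    variance_partition,
    vif,
)
from oracles import spearman_rank_pearson


def random_table(seed, n=120, k=5, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{j}" for j in range(k)]
    table = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)
    return table, rng


class TestSpearman:
    def test_monotone_pairs_give_unit_correlation(self):
        x = np.array([1.0, 2.5, 4.0, 9.0])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = rng.integers(0, 4, 30).astype(float)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))

    @given(st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y)[0]
        assert spearman(np.exp(x), y)[0] == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3)[0] == pytest.approx(base, abs=1e-12)


class TestVariancePartition:
    def test_single_group_partition_is_marginal_r2(self):
        table, rng = random_table(1, k=2, names=["a", "b"])
        y = table["a"] * 2 + rng.normal(size=len(table))
        part = variance_partition(y.to_numpy(), {"G": ["a", "b"]}, table)
        fit = ols_fit(
            table.assign(y=y), ModelSpec(response="y", terms=(TermSpec("a"), TermSpec("b")))
        )
        assert part.unique["G"] == pytest.approx(part.full_r2)
        assert part.full_r2 == pytest.approx(fit.r2, abs=1e-10)

    def test_orthogonal_groups_share_nothing(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(200, 2))
        q, _ = np.linalg.qr(np.column_stack([np.ones(200), raw]))
        table = pd.DataFrame({"a": q[:, 1], "b": q[:, 2]})
        y = 1.5 * table["a"] - 0.8 * table["b"] + 0.0
        part = variance_partition(y.to_numpy(), {"A": ["a"], "B": ["b"]}, table)
        marg_a = part.subset_r2[frozenset({"A"})]
        marg_b = part.subset_r2[frozenset({"B"})]
        assert part.unique["A"] == pytest.approx(marg_a, abs=1e-10)
        assert part.unique["B"] == pytest.approx(marg_b, abs=1e-10)
        assert part.shared == pytest.approx(0.0, abs=1e-10)

    def test_components_sum_to_full_r2(self):
        table, rng = random_table(3, k=4, names=["a", "b", "c", "d"])
        y = table.sum(axis=1) + rng.normal(size=len(table))
        part = variance_partition(
            y.to_numpy(), {"G1": ["a", "b"], "G2": ["c"], "G3": ["d"]}, table
        )
        assert sum(part.unique.values()) + part.shared == pytest.approx(part.full_r2)


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(4)
        # columns orthogonal to each other and to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(100), rng.normal(size=(100, 4))]))
        table = pd.DataFrame(q[:, 1:], columns=list("abcd"))
        v = vif(table, list("abcd"))
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_is_infinite(self):
        table, _ = random_table(5, k=2, names=["a", "b"])
        table["dup"] = table["a"]
        v = vif(table, ["a", "b", "dup"])
        assert np.isinf(v["a"]) and np.isinf(v["dup"])

    def test_matches_bruteforce_per_column_regressions(self):
        table, _ = random_table(6, k=5)
        terms = list(table.columns)
        v = vif(table, terms)
        X = table.to_numpy()
        for j, name in enumerate(terms):
            others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert v[name] == pytest.approx(1 / (1 - r2), abs=1e-9)


class TestCollinearityScreen:
    def test_orthogonal_table_keeps_everything(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(150, 4)))
        table = pd.DataFrame(q, columns=list("abcd"))
        res = collinearity_screen(table, list("abcd"))
        assert res.retained == list("abcd") and not res.dropped

    def test_planted_near_duplicate_is_removed(self):
        table, rng = random_table(8, k=3, names=["a", "b", "c"])
        table["a_twin"] = table["a"] + rng.normal(0, 0.01, len(table))
        res = collinearity_screen(table, ["a", "b", "c", "a_twin"])
        dropped_names = {d["term"] for d in res.dropped}
        assert dropped_names & {"a", "a_twin"}
        kept = set(res.retained)
        assert ("a" in kept) != ("a_twin" in kept)
        # re-screen of the retained set is clean
        again = collinearity_screen(table, res.retained)
        assert not again.dropped

    def test_drop_records_carry_statistics(self):
        table, _ = random_table(9, k=2, names=["a", "b"])
        table["dup"] = table["a"] * 2.0
        res = collinearity_screen(table, ["a", "b", "dup"])
        drop = res.dropped[0]
        assert drop["reason"] == "pairwise_r"
        assert drop["statistic"] > 0.99


class TestOLSFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 50)
        table = pd.DataFrame({"x": x, "y": 3 + 2 * x})
        fit = ols_fit(table, ModelSpec(response="y", terms=(TermSpec("x"),)))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.raw_params["x"] == pytest.approx(2.0, abs=1e-10)
        # standardized slope = raw slope * SD(x); back-scaling identity
        assert fit.params["x"] == pytest.approx(2.0 * x.std(ddof=0), abs=1e-10)
        np.testing.assert_allclose(fit.fitted + fit.residuals, table["y"], atol=1e-10)

    def test_matches_normal_equations_with_many_predictors(self):
        rng = np.random.default_rng(10)
        names = [f"v{j}" for j in range(12)]
        table = pd.DataFrame(rng.normal(size=(300, 12)), columns=names)
        table["y"] = rng.normal(size=300)
        fit = ols_fit(
            table, ModelSpec(response="y", terms=tuple(TermSpec(n) for n in names))
        )
        Z = fit.design.to_numpy()
        D = np.column_stack([np.ones(len(Z)), Z])
        beta = np.linalg.solve(D.T @ D, D.T @ table["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_polynomial_column_built_from_centred_base(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"x": rng.normal(2.0, 1.0, 200)})
        table["y"] = table["x"] ** 2 + rng.normal(size=200)
        fit = ols_fit(
            table, ModelSpec(response="y", terms=(TermSpec("x", degree=2),))
        )
        assert list(fit.design.columns) == ["x", "x^2"]
        x = table["x"].to_numpy()
        centred_sq = (x - x.mean()) ** 2
        expected = (centred_sq - centred_sq.mean()) / centred_sq.std(ddof=0)
        np.testing.assert_allclose(fit.design["x^2"].to_numpy(), expected, atol=1e-12)

    def test_singular_design_names_offender(self):
        table, rng = random_table(12, k=2, names=["a", "b"])
        table["c"] = table["a"] * 2.0  # identical to a after z-scoring
        table["y"] = table["a"] + rng.normal(size=len(table))
        with pytest.raises(ValueError, match="offending columns: \\['c'\\]"):
            ols_fit(
                table,
                ModelSpec(response="y", terms=(TermSpec("a"), TermSpec("b"), TermSpec("c"))),
            )

    def test_missing_rows_excluded_complete_case(self):
        table = pd.DataFrame(
            {"x": [1.0, 2, 3, np.nan, 5, 6, 7], "y": [2.0, 4, 6, 8, np.nan, 12, 14]}
        )
        fit = ols_fit(table, ModelSpec(response="y", terms=(TermSpec("x"),)))
        assert fit.n == 5

    def test_unit_rescaling_leaves_standardized_fit_unchanged(self):
        table, rng = random_table(13, k=3, names=["a", "b", "c"])
        table["y"] = table["a"] - table["b"] + rng.normal(size=len(table))
        spec = ModelSpec(
            response="y", terms=(TermSpec("a"), TermSpec("b"), TermSpec("c", degree=2))
        )
        base = ols_fit(table, spec)
        scaled = table.assign(a=table["a"] * 1000.0, c=table["c"] / 37.0)
        other = ols_fit(scaled, spec)
        np.testing.assert_allclose(base.params, other.params, atol=1e-9)
        np.testing.assert_allclose(base.pvalues, other.pvalues, atol=1e-9)
        assert base.r2 == pytest.approx(other.r2, abs=1e-9)
        assert base.aic == pytest.approx(other.aic, abs=1e-9)


class TestBackwardAIC:
    def test_noiseless_full_signal_keeps_all_terms(self):
        table, _ = random_table(14, k=3, names=["a", "b", "c"])
        table["y"] = table["a"] + table["b"] + table["c"]
        spec = ModelSpec(
            response="y", terms=(TermSpec("a"), TermSpec("b"), TermSpec("c"))
        )
        fit = aic_backward(table, spec)
        assert set(fit.term_names) == {"a", "b", "c"}

    def test_matches_exhaustive_search_for_small_models(self):
        """Greedy backward selection reaches the AIC-best model among all
        backward-reachable subsets for a 5-term fixture."""
        rng = np.random.default_rng(15)
        names = list("abcde")
        table = pd.DataFrame(rng.normal(size=(150, 5)), columns=names)
        table["y"] = (
            1.2 * table["a"] - 0.9 * table["b"] + rng.normal(size=150)
        )
        spec = ModelSpec(response="y", terms=tuple(TermSpec(n) for n in names))
        fit = aic_backward(table, spec)
        from itertools import combinations

        best_aic, best_terms = np.inf, None
        for r in range(1, 6):
            for combo in combinations(names, r):
                cand = ols_fit(
                    table, ModelSpec(response="y", terms=tuple(TermSpec(n) for n in combo))
                )
                if cand.aic < best_aic:
                    best_aic, best_terms = cand.aic, set(combo)
        assert set(fit.term_names) == best_terms
        assert fit.aic == pytest.approx(best_aic)

    def test_square_leaves_before_its_base(self):
        """Dropping a degree-2 term removes its square first, and the
        base column survives anywhere the square is present."""
        spec = ModelSpec(
            response="y", terms=(TermSpec("x", degree=2), TermSpec("z"))
        )
        reduced = spec.drop("x")
        assert [(t.name, t.degree) for t in reduced.terms] == [("x", 1), ("z", 1)]
        assert [(t.name, t.degree) for t in reduced.drop("x").terms] == [("z", 1)]

        rng = np.random.default_rng(16)
        table = pd.DataFrame({"x": rng.normal(size=200), "z": rng.normal(size=200)})
        table["y"] = 2.0 * table["x"] + rng.normal(size=200)  # linear only
        fit = aic_backward(table, spec)
        assert "x" in fit.term_names
        for terms, _ in fit.selection_path:
            assert "x" in terms  # base present in every visited model


class TestPartialResiduals:
    def test_single_predictor_noiseless_collinear_with_term(self):
        x = np.linspace(-3, 3, 40)
        table = pd.DataFrame({"x": x, "y": 1 + 4 * x})
        fit = ols_fit(table, ModelSpec(response="y", terms=(TermSpec("x"),)))
        pr = partial_residuals(fit, "x")
        r = np.corrcoef(pr, fit.design["x"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_slope_against_term_equals_coefficient(self):
        table, rng = random_table(17, k=3, names=["a", "b", "c"])
        table["y"] = table["a"] * 2 - table["c"] + rng.normal(size=len(table))
        fit = ols_fit(
            table,
            ModelSpec(response="y", terms=(TermSpec("a"), TermSpec("b"), TermSpec("c"))),
        )
        for term in ["a", "b", "c"]:
            pr = partial_residuals(fit, term)
            z = fit.design[term].to_numpy()
            slope = (z @ pr) / (z @ z)
            assert slope == pytest.approx(fit.params[term], abs=1e-10)

    def test_unknown_term_rejected(self):
        table, rng = random_table(18, k=2, names=["a", "b"])
        table["y"] = table["a"] + rng.normal(size=len(table))
        fit = ols_fit(table, ModelSpec(response="y", terms=(TermSpec("a"),)))
        with pytest.raises(KeyError):
            partial_residuals(fit, "b")
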