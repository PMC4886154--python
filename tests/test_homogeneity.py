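"""Homogeneity (Gifi/MCA) analysis, item selection and reliability statistics."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from twingxe.homogeneity import (build_indicator,
                                 category_points, cronbach_alpha,
                                 fit_homogeneity, guttman_lambda2,
                                 loading_missing_regression, reliability_stats,
                                 select_items)
from twingxe.params import PAPER_SELECTED_ITEMS, ItemParams
from twingxe.simulate import _sample_items


def _frame(y):
    return pd.DataFrame(np.asarray(y, dtype=float),
                        columns=[f"item_{j+1}" for j in range(np.shape(y)[1])])


class TestIndicator:
    def test_basic_construction(self):
        df = _frame([[0, 1], [1, 2], [2, 0], [1, 1]])
        ind = build_indicator(df)
        assert ind.matrix.shape == (4, 6)
        assert np.all(ind.matrix.sum(axis=1) == 2)       # row sums = k
        # each item block has exactly one 1 per row
        assert np.all(ind.matrix[:, :3].sum(axis=1) == 1)

    def test_missing_rows_dropped_and_counted(self):
        df = _frame([[0, 1], [1, np.nan], [2, 0], [1, 1]])
        ind = build_indicator(df)
        assert ind.matrix.shape[0] == 3
        assert ind.n_dropped_rows == 1
        assert ind.matrix.shape[0] + ind.n_dropped_rows == 4

    def test_column_sums_match_tabulation_oracle(self, rng):
        y = rng.integers(0, 3, size=(50, 4))
        ind = build_indicator(_frame(y))
        for j in range(4):
            counts = np.bincount(y[:, j], minlength=3)
            assert np.array_equal(ind.matrix[:, 3 * j:3 * j + 3].sum(axis=0),
                                  counts)

    def test_degenerate_item_dropped_with_warning(self):
        y = np.column_stack([np.zeros(10), np.arange(10) % 3])
        with pytest.warns(UserWarning, match="single observed category"):
            ind = build_indicator(_frame(y))
        assert ind.n_items == 1
        assert ind.dropped_items == ["item_1"]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            build_indicator(_frame([[0, 1]]))


class TestHomogeneityFit:
    def test_identical_items_share_loading_and_group_objects(self, rng):
        x = rng.integers(0, 3, size=200)
        df = _frame(np.column_stack([x, x]))
        sol = fit_homogeneity(build_indicator(df), ndim=2)
        assert sol.loadings_[0, 0] == pytest.approx(sol.loadings_[1, 0], abs=1e-8)
        assert sol.loadings_[0, 1] == pytest.approx(sol.loadings_[1, 1], abs=1e-8)
        # individuals sharing the response land on the same object score
        for c in range(3):
            grp = sol.object_scores_[x == c]
            assert np.allclose(grp, grp[0], atol=1e-8)
        # dimension-1 scores coincide with the item's own quantification
        q = sol.quantifications_["item_1"][x, 0]
        rho = abs(np.corrcoef(sol.object_scores_[:, 0], q)[0, 1])
        assert rho == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_match_burt_matrix_oracle(self, rng):
        # stationary eigenvalues equal those of (1/k) D^-1/2 Gc' Gc D^-1/2
        y = rng.integers(0, 3, size=(120, 2))
        ind = build_indicator(_frame(y))
        sol = fit_homogeneity(ind, ndim=2, tol=1e-12)
        G = ind.matrix
        n, k = G.shape[0], 2
        Gc = G - G.mean(axis=0)
        d = G.sum(axis=0)
        M = (Gc.T @ Gc) / np.sqrt(np.outer(d, d)) / k
        eig = np.sort(np.linalg.eigvalsh(M))[::-1]
        assert np.allclose(sol.eigenvalues_, eig[:2], atol=1e-6)

    def test_loss_nonincreasing_and_eigenvalues_sorted(self, rng):
        y = rng.integers(0, 3, size=(300, 6))
        sol = fit_homogeneity(build_indicator(_frame(y)), ndim=3)
        loss = np.array(sol.loss_trace_)
        assert np.all(np.diff(loss) <= 1e-9)
        ev = sol.eigenvalues_
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12)

    def test_object_scores_centered_unit_variance(self, rng):
        y = rng.integers(0, 3, size=(250, 5))
        sol = fit_homogeneity(build_indicator(_frame(y)), ndim=2)
        X = sol.object_scores_
        assert np.allclose(X.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(X.var(axis=0), 1.0, atol=1e-6)

    def test_dimension1_recovers_generating_trait(self):
        # unidimensional ordinal generative model: object scores on the
        # leading dimension track the latent trait
        rng = np.random.default_rng(2024)
        theta = rng.normal(0, 1, 5000)
        items = tuple(ItemParams(1.5, -0.6, 0.6) for _ in range(9))
        y = _sample_items(theta, items, rng)
        sol = fit_homogeneity(build_indicator(_frame(y)), ndim=2)
        r = abs(np.corrcoef(sol.object_scores_[:, 0], theta)[0, 1])
        assert r >= 0.9


class TestCategoryPoints:
    def test_ordinal_item_from_monotone_construction(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 1, 3000)
        items = tuple(ItemParams(1.5, -0.5, 0.5) for _ in range(5))
        y = _sample_items(theta, items, rng)
        sol = fit_homogeneity(build_indicator(_frame(y)), ndim=2)
        pts, is_ordinal = category_points(sol, "item_1", ordinal_dim=0)
        assert pts.shape == (3, 2)
        assert is_ordinal

    def test_question_mark_outside_segment_flagged(self):
        sol = SimpleNamespace(
            indicator_=SimpleNamespace(items=["item_1"]),
            quantifications_={"item_1": np.array([[-1.0, 0.0],
                                                  [2.0, 0.0],
                                                  [1.0, 0.0]])})
        _, is_ordinal = category_points(sol, "item_1", ordinal_dim=0)
        assert not is_ordinal

    def test_unknown_item(self, rng):
        y = rng.integers(0, 3, size=(50, 2))
        sol = fit_homogeneity(build_indicator(_frame(y)), ndim=1)
        with pytest.raises(KeyError):
            category_points(sol, "item_99")


class TestSelectItems:
    def test_strict_absolute_rule(self):
        loadings = np.array([[0.2, 0.5],    # keep
                             [0.5, 0.2],    # drop
                             [0.3, 0.3],    # tie -> drop
                             [0.1, -0.4]])  # negative loading kept by |.|
        kept = select_items(loadings, dim_keep=1, dim_drop=0)
        assert kept.tolist() == [0, 3]

    def test_published_selection_constant(self):
        assert len(PAPER_SELECTED_ITEMS) == 9
        assert "Gay rights" in PAPER_SELECTED_ITEMS
        assert "School prayer (reverse-coded)" in PAPER_SELECTED_ITEMS

    def test_requires_two_dimensions(self):
        with pytest.raises(ValueError):
            select_items(np.array([[0.3], [0.4]]))


class TestReliability:
    def test_perfectly_correlated_items(self):
        x = np.tile(np.array([0, 1, 2, 1, 0, 2.0]), (2, 1)).T
        rep = reliability_stats(_frame(x))
        assert rep.cronbach_alpha == pytest.approx(1.0)
        assert rep.guttman_lambda2 == pytest.approx(1.0)

    def test_alpha_closed_form(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert cronbach_alpha(cov) == pytest.approx(2 / 3)

    def test_lambda2_at_least_alpha_on_random_covariances(self, rng):
        for _ in range(100):
            k = rng.integers(2, 8)
            a = rng.normal(size=(k, k + 2))
            cov = a @ a.T + 1e-6 * np.eye(k)
            assert guttman_lambda2(cov) >= cronbach_alpha(cov) - 1e-12

    def test_item_total_range_and_rest_score(self, rng):
        y = rng.integers(0, 3, size=(200, 5))
        rep = reliability_stats(_frame(y))
        assert np.all(np.abs(rep.item_total) <= 1)
        rest = reliability_stats(_frame(y), rest_score=True)
        assert rest.rest_score and not rep.rest_score

    def test_reverse_items_applied(self, rng):
        theta = rng.normal(0, 1, 800)
        items = tuple(ItemParams(1.5, -0.3, 0.3) for _ in range(4))
        y = _sample_items(theta, items, rng).astype(float)
        y[:, 0] = 2 - y[:, 0]  # miskeyed item
        low = reliability_stats(_frame(y)).cronbach_alpha
        fixed = reliability_stats(_frame(y), reverse_items=[0]).cronbach_alpha
        assert fixed > low


class TestLoadingMissingRegression:
    def test_exact_linear_relationship(self):
        x = np.linspace(0.05, 0.5, 10)
        load = 0.2 + 1.5 * x
        res = loading_missing_regression(load, x)
        assert res.loc[0, "r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert res.loc[0, "p"] < 1e-10
        assert res.loc[0, "df"] == 8

    def test_matches_closed_form_ols_oracle(self, rng):
        from scipy import stats as sps

        for _ in range(10):
            k = int(rng.integers(5, 30))
            x = rng.uniform(0, 1, k)
            yv = rng.normal(0, 1, k)
            res = loading_missing_regression(yv, x)
            # textbook OLS: slope, t with k-2 df
            xc = x - x.mean()
            slope = (xc * (yv - yv.mean())).sum() / (xc ** 2).sum()
            resid = yv - yv.mean() - slope * xc
            se = np.sqrt(resid @ resid / (k - 2) / (xc ** 2).sum())
            t = slope / se
            p = 2 * sps.t.sf(abs(t), k - 2)
            assert res.loc[0, "slope"] == pytest.approx(slope, rel=1e-8)
            assert res.loc[0, "t"] == pytest.approx(t, rel=1e-8)
            assert res.loc[0, "p"] == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            loading_missing_regression(np.arange(5.0), np.full(5, 0.3))

    def test_permuted_predictor_null_behaviour(self, rng):
        x = rng.uniform(0, 1, 20)
        yv = 2 * x + rng.normal(0, 0.01, 20)
        slopes = []
        for _ in range(200):
            slopes.append(loading_missing_regression(
                yv, rng.permutation(x)).loc[0, "slope"])
        assert abs(np.mean(slopes)) < 0.2
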