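import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import phylogrid as pg
from phylogrid.core import GridCell
from phylogrid.drivers import SpatialWeights


def grid_cells(nr, nc):
    return [GridCell(f"c{r}_{c}", r, c) for r in range(nr) for c in range(nc)]


class TestCollinearityScreen:
    def test_perfect_pair_flagged_and_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        env = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)})
        kept, flagged = pg.collinearity_screen(env)
        assert [(p[0], p[1]) for p in flagged] == [("a", "b")]
        assert kept == ["a", "c"]  # alphabetically earlier member survives

    def test_keep_list_overrides_alphabetical_drop(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        env = pd.DataFrame({"a": x, "b": x})
        kept, _ = pg.collinearity_screen(env, keep_list=("b",))
        assert kept == ["b"]

    def test_independent_noise_not_flagged(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.standard_normal((1000, 5)),
                           columns=list("abcde"))
        kept, flagged = pg.collinearity_screen(env)
        assert flagged == [] and kept == list("abcde")

    def test_exact_threshold_not_flagged(self):
        """|r| equal to the threshold stays (strict inequality)."""
        x = np.array([0.0, 1, 2, 3])
        y = np.array([0.0, 1, 2, 3])
        env = pd.DataFrame({"a": x, "b": y})
        _, flagged = pg.collinearity_screen(env, threshold=1.0)
        assert flagged == []

    def test_constant_column_excluded_with_warning(self):
        env = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10),
                            "c": np.arange(10.0) ** 2})
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = pg.collinearity_screen(env)
        assert "b" not in kept


class TestOlsSingle:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        fit = pg.ols_single(2 * x, x)
        assert fit["coef"] == pytest.approx(1.0)
        assert fit["r2"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        fit = pg.ols_single(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(fit["coef"]) < 0.05 and fit["r2"] < 0.01

    def test_standardized_coef_equals_pearson_r(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = 0.4 * x + rng.standard_normal(200)
        fit = pg.ols_single(y, x)
        assert fit["coef"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pg.ols_single(np.ones(10), np.arange(10.0))


class TestSpatialWeights:
    def test_queen_interior_corner_neighbour_counts(self):
        w = pg.build_spatial_weights(grid_cells(3, 3))
        deg = np.asarray(w.adjacency.sum(axis=1)).ravel()
        centre = 4  # (1,1) in row-major order
        assert deg[centre] == 8
        assert deg[0] == 3  # corner
        centre_row = w.W[centre].toarray().ravel()
        assert np.allclose(centre_row[centre_row > 0], 1 / 8)
        corner_row = w.W[0].toarray().ravel()
        assert np.allclose(corner_row[corner_row > 0], 1 / 3)

    def test_rows_sum_to_one(self):
        w = pg.build_spatial_weights(grid_cells(4, 5))
        assert np.allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            pg.build_spatial_weights(grid_cells(1, 1))

    def test_rook_scheme(self):
        w = pg.build_spatial_weights(grid_cells(3, 3), scheme="rook")
        assert np.asarray(w.adjacency.sum(axis=1)).ravel()[4] == 4


class TestSarErrorMl:
    def test_lambda_zero_data_reduce_to_ols(self):
        cells = grid_cells(20, 20)
        w = pg.build_spatial_weights(cells)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((400, 2))
        y = X @ np.array([0.5, -0.3]) + rng.standard_normal(400)
        fit = pg.sar_error_ml(y, X, w)
        ols = np.linalg.lstsq(np.column_stack([np.ones(400), X]), y, rcond=None)[0]
        assert np.abs(fit.beta - ols[1:]).max() < 0.02
        assert abs(fit.lam) < 0.2

    def test_zero_weight_matrix_reproduces_ols(self):
        n = 100
        Z = sparse.csr_matrix((n, n))
        w = SpatialWeights(Z, Z.copy(), "none", True)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((n, 2))
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        fit = pg.sar_error_ml(y, X, w)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        assert np.abs(fit.beta - ols[1:]).max() < 1e-8

    def test_ml_dominates_lambda_zero(self):
        cells = grid_cells(10, 10)
        w = pg.build_spatial_weights(cells)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 1))
        Wd = w.W.toarray()
        u = np.linalg.solve(np.eye(100) - 0.6 * Wd, rng.standard_normal(100))
        y = X[:, 0] * 0.5 + u
        fit = pg.sar_error_ml(y, X, w)
        # concentrated loglik at lam-hat vs at 0
        X1 = np.column_stack([np.ones(100), X])
        beta0 = np.linalg.lstsq(X1, y, rcond=None)[0]
        rss0 = ((y - X1 @ beta0) ** 2).sum()
        ll0 = -0.5 * 100 * (np.log(2 * np.pi * rss0 / 100) + 1)
        assert fit.loglik >= ll0 - 1e-8
        assert fit.lam > 0.2

    def test_singular_design_rejected(self):
        w = pg.build_spatial_weights(grid_cells(3, 3))
        X = np.ones((9, 2))
        with pytest.raises(ValueError, match="singular"):
            pg.sar_error_ml(np.arange(9.0), X, w)


class TestRda:
    def test_exact_linear_response_fully_constrained(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        Y = X @ rng.standard_normal((3, 4))
        r = pg.rda_fit(Y, X)
        assert r.constrained_proportion == pytest.approx(1.0, abs=1e-10)

    def test_noise_predictors_explain_almost_nothing(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((10_000, 3))
        X = rng.standard_normal((10_000, 2))
        r = pg.rda_fit(Y, X)
        assert r.constrained_proportion < 0.01

    def test_proportions_sum_to_one(self, default_dataset):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((100, 4))
        X = rng.standard_normal((100, 3))
        r = pg.rda_fit(Y, X)
        assert r.proportions.sum() + r.residual_proportions.sum() == pytest.approx(1.0)

    def test_single_response_equals_multiple_regression_r2(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.standard_normal(80)
        r = pg.rda_fit(y, X)
        ys = (y - y.mean()) / y.std()
        X1 = np.column_stack([np.ones(80), X])
        beta = np.linalg.lstsq(X1, ys, rcond=None)[0]
        r2 = 1 - ((ys - X1 @ beta) ** 2).sum() / (ys ** 2).sum()
        assert r.constrained_proportion == pytest.approx(r2, abs=1e-10)

    def test_aliased_predictors_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        X = np.column_stack([x, 2 * x, rng.standard_normal(40)])
        Y = rng.standard_normal((40, 2))
        with pytest.warns(UserWarning, match="aliased"):
            r = pg.rda_fit(Y, X, ["a", "b", "c"])
        assert r.dropped_predictors == ["b"]


class TestVariancePartition:
    def _groups(self, rng, n=2000):
        return {g: rng.standard_normal((n, 2)) for g in ("EW", "CS", "HA", "TO")}

    def test_orthogonal_sets_have_no_overlap(self):
        rng = np.random.default_rng(0)
        g = self._groups(rng)
        y = g["EW"] @ [1.0, 0.5] + g["CS"] @ [0.7, 0.0] + rng.standard_normal(2000)
        vp = pg.variance_partition4(y, g)
        overlaps = [v for k, v in vp.fractions.items() if len(k) > 1]
        assert max(abs(v) for v in overlaps) < 0.01
        assert vp.unique["EW"] == pytest.approx(vp.marginal["EW"], abs=0.01)

    def test_duplicated_sets_share_everything(self):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal((2000, 2))
        g = {"EW": shared, "CS": shared.copy(),
             "HA": rng.standard_normal((2000, 2)), "TO": rng.standard_normal((2000, 2))}
        y = shared @ [1.0, -0.5] + rng.standard_normal(2000)
        vp = pg.variance_partition4(y, g)
        assert vp.unique["EW"] == pytest.approx(0.0, abs=0.01)
        assert vp.fractions[("EW", "CS")] == pytest.approx(vp.marginal["EW"], abs=0.02)

    def test_fractions_sum_to_full_adjusted_r2(self):
        rng = np.random.default_rng(2)
        g = self._groups(rng, n=300)
        y = g["TO"] @ [0.5, 0.5] + rng.standard_normal(300)
        vp = pg.variance_partition4(y, g)
        assert sum(vp.fractions.values()) == pytest.approx(vp.full, abs=1e-10)

    def test_invariant_to_within_set_reordering(self):
        rng = np.random.default_rng(3)
        g = self._groups(rng, n=400)
        y = g["EW"] @ [1.0, 0.3] + rng.standard_normal(400)
        vp1 = pg.variance_partition4(y, g)
        g2 = dict(g)
        g2["EW"] = g["EW"][:, ::-1]
        vp2 = pg.variance_partition4(y, g2)
        for k in vp1.fractions:
            assert vp1.fractions[k] == pytest.approx(vp2.fractions[k], abs=1e-9)

    def test_insufficient_df_rejected(self):
        rng = np.random.default_rng(4)
        g = {k: rng.standard_normal((7, 2)) for k in ("EW", "CS", "HA", "TO")}
        with pytest.raises(ValueError, match="insufficient df"):
            pg.variance_partition4(rng.standard_normal(7), g)


def brute_force_jenks(x, k):
    """Minimal within-class SSE over all contiguous partitions of sorted x."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)

    def sse(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(sse(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


class TestJenks:
    def test_two_obvious_clusters(self):
        breaks, labels = pg.jenks_breaks(np.array([1, 2, 3, 10, 11, 12.0]), k=2)
        assert breaks.tolist() == [3.0]
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_k_equals_n_zero_sse(self):
        x = np.array([5.0, 1.0, 3.0])
        breaks, labels = pg.jenks_breaks(x, k=3)
        assert sorted(labels) == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(2, 5))
        x = rng.uniform(0, 100, n)
        _, labels = pg.jenks_breaks(x, k=k)
        total = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum()
                    for c in range(k) if (labels == c).any())
        assert total == pytest.approx(brute_force_jenks(x, k), abs=1e-8)

    def test_scale_equivariance(self):
        x = np.array([1, 2, 3, 10, 11, 12.0])
        b1, _ = pg.jenks_breaks(x, k=2)
        b2, _ = pg.jenks_breaks(10 * x, k=2)
        assert np.allclose(10 * b1, b2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 20)
        b1, l1 = pg.jenks_breaks(x, k=4)
        perm = rng.permutation(20)
        b2, l2 = pg.jenks_breaks(x[perm], k=4)
        assert np.allclose(b1, b2)
        assert np.array_equal(l1[perm], l2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pg.jenks_breaks(np.arange(3.0), k=5)


class TestElevationGradient:
    def test_perfect_negative_gradient(self):
        elev = np.linspace(3000, 5000, 30)
        fit = pg.elevation_gradient_fit(-elev, elev)
        assert fit["coef"] == pytest.approx(-1.0)
        assert fit["r2"] == pytest.approx(1.0)

    def test_synthetic_landscape_sr_declines_with_elevation(self):
        data = pg.simulate_dataset(assembly=pg.AssemblyConfig(phi=8.0), seed=21)
        # warm low-elevation cells host more species: niche centres follow
        # the temperature field, which runs opposite to elevation
        sr = data["matrix"].richness().astype(float)
        elev = data["env"].table["elevation"].to_numpy()
        fit = pg.elevation_gradient_fit(sr, elev)
        assert fit["coef"] < 0

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError):
            pg.elevation_gradient_fit(np.ones(10), np.arange(10.0))
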