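import numpy as np
import pandas as pd
import pytest

from firestats.catalog import FireCatalog
from firestats.covariates import (
    TABLE_VARIABLES,
    CorrelationMatrix,
    CovariateStack,
    filter_correlated,
    grid_aggregate,
    logistic_fit,
    pca,
    raster_correlation,
)
from firestats.density import RasterGrid

from conftest import make_record


def stack_from_arrays(**named):
    layers = {
        k: RasterGrid(x0=0.0, y0=1000.0, cell_size=100.0, values=np.asarray(v, float))
        for k, v in named.items()
    }
    return CovariateStack(layers=layers)


class TestRasterCorrelation:
    def test_self_correlation_is_one_and_negation_minus_one(self):
        rng = np.random.default_rng(20)
        z = rng.normal(size=(4, 4))
        corr = raster_correlation(stack_from_arrays(a=z, b=z.copy(), c=-z))
        f = corr.to_frame()
        assert f.loc["a", "b"] == pytest.approx(1.0)
        assert f.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.r, corr.r.T)

    def test_hand_computed_four_cell_example(self):
        z1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        z2 = np.array([[1.0, 2.0], [3.0, 5.0]])
        corr = raster_correlation(stack_from_arrays(z1=z1, z2=z2))
        # cov = 6.5/3, sds = 1.2910, 1.7078 -> r = 0.9827
        assert corr.to_frame().loc["z1", "z2"] == pytest.approx(0.9827, abs=1e-4)

    def test_zero_variance_layer_named(self):
        z = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError, match="flat"):
            raster_correlation(stack_from_arrays(a=z, flat=np.full((3, 3), 2.0)))

    def test_mismatched_georef_rejected(self):
        a = RasterGrid(0.0, 1000.0, 100.0, np.zeros((3, 3)))
        b = RasterGrid(0.0, 1000.0, 200.0, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            CovariateStack(layers={"a": a, "b": b})


def paper_pattern_matrix():
    """A 12-variable correlation fixture with the classic redundancy
    pattern: road/powerline distances, housing/population, and an
    elevation-climate block, all |r| > 0.5; everything else weak."""
    names = list(TABLE_VARIABLES)
    k = len(names)
    r = np.eye(k)
    strong = {
        ("distance_to_roads", "distance_to_powerline"): 0.5524,
        ("housing_density", "population_density"): 0.8132,
        ("elevation", "tmax"): -0.6086,
        ("elevation", "vpdmax"): -0.8359,
    }
    for (a, b), v in strong.items():
        i, j = names.index(a), names.index(b)
        r[i, j] = r[j, i] = v
    return CorrelationMatrix(names=tuple(names), r=r)


class TestFilterCorrelated:
    def test_no_violations_is_identity(self):
        m = CorrelationMatrix(names=("a", "b"), r=np.array([[1.0, 0.3], [0.3, 1.0]]))
        res = filter_correlated(m)
        assert res.retained == ("a", "b") and res.removed == ()

    def test_redundancy_pattern_with_keep_rules(self):
        res = filter_correlated(
            paper_pattern_matrix(),
            threshold=0.5,
            keep_rules=("distance_to_roads", "housing_density", "tmax", "vpdmax"),
        )
        assert set(res.removed) == {"distance_to_powerline", "population_density", "elevation"}
        assert len(res.log) == 3

    def test_postcondition_no_violating_pair_remains(self):
        rng = np.random.default_rng(21)
        A = rng.normal(size=(40, 8))
        A[:, 3] = A[:, 2] + 0.1 * rng.normal(size=40)
        r = np.corrcoef(A, rowvar=False)
        m = CorrelationMatrix(names=tuple("abcdefgh"), r=r)
        res = filter_correlated(m, threshold=0.5)
        idx = [m.names.index(v) for v in res.retained]
        sub = np.abs(r[np.ix_(idx, idx)])
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.5

    def test_deterministic(self):
        m = paper_pattern_matrix()
        assert filter_correlated(m) == filter_correlated(m)


class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=200)
        res = pca(pd.DataFrame({"a": x, "b": 2 * x + 1}), standardize=True)
        np.testing.assert_allclose(res.explained, [1.0, 0.0], atol=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(23)
        res = pca(pd.DataFrame(rng.normal(size=(100, 5))))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)

    def test_variance_fractions_sum_to_one_and_descend(self):
        rng = np.random.default_rng(24)
        res = pca(pd.DataFrame(rng.normal(size=(80, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.1])))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(60, 4))
        res = pca(pd.DataFrame(X), standardize=False)
        C = np.cov(X, rowvar=False)
        L, lam = res.loadings.to_numpy(), res.eigenvalues
        np.testing.assert_allclose(L @ np.diag(lam) @ L.T, C, atol=1e-8)

    def test_isotropic_data_has_flat_spectrum(self):
        rng = np.random.default_rng(26)
        res = pca(pd.DataFrame(rng.normal(size=(20000, 4))))
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.05)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(27)
        X = pd.DataFrame(rng.normal(size=(50, 3)))
        a, b = pca(X), pca(X)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for col in a.loadings.columns:
            v = a.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestGridAggregate:
    def test_corner_point_half_open_assignment(self):
        z = np.zeros((10, 10))
        stack = stack_from_arrays(v=z)  # 1 km square, 100 m cells
        cat = FireCatalog.from_records([make_record(0, x=500.0, y=500.0)])
        grid = grid_aggregate(cat, stack, cell_size=500.0)
        t = grid.table.set_index("cell_id")
        # point at the exact lower-left corner of cell (row 1, col 1)
        hot = t[t.presence == 1]
        assert len(hot) == 1
        assert hot.iloc[0]["cx"] == 750.0 and hot.iloc[0]["cy"] == 750.0

    def test_constant_layer_averages_to_constant(self):
        stack = stack_from_arrays(v=np.full((10, 10), 4.2))
        grid = grid_aggregate(FireCatalog(records=()), stack, cell_size=500.0)
        assert np.allclose(grid.table["v"], 4.2)
        assert len(grid.table) == 4

    def test_presence_matches_brute_force_point_in_cell(self, canonical_stack, small_scenario):
        from firestats.synthetic import gen_catalog

        cat = gen_catalog(small_scenario)
        grid = grid_aggregate(cat, canonical_stack, cell_size=9000.0)
        xmin, ymin = grid.origin
        expected = set()
        n_cx = int(np.ceil((small_scenario.window[2] - xmin) / 9000.0))
        for r in cat:
            if small_scenario.window[0] <= r.x < small_scenario.window[2] and \
               small_scenario.window[1] <= r.y < small_scenario.window[3]:
                expected.add(int((r.y - ymin) // 9000.0) * n_cx + int((r.x - xmin) // 9000.0))
        hot = set(grid.table.loc[grid.table.presence == 1, "cell_id"])
        assert hot == {c for c in expected if c in set(grid.table.cell_id)}

    def test_outside_points_counted(self):
        stack = stack_from_arrays(v=np.zeros((10, 10)))
        cat = FireCatalog.from_records([make_record(0, x=-50.0, y=500.0)])
        grid = grid_aggregate(cat, stack, cell_size=500.0)
        assert grid.n_points_outside == 1
        assert grid.table.presence.sum() == 0


class TestLogisticFit:
    def _grid(self, frame):
        from firestats.covariates import GridDataset

        return GridDataset(table=frame, cell_size=1.0, origin=(0.0, 0.0))

    def test_intercept_only_at_half_presence(self):
        frame = pd.DataFrame(
            {"cell_id": range(10), "cx": 0.0, "cy": 0.0, "presence": [0, 1] * 5}
        )
        fit = logistic_fit(self._grid(frame), variables=[])
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_binary_covariate_equals_log_odds_ratio(self):
        # 2x2 table: exposed 30/70 present, unexposed 10/90
        rows = (
            [{"z": 1.0, "presence": 1}] * 30 + [{"z": 1.0, "presence": 0}] * 70
            + [{"z": 0.0, "presence": 1}] * 10 + [{"z": 0.0, "presence": 0}] * 90
        )
        frame = pd.DataFrame(rows)
        frame["cell_id"] = range(len(frame))
        frame["cx"] = frame["cy"] = 0.0
        fit = logistic_fit(self._grid(frame), variables=["z"])
        log_or = np.log((30 / 70) / (10 / 90))
        assert fit.coefficients["z"] == pytest.approx(log_or, rel=1e-5)
        assert 0 < fit.p_values["z"] < 1 and fit.std_errors["z"] > 0

    def test_single_class_rejected(self):
        frame = pd.DataFrame(
            {"cell_id": range(6), "cx": 0.0, "cy": 0.0, "presence": 1, "z": range(6)}
        )
        with pytest.raises(ValueError, match="single class"):
            logistic_fit(self._grid(frame), variables=["z"])

    def test_separation_flagged(self):
        frame = pd.DataFrame(
            {
                "cell_id": range(20),
                "cx": 0.0,
                "cy": 0.0,
                "z": np.r_[np.arange(10), 100 + np.arange(10)].astype(float),
                "presence": [0] * 10 + [1] * 10,
            }
        )
        fit = logistic_fit(self._grid(frame), variables=["z"])
        assert fit.separation or not fit.converged
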