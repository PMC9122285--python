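"""t-SNE reduction, mosaics, color projections and axis regressions."""

import numpy as np
import pandas as pd
import pytest

from convsdm import embedding as E


# --------------------------------------------------------------------------
# brute-force oracles

def oracle_mosaic(z, n):
    """All-pairs scan: for every cell, the in-cell point nearest its center."""
    xmin, ymin = z.min(axis=0)
    xmax, ymax = z.max(axis=0)
    w = (xmax - xmin) or 1.0
    h = (ymax - ymin) or 1.0
    occupant = np.full((n, n), -1)
    for i in range(n):
        for j in range(n):
            cx = xmin + (j + 0.5) * w / n
            cy = ymin + (i + 0.5) * h / n
            best, best_d = -1, np.inf
            for p in range(len(z)):
                jj = min(int((z[p, 0] - xmin) / w * n), n - 1)
                ii = min(int((z[p, 1] - ymin) / h * n), n - 1)
                if (ii, jj) != (i, j):
                    continue
                d = (z[p, 0] - cx) ** 2 + (z[p, 1] - cy) ** 2
                if d < best_d:
                    best, best_d = p, d
            occupant[i, j] = best
    return occupant


def oracle_nearest(points, queries):
    out = np.empty(len(queries), dtype=int)
    for i, q in enumerate(queries):
        out[i] = np.argmin(((points - q) ** 2).sum(axis=1))
    return out


class TestReduceFeatures:
    def test_determinism_given_seed(self, rng):
        x = rng.normal(size=(120, 20))
        a = E.reduce_features(x, out_dim=2, seed=5)
        b = E.reduce_features(x, out_dim=2, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        labels = rng.integers(0, 2, size=200)
        x = rng.normal(size=(200, 30)) + 12.0 * labels[:, None]
        emb = E.reduce_features(x, out_dim=2, seed=3)
        assert silhouette_score(emb.coords, labels) >= 0.2

    def test_pca_preamble_preserves_distances_for_low_rank_data(self, rng):
        from sklearn.decomposition import PCA
        from scipy.spatial.distance import pdist
        from scipy.stats import pearsonr

        # intrinsic dimension 20 << 50 inside a 2048-d ambient space
        x = rng.normal(size=(150, 20)) @ rng.normal(size=(20, 2048))
        reduced = PCA(n_components=50, random_state=0).fit_transform(x)
        r, _ = pearsonr(pdist(x), pdist(reduced))
        assert r >= 0.99

    def test_subsampling_is_seeded_and_sized(self, rng):
        x = rng.normal(size=(100, 10))
        emb = E.reduce_features(x, out_dim=2, sample_size=40, seed=9)
        assert len(emb.indices) == 40 and len(np.unique(emb.indices)) == 40

    def test_invalid_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            E.reduce_features(rng.normal(size=(50, 5)), out_dim=4)


class TestMosaic:
    def test_point_at_cell_center_occupies_it(self):
        z = np.array([[0.0, 0.0], [4.0, 4.0], [2.5, 1.5]])
        grid = E.build_mosaic(z, 4)  # bbox [0,4]^2, cells of 1.0
        assert grid.occupant[1, 2] == 2  # (2.5, 1.5) is the center of cell i=1,j=2

    def test_cells_without_occurrences_stay_empty(self):
        z = np.array([[0.0, 0.0], [9.0, 9.0]])
        grid = E.build_mosaic(z, 3)
        assert (grid.occupant >= 0).sum() == 2

    def test_nearer_of_two_in_cell_wins(self):
        # both points in the top-right cell of a 2x2 grid over [0,2]^2
        z = np.array([[0.0, 0.0], [1.6, 1.6], [1.2, 1.9]])
        grid = E.build_mosaic(z, 2)
        # cell center (1.5, 1.5): point 1 at distance .14, point 2 at .25
        assert grid.occupant[1, 1] == 1

    def test_matches_brute_force_oracle(self, rng):
        z = rng.normal(size=(500, 2))
        n = 9
        grid = E.build_mosaic(z, n)
        np.testing.assert_array_equal(grid.occupant, oracle_mosaic(z, n))

    def test_empty_embedding_rejected(self):
        with pytest.raises(ValueError):
            E.build_mosaic(np.empty((0, 2)), 4)

    def test_payload_lookup(self, rng):
        z = rng.normal(size=(30, 2))
        vals = rng.normal(size=30)
        grid = E.build_mosaic(z, 5)
        pay = E.mosaic_payload(grid, vals)
        filled = grid.occupant >= 0
        np.testing.assert_array_equal(pay[filled], vals[grid.occupant[filled]])
        assert np.isnan(pay[~filled]).all()


class TestBilinearColors:
    corners = np.array([[0, 0, 0], [255, 0, 0], [0, 255, 0], [255, 255, 0]], float)

    def test_corner_points_get_corner_colors(self):
        z = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        c = E.bilinear_embedding_colors(z, self.corners)
        np.testing.assert_allclose(c, self.corners)

    def test_center_is_mean_of_corners(self):
        z = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], float)
        c = E.bilinear_embedding_colors(z, self.corners)
        np.testing.assert_allclose(c[4], self.corners.mean(axis=0))

    def test_edge_points_interpolate_linearly(self):
        # points along the v=0 edge blend the two bottom corners
        ts = np.array([0.0, 0.25, 0.5, 1.0])
        z = np.column_stack([ts, np.zeros(4)])
        z = np.vstack([z, [0.0, 1.0]])  # give the v axis extent
        c = E.bilinear_embedding_colors(z, self.corners)
        expected = (1 - ts)[:, None] * self.corners[0] + ts[:, None] * self.corners[1]
        np.testing.assert_allclose(c[:4], expected, atol=1e-12)

    def test_degenerate_axis_rejected(self):
        z = np.array([[0.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            E.bilinear_embedding_colors(z)


class TestGeographicProjection:
    def test_single_occurrence_colors_whole_map(self):
        raster, _ = E.geographic_projection(
            np.array([[5.0, 5.0]]), np.array([[10.0, 20.0, 30.0]]),
            grid_step=1.0, bounds=(0, 0, 10, 10),
        )
        assert np.all(raster == [10.0, 20.0, 30.0])

    def test_grid_point_coincident_with_occurrence(self):
        pts = np.array([[0.0, 0.0], [4.0, 4.0]])
        cols = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        raster, georef = E.geographic_projection(pts, cols, 1.0, bounds=(0, 0, 4, 4))
        # origin is the north-west grid point (0, 4) -> nearest is (4,4)? no: (0,4)
        assert georef["origin"] == (0.0, 4.0)
        np.testing.assert_array_equal(raster[-1, 0], cols[0])  # grid point (0,0)
        np.testing.assert_array_equal(raster[0, -1], cols[1])  # grid point (4,4)

    def test_two_points_partition_along_bisector(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        cols = np.array([[0.0], [1.0]])
        raster, _ = E.geographic_projection(pts, cols, 1.0, bounds=(0, 0, 10, 0))
        row = raster[0, :, 0]
        assert np.all(row[:5] == 0.0) and np.all(row[6:] == 1.0)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 50, size=(400, 2))
        cols = rng.random((400, 3))
        raster, _ = E.geographic_projection(pts, cols, 5.0, bounds=(0, 0, 50, 50))
        xs = np.arange(0, 51, 5.0)
        ys = np.arange(50, -1, -5.0)
        gx, gy = np.meshgrid(xs, ys)
        queries = np.column_stack([gx.ravel(), gy.ravel()])
        nn = oracle_nearest(pts, queries)
        np.testing.assert_array_equal(raster.reshape(-1, 3), cols[nn])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            E.geographic_projection(np.empty((0, 2)), np.empty((0, 3)), 1.0)


class TestEmbedding3ToRGB:
    def test_minmax_endpoints(self, rng):
        z = rng.normal(size=(40, 3))
        rgb = E.embedding3_to_rgb(z)
        for axis in range(3):
            assert rgb[:, axis].min() == 0.0 and rgb[:, axis].max() == 255.0

    def test_affine_invariance(self, rng):
        z = rng.normal(size=(40, 3))
        scale = np.array([2.0, 0.5, 7.0])
        shift = np.array([-3.0, 11.0, 0.1])
        np.testing.assert_allclose(
            E.embedding3_to_rgb(z), E.embedding3_to_rgb(z * scale + shift), atol=1e-9
        )

    def test_two_dominating_points(self):
        z = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        rgb = E.embedding3_to_rgb(z)
        np.testing.assert_array_equal(rgb[0], [0, 0, 0])
        np.testing.assert_array_equal(rgb[1], [255, 255, 255])

    def test_constant_axis_rejected(self):
        z = np.array([[0.0, 1.0, 5.0], [1.0, 2.0, 5.0]])
        with pytest.raises(ValueError):
            E.embedding3_to_rgb(z)


class TestAxisLinearModels:
    def test_exact_linear_relationship_gives_unit_r2(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        z = np.column_stack([
            1.0 + 2.0 * x["a"] - x["c"],
            0.5 * x["b"],
        ])
        rep = E.axis_linear_models(z, x)
        assert rep.r_squared[0] == pytest.approx(1.0, abs=1e-10)
        assert rep.r_squared[1] == pytest.approx(1.0, abs=1e-10)
        assert rep.tables[0].loc["a", "estimate"] == pytest.approx(2.0, abs=1e-8)

    def test_pure_noise_has_negligible_adjusted_r2(self, rng):
        x = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        z = rng.normal(size=(1000, 2))
        rep = E.axis_linear_models(z, x)
        assert rep.adj_r_squared[0] <= 0.02 and rep.adj_r_squared[1] <= 0.02

    def test_four_point_closed_form(self):
        # simple regression y = b0 + b1 x on 4 points, solved by hand:
        # x = (0,1,2,3), y = (1,3,4,8): b1 = Sxy/Sxx = 11/5, b0 = ybar-b1*xbar
        x = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = np.array([[1.0], [3.0], [4.0], [8.0]])
        rep = E.axis_linear_models(y, x)
        assert rep.tables[0].loc["x", "estimate"] == pytest.approx(11 / 5)
        assert rep.tables[0].loc["intercept", "estimate"] == pytest.approx(4.0 - (11 / 5) * 1.5)

    def test_difference_predictor_excluded_for_environment_set(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 2)), columns=["bio_5", "bio_6"])
        x["bio_7"] = x["bio_5"] - x["bio_6"]
        z = rng.normal(size=(60, 2))
        rep = E.axis_linear_models(z, x, predictor_set="environment")
        assert rep.excluded == ["bio_7"]
        assert "bio_7" not in rep.tables[0].index

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        x["dup"] = x["a"]
        z = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="dup|a"):
            E.axis_linear_models(z, x)

    def test_missing_rows_dropped_and_counted(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        x.iloc[5, 0] = np.nan
        x.iloc[9, 1] = np.nan
        z = rng.normal(size=(40, 2))
        rep = E.axis_linear_models(z, x)
        assert rep.n_dropped == 2 and rep.n_used == 38
        assert rep.adj_r_squared[0] <= rep.r_squared[0]
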