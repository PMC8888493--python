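import numpy as np
import pytest

import nutriscape as ns
from nutriscape.errors import ValidationError
from nutriscape.tps import collapse_to_knots, effective_df_profile


@pytest.fixture(scope="module")
def replicated_data(grid_coords):
    """Noisy replicated responses on the 40-diet design."""
    rng = np.random.default_rng(5)
    locs = np.repeat(grid_coords, 5, axis=0)
    truth = 40 - 0.01 * (locs[:, 0] - 20) ** 2 - 0.008 * (locs[:, 1] - 55) ** 2
    return locs, truth + rng.normal(0, 3, size=len(locs))


def test_lambda_zero_interpolates_knot_means(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec=0.0)
    knots, ybar, _ = collapse_to_knots(locs, vals)
    pred = ns.predict_surface(model, knots)
    assert np.max(np.abs(pred - ybar)) < 1e-8


def test_affine_data_fit_exactly_at_any_lambda(grid_coords):
    vals = 3.0 + 0.25 * grid_coords[:, 0] - 0.4 * grid_coords[:, 1]
    probe = np.array([[10.0, 30.0], [35.0, 55.0], [5.0, 70.0]])
    truth = 3.0 + 0.25 * probe[:, 0] - 0.4 * probe[:, 1]
    for lam in [0.0, 1e-3, 1.0, 1e3]:
        model = ns.fit_tps(grid_coords, vals, lambda_spec=lam)
        assert np.allclose(ns.predict_surface(model, probe), truth, atol=1e-6)


def test_large_lambda_converges_to_weighted_least_squares_plane(replicated_data):
    locs, vals = replicated_data
    knots, ybar, counts = collapse_to_knots(locs, vals)
    # independent weighted plane fit on the knot means
    X = np.column_stack([np.ones(len(knots)), knots])
    W = np.diag(counts)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ybar)
    model = ns.fit_tps(locs, vals, lambda_spec=1e12)
    pred = ns.predict_surface(model, knots)
    assert np.max(np.abs(pred - X @ beta)) < 1e-4


def test_gcv_selects_positive_lambda_on_noisy_replicated_data(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec="gcv")
    assert model.lam > 0
    assert model.gcv_score >= 0
    assert 3 <= model.effective_df <= model.n_knots


def test_effective_df_decreases_with_lambda(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec=1.0)
    lambdas = np.logspace(-6, 6, 13)
    df = effective_df_profile(model, lambdas)
    assert np.all(np.diff(df) <= 1e-8)
    assert df[0] <= model.n_knots + 1e-6
    assert df[-1] >= 3 - 1e-6


def test_kernel_weights_satisfy_orthogonality_side_conditions(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec="gcv")
    z = model._standardize(model.knots)
    T = np.column_stack([np.ones(len(z)), z])
    assert np.allclose(T.T @ model.kernel_weights, 0, atol=1e-8)


def test_prediction_is_continuous_and_vectorization_consistent(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec="gcv")
    p = np.array([22.0, 48.0])
    a = ns.predict_surface(model, p)[0]
    b = ns.predict_surface(model, p + 1e-9)[0]
    assert abs(a - b) < 1e-6
    pts = np.array([[5.0, 10.0], [22.0, 48.0], [50.0, 20.0]])
    batch = ns.predict_surface(model, pts)
    single = [ns.predict_surface(model, q)[0] for q in pts]
    assert np.allclose(batch, single)


def test_fit_equivariant_under_common_coordinate_rescaling(replicated_data):
    locs, vals = replicated_data
    m1 = ns.fit_tps(locs, vals, lambda_spec=0.0)
    m2 = ns.fit_tps(locs * 3.7, vals, lambda_spec=0.0)
    probe = np.array([[12.0, 40.0], [30.0, 60.0]])
    assert np.allclose(
        ns.predict_surface(m1, probe), ns.predict_surface(m2, probe * 3.7), atol=1e-6
    )


def test_interpolation_agrees_with_scipy_rbf_oracle():
    # on pre-standardized coordinates the internal rescaling is a pure
    # translation, so the lambda=0 spline must match scipy's thin-plate RBF
    from scipy.interpolate import RBFInterpolator

    rng = np.random.default_rng(12)
    pts = rng.normal(size=(25, 2))
    pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)
    vals = np.sin(pts[:, 0]) + 0.5 * pts[:, 1] ** 2
    model = ns.fit_tps(pts, vals, lambda_spec=0.0)
    oracle = RBFInterpolator(pts, vals, kernel="thin_plate_spline")
    probe = rng.uniform(-1, 1, size=(40, 2))
    assert np.allclose(ns.predict_surface(model, probe), oracle(probe), atol=1e-6)


def test_collinear_locations_rejected():
    pts = np.column_stack([np.linspace(0, 1, 8), np.linspace(0, 2, 8)])
    with pytest.raises(ValidationError):
        ns.fit_tps(pts, np.arange(8.0))


def test_negative_lambda_rejected(grid_coords):
    with pytest.raises(ValidationError):
        ns.fit_tps(grid_coords, np.arange(40.0), lambda_spec=-1.0)


def test_grid_export_masks_match_point_in_polygon_oracle(replicated_data, grid_coords):
    from matplotlib.path import Path as MplPath

    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec="gcv")
    region = ns.ConvexRegion.from_points(grid_coords)
    grid = ns.export_landscape_grid(model, 100, region)
    assert len(grid) == 100 * 100
    frac = grid["masked"].mean()
    assert 0 < frac < 1
    path = MplPath(np.vstack([region.vertices, region.vertices[:1]]))
    oracle_inside = path.contains_points(grid[["P", "C"]].to_numpy(), radius=1e-9)
    disagreement = np.mean(oracle_inside == grid["masked"].to_numpy())
    assert disagreement < 0.005  # boundary-cell ties only


def test_full_bbox_region_has_no_masked_cells(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec=1.0)
    lo, hi = model.region().bounding_box()
    box = ns.ConvexRegion(
        np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    )
    grid = ns.export_landscape_grid(model, 25, box)
    assert not grid["masked"].any()


def test_resolution_two_gives_four_corner_cells(replicated_data):
    locs, vals = replicated_data
    model = ns.fit_tps(locs, vals, lambda_spec=1.0)
    lo, hi = model.region().bounding_box()
    box = ns.ConvexRegion(
        np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    )
    grid = ns.export_landscape_grid(model, 2, box)
    assert len(grid) == 4
    with pytest.raises(ValidationError):
        ns.export_landscape_grid(model, 1, box)
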