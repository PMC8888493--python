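import numpy as np
import pytest

import nutriscape as ns
from nutriscape.errors import ValidationError
from nutriscape.optima import DistanceComparison, OptimumRegion


def _paraboloid_records(grid, peak=(20.0, 60.0), noise=0.0, n_rep=5, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    k = 0
    for diet in grid:
        p, c = diet.protein_pct, diet.carbohydrate_pct
        mu = 80 - 0.02 * (p - peak[0]) ** 2 - 0.02 * (c - peak[1]) ** 2
        for _ in range(n_rep):
            k += 1
            recs.append(
                ns.IndividualRecord(
                    f"q{k}", "female", diet,
                    lifespan_days=max(mu + rng.normal(0, noise), 0.5),
                    assay_counts=(1,),
                )
            )
    return recs


def test_optimum_of_noise_free_paraboloid_is_near_its_analytic_peak(paper_grid):
    recs = _paraboloid_records(paper_grid)
    sel = [(r.diet.protein_pct, r.diet.carbohydrate_pct, r.lifespan_days) for r in recs]
    arr = np.array(sel)
    model = ns.fit_tps(arr[:, :2], arr[:, 2], lambda_spec=0.0)
    opt, val = ns.find_optimum(model, model.region())
    assert np.linalg.norm(opt - [20.0, 60.0]) < 0.5
    assert val <= 80.0 + 0.5


def test_affine_surface_optimum_is_a_region_vertex(grid_coords):
    vals = 1.0 + 0.0 * grid_coords[:, 0] + 0.5 * grid_coords[:, 1]  # increasing in C
    model = ns.fit_tps(grid_coords, vals, lambda_spec=1e6)
    region = model.region()
    opt, val = ns.find_optimum(model, region)
    # vertex-enumeration oracle: best vertex of the plane over the polygon
    v_vals = ns.predict_surface(model, region.vertices)
    best = region.vertices[np.argmax(v_vals)]
    assert np.linalg.norm(opt - best) < 1e-6
    assert val >= v_vals.max() - 1e-8


def test_point_region_returns_that_point(grid_coords):
    vals = np.hypot(grid_coords[:, 0], grid_coords[:, 1])
    model = ns.fit_tps(grid_coords, vals, lambda_spec=1.0)
    pt = ns.ConvexRegion(np.array([[15.0, 45.0]]))
    opt, val = ns.find_optimum(model, pt)
    assert np.allclose(opt, [15.0, 45.0])
    assert val == pytest.approx(ns.predict_surface(model, np.array([15.0, 45.0]))[0])


def test_optimum_never_below_best_grid_seed(grid_coords):
    rng = np.random.default_rng(3)
    vals = rng.normal(size=40)
    model = ns.fit_tps(grid_coords, vals, lambda_spec=0.01)
    region = model.region()
    opt, val = ns.find_optimum(model, region, seed_resolution=31)
    from nutriscape.optima import _grid_evaluate

    _, seed_vals = _grid_evaluate(model, region, 31)
    assert val >= seed_vals.max() - 1e-9


def test_bootstrap_zero_noise_collapses_the_confidence_region(paper_grid):
    recs = _paraboloid_records(paper_grid, noise=0.0, n_rep=3)
    reg = ns.bootstrap_optimum_region(recs, "lifespan", "female", B=40, seed=9,
                                      lambda_spec=0.0)
    spread = np.ptp(reg.bootstrap_optima, axis=0)
    assert np.all(spread < 1e-8)
    assert np.allclose(reg.cr_polygon, reg.cr_polygon[0])


def test_bootstrap_cloud_stays_inside_search_region_and_is_reproducible(paper_grid):
    recs = _paraboloid_records(paper_grid, noise=6.0, n_rep=5, seed=2)
    reg1 = ns.bootstrap_optimum_region(recs, "lifespan", "female", B=60, seed=4)
    reg2 = ns.bootstrap_optimum_region(recs, "lifespan", "female", B=60, seed=4)
    assert np.array_equal(reg1.bootstrap_optima, reg2.bootstrap_optima)
    assert np.array_equal(reg1.cr_polygon, reg2.cr_polygon)
    sel_region = ns.ConvexRegion.from_points(
        np.array([[r.diet.protein_pct, r.diet.carbohydrate_pct] for r in recs])
    )
    assert np.all(sel_region.contains(reg1.bootstrap_optima, tol=1e-6))


def test_cr_area_shrinks_with_noise(paper_grid):
    areas = []
    for noise in (12.0, 2.0):
        recs = _paraboloid_records(paper_grid, noise=noise, n_rep=5, seed=7)
        reg = ns.bootstrap_optimum_region(recs, "lifespan", "female", B=80, seed=1)
        areas.append(ns.ConvexRegion.from_points(reg.cr_polygon).area())
    assert areas[1] <= areas[0]


def _point_region(pt, label="x"):
    cloud = np.array([pt])
    return OptimumRegion(
        trait=label, sex="female", optimum=np.array(pt), optimum_value=0.0,
        bootstrap_optima=cloud, cr_polygon=cloud, alpha=0.05, seed=0,
    )


def test_distance_identities():
    a = _point_region([3.0, 4.0])
    same = ns.region_distance(a, _point_region([3.0, 4.0]))
    assert same.d == 0 and same.ci == (0, 0)
    offset = ns.region_distance(a, _point_region([6.0, 8.0]))
    assert offset.d == pytest.approx(5.0)
    assert offset.ci == (pytest.approx(5.0), pytest.approx(5.0))


def test_distance_is_symmetric(paper_grid):
    recs = _paraboloid_records(paper_grid, noise=6.0, n_rep=4, seed=5)
    ra = ns.bootstrap_optimum_region(recs, "lifespan", "female", B=40, seed=1)
    rb = ns.bootstrap_optimum_region(recs, "daily_re", "female", B=40, seed=2)
    ab, ba = ns.region_distance(ra, rb), ns.region_distance(rb, ra)
    assert ab == DistanceComparison(ba.d, ba.ci, ba.n_pairs)


def test_mismatched_alpha_rejected():
    a = _point_region([1.0, 1.0])
    b = _point_region([2.0, 2.0])
    b.alpha = 0.10
    with pytest.raises(ValidationError):
        ns.region_distance(a, b)


@pytest.mark.parametrize(
    "coord, expected",
    [
        ((4.25, 67.70), "1:15.93"),
        ((6.0, 6.0), "1:1"),
        ((36.50, 42.22), "1:1.16"),
        ((45.0, 15.0), "3:1"),
    ],
)
def test_pc_ratio_normalizes_to_the_smaller_side(coord, expected):
    assert ns.pc_ratio(coord) == expected


def test_pc_ratio_rejects_nonpositive_protein():
    with pytest.raises(ValidationError):
        ns.pc_ratio((0.0, 10.0))
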