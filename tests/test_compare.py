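import numpy as np
import pytest

import nutriscape as ns
from nutriscape.errors import ValidationError
from nutriscape.surface import design_matrix


def _dataset(grid, beta, noise, n_rep, seed, label="a"):
    from nutriscape.simulate import _standardized_grid_coords

    zp, zc = _standardized_grid_coords(grid)
    rng = np.random.default_rng(seed)
    P, C, y = [], [], []
    for i, diet in enumerate(grid):
        X = design_matrix(np.array([zp[i]]), np.array([zc[i]]))
        mu = float((X @ beta)[0])
        for _ in range(n_rep):
            P.append(diet.protein_pct)
            C.append(diet.carbohydrate_pct)
            y.append(mu + rng.normal(0, noise))
    return ns.TraitDataset(label, np.array(P), np.array(C), np.array(y))


BETA = np.array([0.0, -0.4, 0.5, 0.2, -0.3, -0.25])


def test_sequential_df_structure_for_two_groups_of_800(paper_records):
    a = ns.TraitDataset.from_records(paper_records, "lifespan", "male")
    b = ns.TraitDataset.from_records(paper_records, "lifespan", "female")
    assert a.n == b.n == 800
    res = ns.sequential_compare(a, b)
    assert [r.stage for r in res] == ["linear", "quadratic", "correlational"]
    assert [(r.df1, r.df2) for r in res] == [(2, 1594), (2, 1590), (1, 1588)]
    for r in res:
        assert r.ss_reduced >= r.ss_complete
        assert 0 <= r.p_value <= 1


def test_identical_groups_give_zero_f_at_every_stage(paper_grid):
    a = _dataset(paper_grid, BETA, noise=1.0, n_rep=5, seed=1)
    b = ns.TraitDataset("b", a.P.copy(), a.C.copy(), a.y.copy())
    for r in ns.sequential_compare(a, b):
        assert r.f_value == pytest.approx(0, abs=1e-10)
    f, _ = ns.univariate_followup(a, b, "linear", "P")
    assert f == pytest.approx(0, abs=1e-10)


def test_stage_f_matches_brute_force_double_fit_oracle(paper_grid):
    # 60-record instance: refit both nested models explicitly and plug the
    # residual sums of squares into the partial-F formula
    a = _dataset(paper_grid[:20], BETA, noise=1.0, n_rep=2, seed=3)
    b = _dataset(paper_grid[:20], -BETA, noise=1.0, n_rep=1, seed=4, label="b")
    res = ns.sequential_compare(a, b)

    zy = np.concatenate([ns.zscore(a.y)[0], ns.zscore(b.y)[0]])
    zP = ns.zscore(np.concatenate([a.P, b.P]))[0]
    zC = ns.zscore(np.concatenate([a.C, b.C]))[0]
    g = np.concatenate([np.zeros(a.n), np.ones(b.n)])

    def rss(cols):
        X = np.column_stack(cols)
        r = zy - X @ np.linalg.lstsq(X, zy, rcond=None)[0]
        return r @ r

    one = np.ones_like(zy)
    red = rss([one, g, zP, zC])
    com = rss([one, g, zP, zC, g * zP, g * zC])
    n = len(zy)
    f_oracle = ((red - com) / 2) / (com / (n - 6))
    assert res[0].f_value == pytest.approx(f_oracle)
    assert res[0].ss_reduced == pytest.approx(red)
    assert res[0].ss_complete == pytest.approx(com)

    red_q = rss([one, g, zP, zC, g * zP, g * zC, zP**2, zC**2])
    com_q = rss([one, g, zP, zC, g * zP, g * zC, zP**2, zC**2, g * zP**2, g * zC**2])
    f_oracle_q = ((red_q - com_q) / 2) / (com_q / (n - 10))
    assert res[1].f_value == pytest.approx(f_oracle_q)


def test_stage_f_invariant_to_group_label_exchange(paper_grid):
    a = _dataset(paper_grid, BETA, noise=1.0, n_rep=3, seed=5)
    b = _dataset(paper_grid, 0.5 * BETA, noise=1.0, n_rep=3, seed=6, label="b")
    fwd = ns.sequential_compare(a, b)
    rev = ns.sequential_compare(b, a)
    for r1, r2 in zip(fwd, rev):
        assert r1.f_value == pytest.approx(r2.f_value)
        assert (r1.df1, r1.df2) == (r2.df1, r2.df2)


def test_univariate_followup_df_and_pvalue_match_permutation_oracle(paper_grid):
    # small instance: compare the parametric p-value with a label-shuffle null
    sub = paper_grid[:20]  # 5 ratios x 4 dilutions
    a = _dataset(sub, BETA, noise=2.0, n_rep=1, seed=7)
    b = _dataset(sub, BETA * np.array([1, -1, 1, 1, 1, 1]), noise=2.0, n_rep=1,
                 seed=8, label="b")
    f_obs, p_obs = ns.univariate_followup(a, b, "linear", "P")

    rng = np.random.default_rng(99)
    y_all = np.concatenate([a.y, b.y])
    n_perm, hits = 500, 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y_all))
        ya, yb = y_all[perm[: a.n]], y_all[perm[a.n:]]
        pa = ns.TraitDataset("a", a.P, a.C, ya)
        pb = ns.TraitDataset("b", b.P, b.C, yb)
        f_perm, _ = ns.univariate_followup(pa, pb, "linear", "P")
        hits += f_perm >= f_obs
    p_perm = (hits + 1) / (n_perm + 1)
    se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
    assert abs(p_obs - p_perm) < max(4 * se, 0.02)


def test_univariate_df2_at_linear_stage_is_n_minus_six(paper_records):
    a = ns.TraitDataset.from_records(paper_records, "daily_re", "male")
    b = ns.TraitDataset.from_records(paper_records, "daily_re", "female")
    res = ns.sequential_compare(a, b)
    assert res[0].df2 == 1594  # univariate follow-ups share this denominator
    f, p = ns.univariate_followup(a, b, "linear", "C")
    assert f >= 0 and 0 <= p <= 1
    with pytest.raises(ValidationError):
        ns.univariate_followup(a, b, "linear", "PC")


@pytest.mark.parametrize(
    "v1, v2, expected",
    [
        ((1, 0), (0, 1), 90.0),
        ((1, 1), (2, 2), 0.0),
        ((1, 0), (-1, 0), 180.0),
    ],
)
def test_angle_identities(v1, v2, expected):
    # arccos loses ~sqrt(eps) precision at cos = +/-1, hence the loose abs tol
    assert ns.angle_between(v1, v2) == pytest.approx(expected, abs=1e-4)


def test_angle_of_rounded_published_lifespan_vectors():
    # arccos of the normalized dot product, computed independently via atan2
    v1, v2 = np.array([-0.31, 0.38]), np.array([-0.17, 0.25])
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    expected = np.degrees(abs(np.arctan2(cross, np.dot(v1, v2))))
    assert ns.angle_between(v1, v2) == pytest.approx(expected)
    assert 4.0 < expected < 6.0


def test_angle_invariant_to_positive_rescaling():
    assert ns.angle_between((0.2, 0.7), (0.5, 0.1)) == pytest.approx(
        ns.angle_between((2.0, 7.0), (0.05, 0.01))
    )


def test_angle_with_zero_vector_rejected():
    with pytest.raises(ValidationError):
        ns.angle_between((0, 0), (1, 1))


def test_bootstrap_angle_identical_true_vectors_low_noise(paper_grid):
    a = _dataset(paper_grid, BETA, noise=0.05, n_rep=5, seed=10)
    b = _dataset(paper_grid, BETA, noise=0.05, n_rep=5, seed=11, label="b")
    ang = ns.bootstrap_angle(a, b, B=200, seed=12)
    assert ang.theta_deg < 5.0
    assert 0 <= ang.ci[0] <= ang.ci[1] <= 180


def test_bootstrap_angle_orthogonal_true_vectors(paper_grid):
    beta_a = np.array([0.0, 0.5, 0.0, 0.1, -0.1, 0.05])
    beta_b = np.array([0.0, 0.0, 0.5, 0.1, -0.1, 0.05])
    a = _dataset(paper_grid, beta_a, noise=0.05, n_rep=5, seed=13)
    b = _dataset(paper_grid, beta_b, noise=0.05, n_rep=5, seed=14, label="b")
    ang = ns.bootstrap_angle(a, b, B=200, seed=15)
    assert ang.ci[0] <= 90.0 <= ang.ci[1]
    assert ang.theta_deg == pytest.approx(90.0, abs=5.0)


def test_bootstrap_angle_is_seed_reproducible(paper_grid):
    a = _dataset(paper_grid, BETA, noise=1.0, n_rep=3, seed=16)
    b = _dataset(paper_grid, -BETA, noise=1.0, n_rep=3, seed=17, label="b")
    r1 = ns.bootstrap_angle(a, b, B=50, seed=18)
    r2 = ns.bootstrap_angle(a, b, B=50, seed=18)
    assert r1 == r2
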