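"""Landscape optima, bootstrap confidence regions, and optimum distances.

The global optimum of a fitted landscape is searched inside the convex hull
of the observed diet coordinates only (no extrapolation): a dense grid over
the hull seeds a constrained local refinement.  Uncertainty comes from a
stratified bootstrap — individuals are resampled with replacement within
each diet, the spline is refitted at the point estimate's smoothing level,
and the optimum re-located — giving a cloud of bootstrap optima whose
trimmed convex hull is the confidence region.  Distances between two
optimum regions are summarized by the mean pairwise Euclidean distance
between their bootstrap clouds with percentile confidence bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ValidationError
from .geometry import ConvexRegion
from .records import IndividualRecord
from .tps import TPSLandscape, _kernel_matrix, _TPSSystem, fit_tps, predict_surface

logger = logging.getLogger(__name__)

MAX_DISTANCE_PAIRS = 10**6


@dataclass
class OptimumRegion:
    """A landscape optimum with its bootstrap confidence region."""

    trait: str
    sex: str
    optimum: np.ndarray           # (P, C) raw scale
    optimum_value: float
    bootstrap_optima: np.ndarray  # (B, 2)
    cr_polygon: np.ndarray        # hull vertices of the trimmed cloud
    alpha: float
    seed: int


@dataclass
class DistanceComparison:
    """Mean pairwise distance between two bootstrap-optimum clouds."""

    d: float
    ci: tuple[float, float]
    n_pairs: int


def find_optimum(
    model: TPSLandscape,
    region: ConvexRegion,
    seed_resolution: int = 101,
    polish: bool = True,
) -> tuple[np.ndarray, float]:
    """Locate the maximizer of the predicted surface within a convex region.

    A ``seed_resolution``^2 grid over the region's bounding box (restricted
    to the region) is evaluated; the best seed is refined by SLSQP under
    the region's half-space constraints.  Ties between seeds break toward
    the lower protein coordinate.  The result never falls below the best
    grid seed.
    """
    if region.is_degenerate and len(region.vertices) == 1:
        pt = region.vertices[0]
        return pt.copy(), float(predict_surface(model, pt)[0])
    data_region = model.region()
    if not np.any(data_region.contains(region.vertices)):
        warnings.warn(
            "search region lies entirely outside the fitted diet hull; "
            "optimum is an extrapolation",
            stacklevel=2,
        )
    pts, vals = _grid_evaluate(model, region, seed_resolution)
    best_idx = _lexi_best(pts, vals)
    best_pt, best_val = pts[best_idx], vals[best_idx]
    if polish and not region.is_degenerate:
        refined = _polish(model, region, best_pt)
        if refined is not None:
            ref_pt, ref_val = refined
            if ref_val > best_val:
                best_pt, best_val = ref_pt, ref_val
    return best_pt.copy(), float(best_val)


def _grid_evaluate(
    model: TPSLandscape, region: ConvexRegion, resolution: int
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = region.bounding_box()
    ps = np.linspace(lo[0], hi[0], resolution)
    cs = np.linspace(lo[1], hi[1], resolution)
    P, C = np.meshgrid(ps, cs, indexing="ij")
    pts = np.column_stack([P.ravel(), C.ravel()])
    inside = region.contains(pts)
    # always include the vertices so flat/affine surfaces find their corner
    pts = np.vstack([pts[inside], region.vertices])
    return pts, predict_surface(model, pts)


def _lexi_best(pts: np.ndarray, vals: np.ndarray) -> int:
    order = np.lexsort((pts[:, 0], -vals))  # by value desc, then protein asc
    return int(order[0])


def _polish(
    model: TPSLandscape, region: ConvexRegion, x0: np.ndarray
) -> tuple[np.ndarray, float] | None:
    A, b = region.halfspaces()
    cons = [{"type": "ineq", "fun": lambda x: -(A @ x + b)}]
    try:
        res = minimize(
            lambda x: -predict_surface(model, x)[0],
            x0,
            method="SLSQP",
            constraints=cons,
            options={"maxiter": 60, "ftol": 1e-10},
        )
    except Exception:  # pragma: no cover - optimizer failure is non-fatal
        return None
    if not np.all(region.contains(res.x, tol=1e-6)):
        return None
    x = np.clip(res.x, *region.bounding_box())
    return x, float(predict_surface(model, x)[0])


class _BootstrapMachine:
    """Fast refitting for stratified resamples on a fixed diet design.

    Stratified resampling within diets preserves both the knot locations
    and the per-knot replicate counts, so the penalized spline system can
    be factored once; each replicate only changes the right-hand side
    (the per-diet mean responses).  A cached kernel matrix over a dense
    search grid turns each replicate's optimum search into two matrix-vector
    products plus a local zoom.
    """

    def __init__(
        self,
        model: TPSLandscape,
        region: ConvexRegion,
        grid_resolution: int = 61,
        reselect_lambda: bool = False,
    ):
        self.model = model
        self.region = region
        z_knots = model._standardize(model.knots)
        self.system = _TPSSystem(z_knots, model.replicate_weights, model.lam)
        self.reselect = reselect_lambda
        if reselect_lambda:
            # pre-factor the whole GCV search grid: the penalized system
            # matrix depends only on the (resampling-invariant) design, so
            # per-replicate smoothing selection costs one back-substitution
            # per candidate lambda
            from .tps import _kernel_matrix as kmat, lambda_search_grid

            K = kmat(z_knots, z_knots)
            w = model.replicate_weights
            self._lam_systems = [
                _TPSSystem(z_knots, w, lam) for lam in lambda_search_grid(K, w)
            ]
            self._lam_traces = [s.hat_trace() for s in self._lam_systems]
            self._w = w
            self._w_tot = w.sum()
        lo, hi = region.bounding_box()
        ps = np.linspace(lo[0], hi[0], grid_resolution)
        cs = np.linspace(lo[1], hi[1], grid_resolution)
        P, C = np.meshgrid(ps, cs, indexing="ij")
        pts = np.column_stack([P.ravel(), C.ravel()])
        inside = region.contains(pts)
        self.grid_pts = np.vstack([pts[inside], region.vertices])
        z_grid = model._standardize(self.grid_pts)
        self.Phi_grid = _kernel_matrix(z_grid, z_knots)
        self.T_grid = np.column_stack([np.ones(len(z_grid)), z_grid])
        self.spacing = (hi - lo) / max(grid_resolution - 1, 1)

    def _solve(self, ybar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.reselect:
            return self.system.solve(ybar)
        m = len(ybar)
        best = None
        for sys, tr in zip(self._lam_systems, self._lam_traces):
            c, a = sys.solve(ybar)
            denom = (1.0 - tr / m) ** 2
            if denom <= 1e-12:
                continue
            resid = ybar - (sys.K @ c + sys.T @ a)
            score = (self._w * resid**2).sum() / self._w_tot / denom
            if best is None or score < best[0]:
                best = (score, c, a)
        return best[1], best[2]

    def optimum_for(self, ybar: np.ndarray) -> tuple[np.ndarray, float]:
        c, a = self._solve(ybar)
        vals = self.Phi_grid @ c + self.T_grid @ a
        idx = _lexi_best(self.grid_pts, vals)
        best_pt, best_val = self.grid_pts[idx], vals[idx]
        # two local zoom passes around the best cell, staying in the region
        half = self.spacing.copy()
        for _ in range(2):
            loc = best_pt + np.stack(
                np.meshgrid(
                    np.linspace(-half[0], half[0], 7),
                    np.linspace(-half[1], half[1], 7),
                    indexing="ij",
                ),
                axis=-1,
            ).reshape(-1, 2)
            loc = loc[self.region.contains(loc)]
            if len(loc) == 0:
                break
            z_loc = self.model._standardize(loc)
            v = (
                _kernel_matrix(z_loc, self.model._standardize(self.model.knots)) @ c
                + np.column_stack([np.ones(len(z_loc)), z_loc]) @ a
            )
            j = _lexi_best(loc, v)
            if v[j] > best_val:
                best_pt, best_val = loc[j], v[j]
            half /= 3.0
        return best_pt, float(best_val)


def bootstrap_optimum_region(
    records: Sequence[IndividualRecord],
    trait: str,
    sex: str,
    B: int,
    alpha: float = 0.05,
    seed: int = 0,
    lambda_spec: float | str = "gcv",
    grid_resolution: int = 61,
    lambda_reselect: bool | None = None,
) -> OptimumRegion:
    """Optimum of one trait's landscape with a stratified-bootstrap CR.

    Individuals are resampled with replacement within each diet, the spline
    is refitted and re-optimized within the diet hull.  When the smoothing
    parameter is GCV-selected, each replicate re-selects it as well (the
    replicate then mimics the full estimation pipeline, so the cloud carries
    smoothing-selection variability); pass ``lambda_reselect=False`` to
    freeze lambda at the point estimate's value instead, or give a numeric
    ``lambda_spec`` to fix it throughout.  The confidence region is the
    convex hull of the bootstrap optima after discarding the
    ``ceil(alpha * B)`` most outlying points (Mahalanobis distance from the
    coordinate-wise median).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    sel = [r for r in records if r.sex == sex]
    if not sel:
        raise ValidationError(f"no records for sex {sex!r}")
    locs = np.array([[r.diet.protein_pct, r.diet.carbohydrate_pct] for r in sel])
    y = np.array([r.trait_value(trait) for r in sel])

    model = fit_tps(locs, y, lambda_spec=lambda_spec)
    region = model.region()
    optimum, value = find_optimum(model, region)

    # group record indices by knot; stratified resampling preserves these
    knot_index = {tuple(k): i for i, k in enumerate(model.knots)}
    groups: list[list[int]] = [[] for _ in model.knots]
    for j, loc in enumerate(locs):
        groups[knot_index[tuple(loc)]].append(j)
    groups_arr = [np.array(g) for g in groups]

    if lambda_reselect is None:
        lambda_reselect = lambda_spec == "gcv"
    machine = _BootstrapMachine(
        model, region, grid_resolution, reselect_lambda=lambda_reselect
    )
    rng = np.random.default_rng(seed)
    optima = np.empty((B, 2))
    for b in range(B):
        for attempt in range(10):
            ybar = np.array(
                [y[rng.choice(g, size=len(g), replace=True)].mean() for g in groups_arr]
            )
            try:
                pt, _ = machine.optimum_for(ybar)
            except np.linalg.LinAlgError:  # pragma: no cover - guarded redraw
                logger.warning("degenerate bootstrap replicate %d redrawn", b)
                continue
            optima[b] = pt
            break
        else:  # pragma: no cover
            raise ValidationError("bootstrap replicate failed after 10 redraws")

    cr = _trimmed_hull(optima, alpha)
    return OptimumRegion(
        trait=trait,
        sex=sex,
        optimum=optimum,
        optimum_value=value,
        bootstrap_optima=optima,
        cr_polygon=cr,
        alpha=alpha,
        seed=seed,
    )


def _trimmed_hull(cloud: np.ndarray, alpha: float) -> np.ndarray:
    """Hull of the cloud after trimming the ceil(alpha*B) most outlying points.

    Outlyingness is Mahalanobis distance from the coordinate-wise median
    (anisotropy-aware, so elongated clouds are not over-trimmed along their
    major axis); for a degenerate cloud covariance it falls back to
    Euclidean distance.
    """
    n_trim = int(np.ceil(alpha * len(cloud)))
    med = np.median(cloud, axis=0)
    dev = cloud - med
    cov = np.cov(cloud.T) if len(cloud) > 2 else np.eye(2)
    if np.linalg.cond(cov) < 1e12 and np.all(np.isfinite(cov)):
        dist = np.einsum("ij,ij->i", dev @ np.linalg.inv(cov), dev)
    else:
        dist = np.linalg.norm(dev, axis=1)
    keep = cloud[np.argsort(dist, kind="stable")[: max(len(cloud) - n_trim, 1)]]
    return ConvexRegion.from_points(keep).vertices


def region_distance(a: OptimumRegion, b: OptimumRegion) -> DistanceComparison:
    """Mean pairwise Euclidean distance between two bootstrap clouds.

    The confidence bounds are the 2.5th and 97.5th percentiles of the
    pairwise-distance distribution; with more than 10^6 pairs a
    deterministic even subsample is used.
    """
    if a.alpha != b.alpha:
        raise ValidationError("regions must share the same alpha")
    ca, cb = a.bootstrap_optima, b.bootstrap_optima
    if len(ca) == 0 or len(cb) == 0:
        raise ValidationError("empty bootstrap cloud")
    n_pairs = len(ca) * len(cb)
    if n_pairs > MAX_DISTANCE_PAIRS:
        stride = int(np.ceil(n_pairs / MAX_DISTANCE_PAIRS))
        idx = np.arange(0, n_pairs, stride)
        ia, ib = idx // len(cb), idx % len(cb)
        dists = np.linalg.norm(ca[ia] - cb[ib], axis=1)
    else:
        dists = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2).ravel()
    lo, hi = np.percentile(dists, [2.5, 97.5])
    return DistanceComparison(
        d=float(dists.mean()), ci=(float(lo), float(hi)), n_pairs=len(dists)
    )


def pc_ratio(coordinate: Sequence[float]) -> str:
    """Normalized P:C ratio string for a nutrient-plane coordinate.

    The smaller side is scaled to 1 and the other side rounded to two
    decimals, e.g. (4.25, 67.70) -> ``"1:15.93"``.
    """
    p, c = float(coordinate[0]), float(coordinate[1])
    if p <= 0 or c <= 0:
        raise ValidationError("both coordinates must be positive to form a ratio")
    if p <= c:
        return f"1:{round(c / p, 2):g}"
    return f"{round(p / c, 2):g}:1"
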