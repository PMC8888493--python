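"""Thin-plate-spline nutrient landscapes with GCV smoothing selection.

The landscape for one trait is a penalized thin-plate spline over
(protein %, carbohydrate %).  Experiments place many individuals on few
distinct diets, so records are first collapsed to per-diet weighted means
(weights = replicate counts) and the spline is fitted to those knots via
the penalized weighted system

    minimize  sum_i w_i (ybar_i - f(x_i))^2 + lambda * c' K c

with f(x) = sum_j c_j Phi(|x - x_j|) + a0 + a1*P + a2*C and the radial
kernel Phi(r) = r^2 log r (Phi(0) = 0).  Stationarity gives the symmetric
saddle system

    [K + lambda * W^-1   T] [c]   [ybar]
    [T'                  0] [a] = [0]

whose lambda = 0 limit interpolates the knot means and whose large-lambda
limit is the weighted least-squares plane (the affine null space of the
penalty).  Coordinates are z-scored internally before kernel evaluation;
all public inputs and outputs stay on the raw percentage scale.

When ``lambda_spec="gcv"`` the smoothing parameter minimizes the weighted
generalized cross-validation score over a fixed 61-point log-spaced grid
anchored to a data-scale pivot, which keeps the selection reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import ConvexRegion

LAMBDA_GRID_SIZE = 61
LAMBDA_LOG_RANGE = (-8.0, 4.0)  # decades around the pivot


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """Phi(r) = r^2 log r with the removable singularity closed at 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return _tps_kernel(d)


@dataclass
class TPSLandscape:
    """A fitted thin-plate-spline surface over the nutrient plane."""

    knots: np.ndarray                 # (m, 2) raw-scale coordinates
    knot_values: np.ndarray           # per-knot weighted mean responses
    replicate_weights: np.ndarray     # per-knot replicate counts
    kernel_weights: np.ndarray        # c, one per knot
    affine_coeffs: np.ndarray         # (a0, aP, aC) on standardized scale
    lam: float                        # smoothing parameter actually used
    effective_df: float
    gcv_score: float
    coordinate_scaling: dict[str, float] = field(default_factory=dict)

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def _standardize(self, points: np.ndarray) -> np.ndarray:
        s = self.coordinate_scaling
        return (points - [s["mean_P"], s["mean_C"]]) / [s["sd_P"], s["sd_C"]]

    def region(self) -> ConvexRegion:
        """Convex hull of the knot (diet) coordinates."""
        return ConvexRegion.from_points(self.knots)


class _TPSSystem:
    """Factored saddle system for a fixed knot set, weights and lambda.

    Refitting under resampling that preserves the design (same diets, same
    per-diet counts) only changes the right-hand side, so the factorization
    is computed once and reused.
    """

    def __init__(self, z_knots: np.ndarray, weights: np.ndarray, lam: float):
        m = len(z_knots)
        K = _kernel_matrix(z_knots, z_knots)
        T = np.column_stack([np.ones(m), z_knots])
        M = np.zeros((m + 3, m + 3))
        M[:m, :m] = K + lam * np.diag(1.0 / weights)
        M[:m, m:] = T
        M[m:, :m] = T.T
        self.m = m
        self.K = K
        self.T = T
        self.weights = weights
        self.lam = lam
        self._lu = None
        self._trace = None
        self.M = M

    def solve(self, ybar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from scipy.linalg import lu_factor, lu_solve

        if self._lu is None:
            self._lu = lu_factor(self.M)
        rhs = np.concatenate([ybar, np.zeros(3)])
        sol = lu_solve(self._lu, rhs)
        return sol[: self.m], sol[self.m :]

    def hat_trace(self) -> float:
        """Trace of the smoother matrix at the knots (cached)."""
        from scipy.linalg import lu_factor, lu_solve

        if getattr(self, "_trace", None) is None:
            if self._lu is None:
                self._lu = lu_factor(self.M)
            rhs = np.vstack([np.eye(self.m), np.zeros((3, self.m))])
            Z = lu_solve(self._lu, rhs)
            A = self.K @ Z[: self.m] + self.T @ Z[self.m :]
            self._trace = float(np.trace(A))
        return self._trace

    def hat_trace_and_fit(self, ybar: np.ndarray) -> tuple[float, np.ndarray]:
        """Trace of the smoother matrix at the knots, and fitted values."""
        c, a = self.solve(ybar)
        return self.hat_trace(), self.K @ c + self.T @ a


def collapse_to_knots(
    locations: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse records to distinct locations: (knots, weighted means, counts)."""
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    knots, inverse = np.unique(locations, axis=0, return_inverse=True)
    m = len(knots)
    counts = np.bincount(inverse, minlength=m).astype(float)
    sums = np.bincount(inverse, weights=values, minlength=m)
    return knots, sums / counts, counts


def _lambda_pivot(K: np.ndarray, weights: np.ndarray) -> float:
    """Data-scale anchor so the search grid spans under- to over-smoothing."""
    off = np.abs(K[~np.eye(len(K), dtype=bool)])
    scale = float(off.mean()) if off.size else 1.0
    return max(scale * float(weights.mean()), 1e-12)


def lambda_search_grid(K: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """The fixed log-spaced lambda grid used by GCV selection."""
    return _lambda_pivot(K, weights) * np.logspace(*LAMBDA_LOG_RANGE, LAMBDA_GRID_SIZE)


def fit_tps(
    locations: np.ndarray,
    values: np.ndarray,
    lambda_spec: float | str = "gcv",
    weights: np.ndarray | None = None,
) -> TPSLandscape:
    """Fit a thin-plate-spline landscape to records at 2-D locations.

    Parameters
    ----------
    locations, values:
        One entry per record; replicated locations are collapsed to
        weighted-mean knots internally.
    lambda_spec:
        A nonnegative smoothing parameter, or ``"gcv"`` to minimize the
        weighted generalized cross-validation score over a log-spaced grid.
    weights:
        Optional per-record weights (defaults to 1 each, so knot weights
        equal replicate counts).
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    if locations.ndim != 2 or locations.shape[1] != 2:
        raise ValidationError("locations must be an (n, 2) array")
    if len(locations) != len(values):
        raise ValidationError("locations and values must have equal length")
    if weights is None:
        knots, ybar, counts = collapse_to_knots(locations, values)
    else:
        weights = np.asarray(weights, dtype=float)
        knots, inverse = np.unique(locations, axis=0, return_inverse=True)
        counts = np.bincount(inverse, weights=weights, minlength=len(knots))
        sums = np.bincount(inverse, weights=weights * values, minlength=len(knots))
        ybar = sums / counts
    m = len(knots)
    if m < 4:
        raise ValidationError("need at least 4 distinct locations")
    if np.linalg.matrix_rank(knots - knots[0], tol=1e-10) < 2:
        raise ValidationError("locations are collinear; the surface is unidentified")

    mean = knots.mean(axis=0)
    sd = knots.std(axis=0, ddof=1)
    z_knots = (knots - mean) / sd
    scaling = {"mean_P": mean[0], "mean_C": mean[1], "sd_P": sd[0], "sd_C": sd[1]}

    K = _kernel_matrix(z_knots, z_knots)
    w_tot = counts.sum()

    def gcv_at(lam: float) -> tuple[float, float, _TPSSystem]:
        sys = _TPSSystem(z_knots, counts, lam)
        tr, fitted = sys.hat_trace_and_fit(ybar)
        resid = ybar - fitted
        denom = (1.0 - tr / m) ** 2
        if denom <= 1e-12:
            score = np.inf
        else:
            score = float((counts * resid**2).sum() / w_tot / denom)
        return score, tr, sys

    if isinstance(lambda_spec, str):
        if lambda_spec != "gcv":
            raise ValidationError(f"unknown lambda_spec {lambda_spec!r}")
        grid = lambda_search_grid(K, counts)
        best = None
        for lam in grid:
            score, tr, sys = gcv_at(lam)
            if best is None or score < best[0]:
                best = (score, tr, sys, lam)
        gcv_score, eff_df, system, lam = best
    else:
        lam = float(lambda_spec)
        if lam < 0:
            raise ValidationError("lambda must be nonnegative")
        gcv_score, eff_df, system = gcv_at(lam)
        if not np.isfinite(gcv_score):
            gcv_score = 0.0  # interpolation limit: GCV undefined, residuals zero

    c, a = system.solve(ybar)
    return TPSLandscape(
        knots=knots,
        knot_values=ybar,
        replicate_weights=counts,
        kernel_weights=c,
        affine_coeffs=a,
        lam=float(lam),
        effective_df=float(eff_df),
        gcv_score=float(gcv_score),
        coordinate_scaling=scaling,
    )


def predict_surface(model: TPSLandscape, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted landscape at raw-scale (P, C) points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    z = model._standardize(points)
    z_knots = model._standardize(model.knots)
    Phi = _kernel_matrix(z, z_knots)
    T = np.column_stack([np.ones(len(z)), z])
    return Phi @ model.kernel_weights + T @ model.affine_coeffs


def effective_df_profile(
    model: TPSLandscape, lambdas: Sequence[float]
) -> np.ndarray:
    """Effective degrees of freedom of the smoother at each lambda."""
    z_knots = model._standardize(model.knots)
    out = []
    for lam in lambdas:
        sys = _TPSSystem(z_knots, model.replicate_weights, float(lam))
        tr, _ = sys.hat_trace_and_fit(model.knot_values)
        out.append(tr)
    return np.array(out)


def contour_plot(
    model: TPSLandscape,
    region: ConvexRegion,
    path: str,
    resolution: int = 100,
    title: str | None = None,
) -> None:
    """Render the landscape as filled contours over the region (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = export_landscape_grid(model, resolution, region)
    P = grid["P"].to_numpy().reshape(resolution, resolution)
    C = grid["C"].to_numpy().reshape(resolution, resolution)
    V = np.where(
        grid["masked"].to_numpy(), np.nan, grid["value"].to_numpy()
    ).reshape(resolution, resolution)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(P, C, V, levels=12, cmap="viridis")
    ax.plot(model.knots[:, 0], model.knots[:, 1], "k.", ms=3)
    fig.colorbar(cs, ax=ax)
    ax.set_xlabel("protein (% diet mass)")
    ax.set_ylabel("carbohydrate (% diet mass)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def export_landscape_grid(
    model: TPSLandscape, resolution: int, region: ConvexRegion
) -> pd.DataFrame:
    """Evaluate the landscape on a rectangular grid over the region's bbox.

    Returns a long-format frame with columns P, C, value, masked; cells
    outside the (convex) region are masked but still evaluated.
    """
    if resolution < 2:
        raise ValidationError("resolution must be >= 2")
    lo, hi = region.bounding_box()
    if np.any(hi <= lo):
        raise ValidationError("degenerate region: bounding box has no area")
    ps = np.linspace(lo[0], hi[0], resolution)
    cs = np.linspace(lo[1], hi[1], resolution)
    P, C = np.meshgrid(ps, cs, indexing="ij")
    pts = np.column_stack([P.ravel(), C.ravel()])
    values = predict_surface(model, pts)
    inside = region.contains(pts)
    return pd.DataFrame(
        {"P": pts[:, 0], "C": pts[:, 1], "value": values, "masked": ~inside}
    )
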