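"""Convex search regions over the nutrient plane."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

from .errors import ValidationError


class ConvexRegion:
    """A convex polygon in (protein %, carbohydrate %) coordinates.

    Degenerate regions (a single point, or collinear points) are supported
    so that optimum searches can be collapsed deliberately; full-dimensional
    regions carry half-space equations from a convex hull.
    """

    def __init__(self, vertices: np.ndarray):
        vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
        if vertices.shape[1] != 2 or len(vertices) == 0:
            raise ValidationError("vertices must be an (m, 2) array")
        uniq = np.unique(vertices, axis=0)
        if len(uniq) == 1:
            self.vertices = uniq
            self._hull = None
        elif np.linalg.matrix_rank(uniq - uniq[0], tol=1e-10) < 2:
            # collinear: keep the two extreme points of the segment
            t = (uniq - uniq[0]) @ (uniq[-1] - uniq[0])
            self.vertices = uniq[[np.argmin(t), np.argmax(t)]]
            self._hull = None
        else:
            hull = ConvexHull(uniq)
            self.vertices = uniq[hull.vertices]
            self._hull = hull

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ConvexRegion":
        """Convex hull of a point cloud."""
        return cls(points)

    @property
    def is_degenerate(self) -> bool:
        return self._hull is None

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside (or on the boundary of) the region."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._hull is None:
            if len(self.vertices) == 1:
                return np.all(np.abs(points - self.vertices[0]) <= tol, axis=1)
            a, b = self.vertices
            ab = b - a
            t = np.clip((points - a) @ ab / (ab @ ab), 0, 1)
            proj = a + np.outer(t, ab)
            return np.linalg.norm(points - proj, axis=1) <= tol
        A = self._hull.equations[:, :2]
        b = self._hull.equations[:, 2]
        return np.all(points @ A.T + b <= tol, axis=1)

    def halfspaces(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) with interior defined by A @ x + b <= 0."""
        if self._hull is None:
            raise ValidationError("degenerate region has no half-space form")
        return self._hull.equations[:, :2], self._hull.equations[:, 2]

    def area(self) -> float:
        return 0.0 if self._hull is None else float(self._hull.volume)
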