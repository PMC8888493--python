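"""Between-group comparison of nutrient effects.

Two fitted datasets (two sexes on one trait, or two traits within a sex)
are compared by a sequential model-building procedure: the standardized
responses are stacked with a group indicator and three nested partial
F-tests ask, in order, whether the groups differ in their linear,
quadratic, and correlational nutrient effects.  The staged complete models
have 6, 10 and 12 parameters, so with two groups of n records each the
denominator degrees of freedom are 2n-6, 2n-10 and 2n-12.

Orientation differences between two traits' nutritional vectors are
summarized by the unsigned angle theta between the linear-gradient
vectors, with percentile bootstrap confidence intervals from stratified
(within-diet) resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DesignError, ValidationError
from .records import IndividualRecord
from .surface import zscore

logger = logging.getLogger(__name__)

STAGES = ("linear", "quadratic", "correlational")


@dataclass(frozen=True)
class TraitDataset:
    """One group's data for comparison: coordinates, response, and a label."""

    label: str
    P: np.ndarray
    C: np.ndarray
    y: np.ndarray

    @classmethod
    def from_records(
        cls, records: Sequence[IndividualRecord], trait: str, sex: str, label: str | None = None
    ) -> "TraitDataset":
        sel = [r for r in records if r.sex == sex]
        if not sel:
            raise ValidationError(f"no records for sex {sex!r}")
        return cls(
            label=label or f"{sex} {trait}",
            P=np.array([r.diet.protein_pct for r in sel]),
            C=np.array([r.diet.carbohydrate_pct for r in sel]),
            y=np.array([r.trait_value(trait) for r in sel]),
        )

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class SequentialTestResult:
    """One stage of the sequential comparison (a nested partial F-test)."""

    stage: str
    ss_reduced: float
    ss_complete: float
    df1: int
    df2: int
    f_value: float
    p_value: float


@dataclass
class AngleComparison:
    """Angle between two nutritional vectors with a bootstrap CI."""

    theta_deg: float
    ci: tuple[float, float]
    B: int
    seed: int


def _stacked_design(a: TraitDataset, b: TraitDataset) -> dict[str, np.ndarray]:
    """Standardize and stack two datasets with a group indicator.

    Each group's response is z-scored internally so the groups sit on a
    comparable scale; the nutrient coordinates are z-scored on the pooled
    (shared) diet design.
    """
    zy_a, _, _ = zscore(a.y)
    zy_b, _, _ = zscore(b.y)
    y = np.concatenate([zy_a, zy_b])
    P_raw = np.concatenate([a.P, b.P])
    C_raw = np.concatenate([a.C, b.C])
    zP, _, _ = zscore(P_raw)
    zC, _, _ = zscore(C_raw)
    g = np.concatenate([np.zeros(a.n), np.ones(b.n)])
    return {"y": y, "P": zP, "C": zC, "g": g}


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("rank-deficient comparison design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _stage_columns(d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    one = np.ones_like(d["y"])
    P, C, g = d["P"], d["C"], d["g"]
    return {
        "1": one, "g": g,
        "P": P, "C": C, "gP": g * P, "gC": g * C,
        "PP": P**2, "CC": C**2, "gPP": g * P**2, "gCC": g * C**2,
        "PC": P * C, "gPC": g * P * C,
    }


# column lists for the reduced/complete model at each stage
_STAGE_MODELS = {
    "linear": (
        ["1", "g", "P", "C"],
        ["1", "g", "P", "C", "gP", "gC"],
    ),
    "quadratic": (
        ["1", "g", "P", "C", "gP", "gC", "PP", "CC"],
        ["1", "g", "P", "C", "gP", "gC", "PP", "CC", "gPP", "gCC"],
    ),
    "correlational": (
        ["1", "g", "P", "C", "gP", "gC", "PP", "CC", "gPP", "gCC", "PC"],
        ["1", "g", "P", "C", "gP", "gC", "PP", "CC", "gPP", "gCC", "PC", "gPC"],
    ),
}


def _partial_f(
    cols: dict[str, np.ndarray],
    y: np.ndarray,
    reduced: list[str],
    complete: list[str],
) -> tuple[float, float, int, int, float, float]:
    Xr = np.column_stack([cols[c] for c in reduced])
    Xc = np.column_stack([cols[c] for c in complete])
    ss_r = _rss(Xr, y)
    ss_c = _rss(Xc, y)
    df1 = len(complete) - len(reduced)
    df2 = len(y) - len(complete)
    f = max(ss_r - ss_c, 0.0) / df1 / (ss_c / df2)
    p = float(stats.f.sf(f, df1, df2))
    return ss_r, ss_c, df1, df2, f, p


def sequential_compare(
    a: TraitDataset, b: TraitDataset
) -> list[SequentialTestResult]:
    """Three-stage nested comparison of nutrient effects between two groups.

    Stage 1 tests group-specific linear terms against common ones; stage 2
    adds the quadratic terms; stage 3 the correlational (P*C) term.  Both
    the reduced and the complete model at each stage inherit the previous
    stage's group-specific structure.
    """
    d = _stacked_design(a, b)
    cols = _stage_columns(d)
    out = []
    for stage in STAGES:
        reduced, complete = _STAGE_MODELS[stage]
        ss_r, ss_c, df1, df2, f, p = _partial_f(cols, d["y"], reduced, complete)
        out.append(
            SequentialTestResult(
                stage=stage, ss_reduced=ss_r, ss_complete=ss_c,
                df1=df1, df2=df2, f_value=f, p_value=p,
            )
        )
    return out


_UNIVARIATE_TERMS = {
    ("linear", "P"): "gP",
    ("linear", "C"): "gC",
    ("quadratic", "P"): "gPP",
    ("quadratic", "C"): "gCC",
    ("correlational", "PC"): "gPC",
}


def univariate_followup(
    a: TraitDataset, b: TraitDataset, stage: str, nutrient: str
) -> tuple[float, float]:
    """Single-nutrient follow-up at a stage: test one group x term column.

    The complete model is the stage's complete model; the reduced model
    drops only the group-specific column for the requested nutrient, so
    df1 = 1 and df2 matches the stage-level test.
    """
    key = (stage, nutrient)
    if key not in _UNIVARIATE_TERMS:
        raise ValidationError(f"unknown stage/nutrient combination {key!r}")
    term = _UNIVARIATE_TERMS[key]
    d = _stacked_design(a, b)
    cols = _stage_columns(d)
    _, complete = _STAGE_MODELS[stage]
    reduced = [c for c in complete if c != term]
    _, _, _, _, f, p = _partial_f(cols, d["y"], reduced, complete)
    return f, p


def angle_between(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Unsigned angle in degrees, in [0, 180], between two 2-vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("angle with a zero vector is undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _linear_vector_ols(ds: TraitDataset) -> np.ndarray:
    """(betaP, betaC) from the full second-order fit, standardized in-dataset."""
    zy, _, _ = zscore(ds.y)
    zP, _, _ = zscore(ds.P)
    zC, _, _ = zscore(ds.C)
    X = np.column_stack([np.ones(ds.n), zP, zC, zP**2, zC**2, zP * zC])
    beta, *_ = np.linalg.lstsq(X, zy, rcond=None)
    return beta[1:3]


def bootstrap_angle(
    a: TraitDataset, b: TraitDataset, B: int, seed: int = 0
) -> AngleComparison:
    """Bootstrap CI for the angle between two traits' nutritional vectors.

    Each replicate resamples records with replacement independently within
    each dataset, stratified by diet coordinate, refits the full response
    surface, and recomputes the angle between the linear vectors.  The
    point estimate uses the full-data fits; the CI is percentile-based.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    theta = angle_between(_linear_vector_ols(a), _linear_vector_ols(b))
    rng = np.random.default_rng(seed)
    groups_a = _diet_groups(a)
    groups_b = _diet_groups(b)
    angles = np.empty(B)
    for rep in range(B):
        for attempt in range(10):
            try:
                va = _linear_vector_ols(_resample(a, groups_a, rng))
                vb = _linear_vector_ols(_resample(b, groups_b, rng))
                angles[rep] = angle_between(va, vb)
            except (ValidationError, np.linalg.LinAlgError):
                logger.warning("degenerate angle bootstrap replicate %d redrawn", rep)
                continue
            break
        else:  # pragma: no cover
            raise ValidationError("angle bootstrap failed after 10 redraws")
    lo, hi = np.percentile(angles, [2.5, 97.5])
    return AngleComparison(
        theta_deg=theta, ci=(float(lo), float(hi)), B=B, seed=seed
    )


def _diet_groups(ds: TraitDataset) -> list[np.ndarray]:
    coords = np.column_stack([ds.P, ds.C])
    _, inverse = np.unique(coords, axis=0, return_inverse=True)
    return [np.flatnonzero(inverse == k) for k in range(inverse.max() + 1)]


def _resample(
    ds: TraitDataset, groups: list[np.ndarray], rng: np.random.Generator
) -> TraitDataset:
    idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
    return TraitDataset(label=ds.label, P=ds.P[idx], C=ds.C[idx], y=ds.y[idx])
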