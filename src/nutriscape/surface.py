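"""Second-order response-surface estimation on standardized coordinates.

For each trait x sex the trait and both nutrient coordinates are z-scored,
then the trait is regressed by ordinary least squares on the linear (P, C),
quadratic (P^2, C^2) and correlational (P*C) terms with an intercept.  The
five slope coefficients are the standardized nutritional gradients; the
linear pair (betaP, betaC) is the trait's nutritional vector.

Quadratic coefficients are reported as the raw OLS coefficients on the
squared standardized predictors (no x2 curvature correction); this is
recorded in the fit metadata so either convention can be derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateScaleError, DesignError, ValidationError
from .records import IndividualRecord

TERMS = ("P", "C", "PP", "CC", "PC")
N_PARAMS = 6  # intercept + five surface terms


def zscore(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, sample SD 1; returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two values to standardize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise DegenerateScaleError("cannot standardize a constant variable")
    return (x - mean) / sd, mean, sd


def design_matrix(z_p: np.ndarray, z_c: np.ndarray) -> np.ndarray:
    """Full second-order design: [1, P, C, P^2, C^2, P*C] columns."""
    return np.column_stack(
        [np.ones_like(z_p), z_p, z_c, z_p**2, z_c**2, z_p * z_c]
    )


@dataclass
class TraitSurfaceFit:
    """Fitted second-order surface for one trait in one sex.

    All coefficient maps are keyed by term name: ``P``, ``C`` (linear),
    ``PP``, ``CC`` (quadratic), ``PC`` (correlational).
    """

    trait: str
    sex: str
    n: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    residual_df: int
    residual_sum_squares: float
    intercept: float
    standardization: dict[str, float] = field(default_factory=dict)
    quadratic_convention: str = "raw-ols"  # not doubled

    def linear_vector(self) -> np.ndarray:
        return np.array([self.coefficients["P"], self.coefficients["C"]])


def _extract_arrays(
    records: Sequence[IndividualRecord], trait: str, sex: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sel = [r for r in records if r.sex == sex]
    if not sel:
        raise ValidationError(f"no records for sex {sex!r}")
    p = np.array([r.diet.protein_pct for r in sel])
    c = np.array([r.diet.carbohydrate_pct for r in sel])
    y = np.array([r.trait_value(trait) for r in sel])
    return p, c, y


def fit_response_surface(
    records: Sequence[IndividualRecord], trait: str, sex: str
) -> TraitSurfaceFit:
    """OLS fit of the standardized trait on the second-order nutrient terms.

    Two-sided p-values come from the t distribution with ``n - 6`` residual
    degrees of freedom.
    """
    p_raw, c_raw, y_raw = _extract_arrays(records, trait, sex)
    n = len(y_raw)
    if n < N_PARAMS + 1:
        raise ValidationError(f"need at least {N_PARAMS + 1} records, got {n}")
    z_p, mean_p, sd_p = zscore(p_raw)
    z_c, mean_c, sd_c = zscore(c_raw)
    z_y, mean_y, sd_y = zscore(y_raw)
    X = design_matrix(z_p, z_c)
    if np.linalg.matrix_rank(X) < N_PARAMS:
        raise DesignError(
            "rank-deficient design: the diets sampled do not identify all "
            "second-order terms"
        )
    res = sm.OLS(z_y, X).fit()
    coefs = dict(zip(TERMS, res.params[1:]))
    return TraitSurfaceFit(
        trait=trait,
        sex=sex,
        n=n,
        coefficients=coefs,
        standard_errors=dict(zip(TERMS, res.bse[1:])),
        t_values=dict(zip(TERMS, res.tvalues[1:])),
        p_values=dict(zip(TERMS, res.pvalues[1:])),
        residual_df=int(res.df_resid),
        residual_sum_squares=float(res.ssr),
        intercept=float(res.params[0]),
        standardization={
            "mean_P": mean_p, "sd_P": sd_p,
            "mean_C": mean_c, "sd_C": sd_c,
            "mean_y": mean_y, "sd_y": sd_y,
        },
    )


def linear_effect_vector(fit: TraitSurfaceFit) -> np.ndarray:
    """The nutritional vector (betaP, betaC) of a fitted surface."""
    return fit.linear_vector()


def surface_table(fits: Sequence[TraitSurfaceFit]) -> pd.DataFrame:
    """Long-format gradient table: one row per trait x sex x term."""
    rows = [
        {
            "trait": f.trait,
            "sex": f.sex,
            "term": term,
            "coefficient": f.coefficients[term],
            "SE": f.standard_errors[term],
            "t": f.t_values[term],
            "p": f.p_values[term],
            "residual_df": f.residual_df,
        }
        for f in fits
        for term in TERMS
    ]
    return pd.DataFrame(rows)
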