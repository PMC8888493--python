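"""Synthetic two-nutrient life-history experiments.

Generates individual-level lifespan and reproduction data over a diet grid
with the structure the downstream response-surface analysis assumes: each
(trait, sex) follows a true quadratic surface on standardized nutrient
coordinates, lifespans are noisy around their surface value, and
reproduction is counted in 5-day assays whose number is set by lifespan
(so longer-lived individuals mechanically accrue more total output).

The default scenario mirrors the reference experimental design: 10 P:C
ratios x 4 dilutions = 40 diets, 20 flies per sex per diet (N = 1600),
protein-averse lifespan surfaces in both sexes, protein-averse male
reproduction and protein-hungry female reproduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .diets import DEFAULT_RATIOS, DEFAULT_TOTALS, DietSpec, build_diet_grid
from .errors import ConfigurationError, ValidationError
from .records import ASSAY_INTERVAL_DAYS, IndividualRecord

logger = logging.getLogger(__name__)

NOISE_FAMILIES = ("gaussian", "negative-binomial", "poisson")

#: Minimum per-assay mean rate; keeps count distributions well-defined
#: where a fitted quadratic surface dips below zero at grid extremes.
RATE_FLOOR = 0.05


@dataclass(frozen=True)
class TrueSurfaceParams:
    """True quadratic surface for one (trait, sex), on standardized coordinates.

    ``trait`` is either ``"lifespan"`` (surface value in days) or
    ``"assay_rate"`` (expected reproduction count per 5-day assay).  The
    surface is evaluated on z-scored protein/carbohydrate percentages of
    the diet grid in use.  ``noise_scale`` is the Gaussian SD for lifespan,
    or the negative-binomial dispersion (smaller = more overdispersed) for
    counts; it is ignored for Poisson noise.
    """

    trait: str
    sex: str
    beta0: float
    betaP: float
    betaC: float
    betaPP: float
    betaCC: float
    betaPC: float
    noise_family: str = "gaussian"
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_family not in NOISE_FAMILIES:
            raise ValidationError(f"unknown noise family {self.noise_family!r}")
        if not self.noise_scale >= 0:
            raise ValidationError("noise_scale must be nonnegative")

    def evaluate(self, z_p: np.ndarray, z_c: np.ndarray) -> np.ndarray:
        """Surface mean at standardized coordinates (vectorized)."""
        return (
            self.beta0
            + self.betaP * z_p
            + self.betaC * z_c
            + self.betaPP * z_p**2
            + self.betaCC * z_c**2
            + self.betaPC * z_p * z_c
        )


def default_surface_params() -> list[TrueSurfaceParams]:
    """Study-condition surfaces for the reference design.

    Sign structure: protein shortens and carbohydrate lengthens life in
    both sexes (more steeply in males); male per-assay siring is maximised
    on carbohydrate-rich food; female per-assay fecundity peaks near a
    balanced protein:carbohydrate blend.  Lifespan means are in days
    (Gaussian noise, SD 8); per-assay reproduction means are counts
    (negative binomial, dispersion 2).
    """
    return [
        TrueSurfaceParams("lifespan", "male", 45.0, -7.0, 7.0, 1.5, -4.5, -4.0,
                          "gaussian", 8.0),
        TrueSurfaceParams("lifespan", "female", 50.0, -4.5, 5.0, 1.0, -3.8, -2.0,
                          "gaussian", 8.0),
        TrueSurfaceParams("assay_rate", "male", 12.0, -2.5, 2.2, 0.3, -1.4, -1.5,
                          "negative-binomial", 2.0),
        TrueSurfaceParams("assay_rate", "female", 40.0, 8.0, 7.0, -9.0, -8.0, 1.0,
                          "negative-binomial", 2.0),
    ]


@dataclass
class Scenario:
    """A full simulation scenario: grid, sample size, surfaces, seed."""

    ratios: Sequence[tuple[float, float]] = field(default_factory=lambda: list(DEFAULT_RATIOS))
    totals: Sequence[float] = field(default_factory=lambda: list(DEFAULT_TOTALS))
    n_per_diet_per_sex: int = 20
    surfaces: list[TrueSurfaceParams] = field(default_factory=default_surface_params)
    seed: int = 0

    def grid(self) -> list[DietSpec]:
        return build_diet_grid(self.ratios, self.totals)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "ratios": [list(r) for r in self.ratios],
            "totals": list(self.totals),
            "n_per_diet_per_sex": self.n_per_diet_per_sex,
            "seed": self.seed,
            "surfaces": [
                {
                    "trait": s.trait, "sex": s.sex,
                    "beta0": s.beta0, "betaP": s.betaP, "betaC": s.betaC,
                    "betaPP": s.betaPP, "betaCC": s.betaCC, "betaPC": s.betaPC,
                    "noise_family": s.noise_family, "noise_scale": s.noise_scale,
                }
                for s in self.surfaces
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        payload = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                ratios=[tuple(r) for r in payload["ratios"]],
                totals=list(payload["totals"]),
                n_per_diet_per_sex=int(payload["n_per_diet_per_sex"]),
                seed=int(payload.get("seed", 0)),
                surfaces=[TrueSurfaceParams(**s) for s in payload["surfaces"]],
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"bad scenario file {path}: {exc}") from exc


def _standardized_grid_coords(grid: Sequence[DietSpec]) -> tuple[np.ndarray, np.ndarray]:
    p = np.array([d.protein_pct for d in grid])
    c = np.array([d.carbohydrate_pct for d in grid])
    sd_p = p.std(ddof=1) if len(p) > 1 else 1.0
    sd_c = c.std(ddof=1) if len(c) > 1 else 1.0
    return (p - p.mean()) / (sd_p or 1.0), (c - c.mean()) / (sd_c or 1.0)


def _draw_counts(
    rng: np.random.Generator, mean: float, n: int, family: str, scale: float
) -> np.ndarray:
    mean = max(mean, RATE_FLOOR)
    if family == "poisson":
        return rng.poisson(mean, size=n)
    if family == "negative-binomial":
        if scale == 0:
            # dispersion -> infinity limit is Poisson; 0 means "no extra noise"
            return np.full(n, round(mean), dtype=int)
        k = scale
        return rng.negative_binomial(k, k / (k + mean), size=n)
    # gaussian family for counts: rounded and clipped at zero
    draw = rng.normal(mean, scale, size=n)
    return np.maximum(np.rint(draw), 0).astype(int)


def simulate_experiment(
    grid: Sequence[DietSpec],
    n_per_diet_per_sex: int,
    params: Sequence[TrueSurfaceParams],
    seed: int,
) -> list[IndividualRecord]:
    """Simulate one experiment: every diet x sex gets ``n`` individuals.

    Lifespans are drawn around each diet's lifespan-surface value
    (zero-truncated Gaussian for the gaussian family); each individual then
    receives one reproduction count per 5-day assay it survives to, drawn
    from its sex's per-assay rate surface.  Individuals dying before their
    first assay carry no reproductive data and are dropped (logged).
    Identical seeds give identical output.
    """
    if n_per_diet_per_sex < 1:
        raise ValidationError("n_per_diet_per_sex must be >= 1")
    by_key = {(p.trait, p.sex): p for p in params}
    for sex in ("male", "female"):
        for trait in ("lifespan", "assay_rate"):
            if (trait, sex) not in by_key:
                raise ConfigurationError(f"missing surface parameters for ({trait}, {sex})")

    z_p, z_c = _standardized_grid_coords(grid)
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    n_dropped = 0
    counter = 0
    for i, diet in enumerate(grid):
        for sex in ("male", "female"):
            ls_par = by_key[("lifespan", sex)]
            rate_par = by_key[("assay_rate", sex)]
            ls_mean = float(ls_par.evaluate(z_p[i], z_c[i]))
            rate_mean = float(rate_par.evaluate(z_p[i], z_c[i]))
            lifespans = _draw_lifespans(rng, ls_mean, ls_par, n_per_diet_per_sex)
            for ls in lifespans:
                counter += 1
                n_assays = int(ls // ASSAY_INTERVAL_DAYS)
                counts = _draw_counts(
                    rng, rate_mean, n_assays, rate_par.noise_family, rate_par.noise_scale
                )
                if n_assays == 0:
                    n_dropped += 1
                    continue
                records.append(
                    IndividualRecord(
                        individual_id=f"ind{counter:06d}",
                        sex=sex,
                        diet=diet,
                        lifespan_days=float(ls),
                        assay_counts=tuple(int(c) for c in counts),
                    )
                )
    if n_dropped:
        logger.info(
            "dropped %d individual(s) that died before their first assay", n_dropped
        )
    return records


def _draw_lifespans(
    rng: np.random.Generator, mean: float, par: TrueSurfaceParams, n: int
) -> np.ndarray:
    mean = max(mean, 1e-6)
    if par.noise_family != "gaussian":
        raise ConfigurationError("lifespan surfaces support gaussian noise only")
    if par.noise_scale == 0:
        return np.full(n, mean)
    # zero-truncated Gaussian keeps lifespans positive without biasing the
    # bulk of the distribution at realistic noise levels
    a = (0.0 - mean) / par.noise_scale
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=par.noise_scale, size=n, random_state=rng
    )
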