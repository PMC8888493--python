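"""End-to-end orchestration: data in, full report bundle out.

One call runs every stage of the analysis for a dataset (read from CSV or
simulated from a scenario): per trait x sex the second-order gradient fit,
the thin-plate-spline landscape with its exported grid, and the bootstrap
optimum region with its P:C ratio; then, per configured pair, the
sequential partial-F comparison with univariate follow-ups, the angle
between nutritional vectors, and the distance between optimum regions.
All tables are written as TSV and all metadata as JSON; a fixed seed makes
the whole bundle reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    AngleComparison,
    SequentialTestResult,
    TraitDataset,
    bootstrap_angle,
    sequential_compare,
    univariate_followup,
)
from .errors import ConfigurationError, ValidationError
from .optima import (
    DistanceComparison,
    OptimumRegion,
    bootstrap_optimum_region,
    pc_ratio,
    region_distance,
)
from .records import IndividualRecord, read_records, write_records
from .simulate import Scenario, simulate_experiment
from .surface import TraitSurfaceFit, fit_response_surface, surface_table
from .tps import TPSLandscape, export_landscape_grid, fit_tps

logger = logging.getLogger(__name__)

TRAITS = ("lifespan", "daily_re", "total_re")
FLOAT_FMT = "%.10g"

DatasetKey = tuple[str, str]  # (trait, sex)


def default_comparisons() -> list[tuple[DatasetKey, DatasetKey]]:
    """Nine canonical pairs: 3 between-sex plus 3 within-sex trait pairs per sex."""
    pairs: list[tuple[DatasetKey, DatasetKey]] = [
        ((t, "male"), (t, "female")) for t in TRAITS
    ]
    for sex in ("male", "female"):
        pairs += [
            (("lifespan", sex), ("daily_re", sex)),
            (("lifespan", sex), ("total_re", sex)),
            (("daily_re", sex), ("total_re", sex)),
        ]
    return pairs


@dataclass
class AnalysisConfig:
    """Everything one full run needs."""

    csv: str | Path | None = None
    assays_csv: str | Path | None = None
    scenario: Scenario | str | Path | None = None
    traits: Sequence[str] = TRAITS
    sexes: Sequence[str] = ("male", "female")
    comparisons: list[tuple[DatasetKey, DatasetKey]] | None = None
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    outdir: str | Path | None = None
    grid_resolution: int = 100
    lambda_spec: float | str = "gcv"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.csv is None and self.scenario is None:
            raise ConfigurationError("either a CSV path or a scenario is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        if "comparisons" in payload and payload["comparisons"] is not None:
            payload["comparisons"] = [
                (tuple(p[0]), tuple(p[1])) for p in payload["comparisons"]
            ]
        return cls(**payload)


@dataclass
class ComparisonRecord:
    """All comparison statistics for one dataset pair."""

    key_a: DatasetKey
    key_b: DatasetKey
    sequential: list[SequentialTestResult]
    univariate: dict[str, tuple[float, float]]
    angle: AngleComparison
    distance: DistanceComparison | None


@dataclass
class ReportBundle:
    """The full analysis output, in memory."""

    fits: dict[DatasetKey, TraitSurfaceFit]
    landscapes: dict[DatasetKey, TPSLandscape]
    optima: dict[DatasetKey, OptimumRegion]
    comparisons: list[ComparisonRecord]
    manifest: dict
    partial: bool = False
    failures: list[str] = field(default_factory=list)


def _load_records(config: AnalysisConfig) -> list[IndividualRecord]:
    if config.csv is not None:
        return read_records(config.csv, config.assays_csv)
    scenario = config.scenario
    if isinstance(scenario, (str, Path)):
        scenario = Scenario.from_yaml(scenario)
    return simulate_experiment(
        scenario.grid(), scenario.n_per_diet_per_sex, scenario.surfaces, scenario.seed
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % 2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every stage of the analysis and (optionally) write the bundle.

    Stage failures are logged and recorded; the bundle is then marked
    partial rather than aborting the run.
    """
    t0 = time.monotonic()
    records = _load_records(config)
    keys = [(t, s) for s in config.sexes for t in config.traits]
    comparisons = (
        config.comparisons if config.comparisons is not None else default_comparisons()
    )
    comparisons = [
        (a, b) for a, b in comparisons if a in keys and b in keys
    ]
    seeds = _child_seeds(config.seed, len(keys) + len(comparisons))

    fits: dict[DatasetKey, TraitSurfaceFit] = {}
    landscapes: dict[DatasetKey, TPSLandscape] = {}
    optima: dict[DatasetKey, OptimumRegion] = {}
    failures: list[str] = []

    for i, (trait, sex) in enumerate(keys):
        try:
            fits[(trait, sex)] = fit_response_surface(records, trait, sex)
            sel = [r for r in records if r.sex == sex]
            locs = np.array(
                [[r.diet.protein_pct, r.diet.carbohydrate_pct] for r in sel]
            )
            y = np.array([r.trait_value(trait) for r in sel])
            landscapes[(trait, sex)] = fit_tps(locs, y, config.lambda_spec)
            optima[(trait, sex)] = bootstrap_optimum_region(
                records, trait, sex,
                B=config.B, alpha=config.alpha, seed=seeds[i],
                lambda_spec=config.lambda_spec,
            )
            logger.info(
                "fitted %s/%s: n=%d lambda=%.4g optimum=(%.2f, %.2f)",
                trait, sex, fits[(trait, sex)].n,
                landscapes[(trait, sex)].lam, *optima[(trait, sex)].optimum,
            )
        except Exception as exc:
            logger.error("stage %s/%s failed: %s", trait, sex, exc)
            failures.append(f"fit {trait}/{sex}: {exc}")

    comp_records: list[ComparisonRecord] = []
    for j, (ka, kb) in enumerate(comparisons):
        try:
            ds_a = TraitDataset.from_records(records, ka[0], ka[1], label=f"{ka[1]} {ka[0]}")
            ds_b = TraitDataset.from_records(records, kb[0], kb[1], label=f"{kb[1]} {kb[0]}")
            seq = sequential_compare(ds_a, ds_b)
            uni = {
                "linear P": univariate_followup(ds_a, ds_b, "linear", "P"),
                "linear C": univariate_followup(ds_a, ds_b, "linear", "C"),
                "quadratic P": univariate_followup(ds_a, ds_b, "quadratic", "P"),
                "quadratic C": univariate_followup(ds_a, ds_b, "quadratic", "C"),
            }
            angle = bootstrap_angle(ds_a, ds_b, B=config.B, seed=seeds[len(keys) + j])
            dist = None
            if ka in optima and kb in optima:
                dist = region_distance(optima[ka], optima[kb])
            comp_records.append(
                ComparisonRecord(ka, kb, seq, uni, angle, dist)
            )
        except Exception as exc:
            logger.error("comparison %s vs %s failed: %s", ka, kb, exc)
            failures.append(f"compare {ka} vs {kb}: {exc}")

    manifest = {
        "package": "nutriscape",
        "version": __version__,
        "seed": config.seed,
        "n_records": len(records),
        "n_diets": len({r.diet.diet_id for r in records}),
        "B": config.B,
        "alpha": config.alpha,
        "traits": list(config.traits),
        "sexes": list(config.sexes),
        "elapsed_s": round(time.monotonic() - t0, 3),
        "versions": _lib_versions(),
    }
    bundle = ReportBundle(
        fits=fits, landscapes=landscapes, optima=optima,
        comparisons=comp_records, manifest=manifest,
        partial=bool(failures), failures=failures,
    )
    if config.outdir is not None:
        write_bundle(bundle, config.outdir, grid_resolution=config.grid_resolution,
                     records=records)
    return bundle


def _lib_versions() -> dict[str, str]:
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_bundle(
    bundle: ReportBundle,
    outdir: str | Path,
    grid_resolution: int = 100,
    records: Sequence[IndividualRecord] | None = None,
) -> None:
    """Write the report bundle as TSV tables + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if records is not None:
        write_records(records, outdir / "records.csv", outdir / "assay_counts.csv")

    surface_table(list(bundle.fits.values())).to_csv(
        outdir / "surface_fits.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    opt_rows = []
    for (trait, sex), reg in bundle.optima.items():
        opt_rows.append(
            {
                "trait": trait,
                "sex": sex,
                "P_opt": reg.optimum[0],
                "C_opt": reg.optimum[1],
                "value": reg.optimum_value,
                "ratio": pc_ratio(reg.optimum),
                "cr_vertices": json.dumps(
                    [[round(float(x), 6) for x in v] for v in reg.cr_polygon]
                ),
            }
        )
    pd.DataFrame(opt_rows).to_csv(
        outdir / "optima.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    seq_rows, ad_rows = [], []
    for comp in bundle.comparisons:
        pair = f"{comp.key_a[1]} {comp.key_a[0]} vs {comp.key_b[1]} {comp.key_b[0]}"
        for st in comp.sequential:
            seq_rows.append(
                {
                    "comparison": pair, "stage": st.stage,
                    "SS_R": st.ss_reduced, "SS_C": st.ss_complete,
                    "DF1": st.df1, "DF2": st.df2,
                    "F": st.f_value, "P": st.p_value,
                }
            )
        for name, (f, p) in comp.univariate.items():
            seq_rows.append(
                {
                    "comparison": pair, "stage": f"univariate {name}",
                    "SS_R": np.nan, "SS_C": np.nan, "DF1": 1,
                    "DF2": next(
                        st.df2 for st in comp.sequential if st.stage == name.split()[0]
                    ),
                    "F": f, "P": p,
                }
            )
        ad_rows.append(
            {
                "comparison": pair,
                "theta_deg": comp.angle.theta_deg,
                "theta_ci_low": comp.angle.ci[0],
                "theta_ci_high": comp.angle.ci[1],
                "d": comp.distance.d if comp.distance else np.nan,
                "d_ci_low": comp.distance.ci[0] if comp.distance else np.nan,
                "d_ci_high": comp.distance.ci[1] if comp.distance else np.nan,
            }
        )
    pd.DataFrame(seq_rows).to_csv(
        outdir / "sequential_tests.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(ad_rows).to_csv(
        outdir / "angles_distances.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    meta = {}
    for (trait, sex), model in bundle.landscapes.items():
        grid = export_landscape_grid(model, grid_resolution, model.region())
        grid.to_csv(
            outdir / f"landscape_{trait}_{sex}.tsv",
            sep="\t", index=False, float_format=FLOAT_FMT,
        )
        meta[f"{trait}/{sex}"] = {
            "lambda": model.lam,
            "gcv": model.gcv_score,
            "effective_df": model.effective_df,
            "n_knots": model.n_knots,
        }
    (outdir / "landscapes.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
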