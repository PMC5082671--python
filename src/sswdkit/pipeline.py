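"""Pipeline orchestration: simulate -> score -> project -> prevalence ->
density change, with per-run artifact directories and manifests.

Every stage writes tidy CSV/JSON into a fresh run directory and never
mutates another stage's inputs.  The manifest records the configuration
hash and seeds so a rerun with the same config reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import density_change, prevalence, projection, reef_abundance, synthetic_data

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    When ``simulate`` is true the three input tables are generated with
    the study-scale default simulators; otherwise ``roving_csv``,
    ``transects_csv`` and ``stars_csv`` must point at existing files.
    """

    output_dir: str = "runs"
    seed: int = 0
    simulate: bool = True
    roving_csv: str | None = None
    transects_csv: str | None = None
    stars_csv: str | None = None
    train_years: tuple[int, int] = (2006, 2013)
    test_years: tuple[int, int] = (2014, 2015)
    level: float = 0.95
    max_order: int = 2
    contrast_family: str = "species"
    n_chains: int = 3
    iterations: int = 6_000
    burn_in: int = 1_000
    thin: int = 5

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        roving = synthetic_data.generate_roving_surveys(
            synthetic_data.default_roving_config(seed=config.seed))
        transects, stars = synthetic_data.generate_transect_surveys(
            synthetic_data.default_transect_config(seed=config.seed + 1))
        return roving, transects, stars
    for name, path in [("roving_csv", config.roving_csv),
                       ("transects_csv", config.transects_csv),
                       ("stars_csv", config.stars_csv)]:
        if path is None or not Path(path).exists():
            raise StageError("load", f"missing input file for {name}: {path}")
    return (pd.read_csv(config.roving_csv),
            pd.read_csv(config.transects_csv),
            pd.read_csv(config.stars_csv))


def score_roving(roving: pd.DataFrame,
                 transform: reef_abundance.CountTransform | None = None) -> pd.DataFrame:
    """Filter, absence-complete and score roving-diver records."""
    filtered = reef_abundance.filter_surveys(roving)
    species = sorted(roving["species"].unique())
    completed = reef_abundance.complete_absences(filtered, species)
    return reef_abundance.score_all(completed, transform)


def project_scores(scores: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """ARIMA-project every species x basin abundance series and flag
    epidemic-year deviations."""
    grid = projection.default_grid(config.max_order)
    rows = []
    for (sp, basin), _ in scores.groupby(["species", "basin"]):
        series = reef_abundance.annual_series(scores, sp, basin)
        train = series.loc[config.train_years[0]:config.train_years[1]].dropna()
        test = series.loc[config.test_years[0]:config.test_years[1]].dropna()
        if len(train) < 4 or len(test) == 0:
            logger.warning("skipping %s / %s: insufficient data", sp, basin)
            continue
        try:
            fit, proj, flags = projection.project_series(
                train.to_numpy(), test.to_numpy(), grid, config.level)
        except projection.ModelSelectionError as exc:
            raise StageError("projection", f"{sp}/{basin}: {exc}") from exc
        for i, (year, obs) in enumerate(test.items()):
            rows.append({
                "species": sp, "basin": basin, "year": int(year),
                "model": str(fit.spec), "aicc": fit.aicc, "sigma2": fit.sigma2,
                "observed": obs, "forecast": proj.point[i],
                "lower": proj.lower[i], "upper": proj.upper[i],
                "flag": flags[i],
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory path."""
    roving, transects, stars = _load_inputs(config)
    run_dir = Path(config.output_dir) / f"run-{config.digest()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "n_roving_rows": int(len(roving)),
        "n_transects": int(len(transects)),
        "n_stars": int(len(stars)),
        "stages": [],
    }

    try:
        scores = score_roving(roving)
        scores.to_csv(run_dir / "scores.csv", index=False)
        manifest["stages"].append("score")

        projections = project_scores(scores, config)
        projections.to_csv(run_dir / "projections.csv", index=False)
        manifest["stages"].append("projection")

        modelled = stars[
            stars["taxon"].isin(prevalence.SPECIES_LEVELS)
            & stars["month"].isin(prevalence.MONTH_LEVELS)
            & (stars["year"] == 2014)
        ]
        prev_table = prevalence.prevalence(modelled)
        prev_table.to_csv(run_dir / "prevalence.csv", index=False)
        fit = prevalence.fit_prevalence_model(modelled)
        prevalence.coefficient_table(fit).to_csv(
            run_dir / "prevalence_coefficients.csv", index=False)
        contrasts = prevalence.pairwise_contrasts(fit, config.contrast_family)
        pd.DataFrame([dataclasses.asdict(c) for c in contrasts]).to_csv(
            run_dir / "prevalence_contrasts.csv", index=False)
        manifest["stages"].append("prevalence")

        counts = density_change.transect_counts(transects, stars)
        density_change.density_table(transects, stars).to_csv(
            run_dir / "density_table.csv", index=False)
        draws = density_change.run_mcmc(
            counts,
            chains=density_change.ChainConfig(
                n_chains=config.n_chains, iterations=config.iterations,
                burn_in=config.burn_in, thin=config.thin, seed=config.seed + 2))
        draws.to_frame().to_csv(run_dir / "density_draws.csv", index=False)
        summary = density_change.summarize(draws)
        summary.table.to_csv(run_dir / "density_summary.csv")
        (run_dir / "density_flags.json").write_text(json.dumps({
            "change_flags": summary.change_flags,
            "decline_probability": summary.decline_probability,
        }, indent=2))
        manifest["stages"].append("density_change")
    except StageError:
        raise
    except Exception as exc:  # halt with the stage context
        raise StageError(manifest["stages"][-1] if manifest["stages"] else "load",
                         str(exc)) from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return run_dir


def subset_rerun(
    roving: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series],
) -> pd.DataFrame:
    """Re-score a record subset and report trajectories side by side.

    ``predicate`` maps the roving frame to a boolean mask (e.g. surveys
    inside harvest-closure zones).  Returns the full-data and subset
    abundance scores merged per species x basin x year.
    """
    full = score_roving(roving)
    mask = predicate(roving)
    subset = roving.loc[mask]
    if subset.empty:
        sub_scores = pd.DataFrame(columns=full.columns)
    else:
        sub_scores = score_roving(subset)
    merged = full.merge(
        sub_scores[["species", "basin", "year", "abundance_score", "n_surveys"]],
        on=["species", "basin", "year"], how="left",
        suffixes=("_full", "_subset"))
    return merged
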