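"""Seeded synthetic survey generators.

Two survey designs are emulated so every downstream stage is testable
without field data:

* **Roving-diver surveys** — per basin and year, a configurable number
  of timed dives; for each species a latent yearly mean count follows a
  stationary AR(1) process on the log scale, multiplied by a
  species-specific survival fraction from the epidemic onset year
  onward.  Per-survey counts are negative-binomial around the yearly
  mean and reduced to the ordinal abundance category actually recorded
  by divers.  A configurable fraction of surveys deliberately violates
  the habitat/time/duration inclusion rules so filtering is exercised.

* **Strip transects** — fixed-area belt transects at a set of sites
  over the months May-August of 2014 and 2015; per-transect taxon
  counts are Poisson with mean proportional to the surveyed area and a
  year-specific density, and each observed star of a modelled species
  receives a wasting-disease status from a Bernoulli draw whose logit
  is a configured intercept plus species and month effects.

All generators are deterministic given the config seed; per-basin and
per-site substreams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .reef_abundance import bin_count_to_category

MONTH_NUMBERS = {"May": 5, "June": 6, "July": 7, "August": 8}

GOOD_HABITATS = ("rock/shale reef", "wall", "cobblestone/boulder field",
                 "kelp forest", "pinnacle")
BAD_HABITATS = ("sandy bottom", "eelgrass bed", "mud/silt bottom", "artificial reef")


@dataclass(frozen=True)
class SpeciesSim:
    """Latent dynamics of one species in the roving-diver simulator.

    ``baseline_mean_count`` is the pre-epidemic marginal mean count per
    survey (the lognormal year-effect is mean-corrected so the yearly
    expectation equals the baseline).  ``epidemic_survival`` multiplies
    the latent mean from ``epidemic_start_year`` onward.
    """

    name: str
    baseline_mean_count: float
    overdispersion_k: float = 5.0
    ar1_phi: float = 0.3
    log_noise_sd: float = 0.15
    epidemic_survival: float = 1.0
    epidemic_start_year: int = 2014

    def __post_init__(self) -> None:
        if not np.isfinite([self.baseline_mean_count, self.overdispersion_k,
                            self.ar1_phi, self.log_noise_sd,
                            self.epidemic_survival]).all():
            raise ValueError(f"{self.name}: non-finite parameter")
        if self.baseline_mean_count < 0:
            raise ValueError(f"{self.name}: baseline_mean_count must be >= 0")
        if self.overdispersion_k <= 0:
            raise ValueError(f"{self.name}: overdispersion k must be > 0")
        if not -1 < self.ar1_phi < 1:
            raise ValueError(f"{self.name}: AR(1) phi must be in (-1, 1)")
        if self.log_noise_sd < 0:
            raise ValueError(f"{self.name}: log_noise_sd must be >= 0")
        if not 0 <= self.epidemic_survival <= 1:
            raise ValueError(f"{self.name}: epidemic_survival must be in [0, 1]")


@dataclass(frozen=True)
class RovingSimConfig:
    """Configuration of the roving-diver survey simulator."""

    basins: tuple[str, ...]
    years: tuple[int, int]  # inclusive range
    surveys_per_basin_year: int | Mapping[str, Mapping[int, int]]
    species: tuple[SpeciesSim, ...]
    seed: int = 0
    filter_violation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must be non-empty")
        if self.years[0] > self.years[1]:
            raise ValueError("years range is empty")
        if not 0 <= self.filter_violation_rate <= 1:
            raise ValueError("filter_violation_rate must be in [0, 1]")

    def n_surveys(self, basin: str, year: int) -> int:
        if isinstance(self.surveys_per_basin_year, int):
            n = self.surveys_per_basin_year
        else:
            n = int(self.surveys_per_basin_year[basin][year])
        if n < 0:
            raise ValueError("survey counts must be >= 0")
        return n


@dataclass(frozen=True)
class TaxonSim:
    """Density of one taxon on the strip transects.

    ``density_2014`` is stars per 100 m^2 in the first study year;
    ``log_density_change`` is the log ratio of 2015 to 2014 density.
    """

    name: str
    density_2014: float
    log_density_change: float = 0.0

    def __post_init__(self) -> None:
        if self.density_2014 < 0:
            raise ValueError(f"{self.name}: density must be >= 0")


@dataclass(frozen=True)
class PrevalenceLogit:
    """Species + month logit parameterisation of disease probability.

    Levels absent from either mapping contribute 0 (reference levels).
    """

    intercept: float = -30.0
    species_effects: Mapping[str, float] = field(default_factory=dict)
    month_effects: Mapping[str, float] = field(default_factory=dict)

    def prob(self, species: str, month: str) -> float:
        logit = (self.intercept
                 + self.species_effects.get(species, 0.0)
                 + self.month_effects.get(month, 0.0))
        return 1.0 / (1.0 + math.exp(-logit))


@dataclass(frozen=True)
class TransectSimConfig:
    """Configuration of the strip-transect simulator."""

    sites: tuple[str, ...]
    taxa: tuple[TaxonSim, ...]
    months: tuple[str, ...] = ("May", "June", "July", "August")
    years: tuple[int, ...] = (2014, 2015)
    transects_per_site_month: int = 2
    transect_area_m2: float = 100.0
    prevalence: PrevalenceLogit = field(default_factory=PrevalenceLogit)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transect_area_m2 <= 0:
            raise ValueError("transect_area_m2 must be > 0")
        bad = set(self.months) - set(MONTH_NUMBERS)
        if bad:
            raise ValueError(f"months outside the configured May-August set: {sorted(bad)}")


def _nb_counts(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    return rng.poisson(rng.gamma(k, mean / k, size=size))


def generate_roving_surveys(config: RovingSimConfig) -> pd.DataFrame:
    """Simulate roving-diver survey records.

    Returns one row per survey x species with columns
    survey_id, basin, date, start_time, duration_min, habitat, species,
    abundance_category (in {0, S, F, M, A}).  Sightings and absences
    are both explicit, so the table is already absence-complete.
    """
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    ss = np.random.SeedSequence(config.seed)
    basin_seeds = ss.spawn(len(config.basins))

    frames: list[pd.DataFrame] = []
    for basin, basin_seed in zip(config.basins, basin_seeds):
        rng = np.random.Generator(np.random.PCG64(basin_seed))
        # latent stationary AR(1) deviation per species, shared by the basin
        latent: dict[str, np.ndarray] = {}
        for sp in config.species:
            sd, phi = sp.log_noise_sd, sp.ar1_phi
            x = np.zeros(len(years))
            stat_var = sd**2 / (1 - phi**2) if sd > 0 else 0.0
            if sd > 0:
                x[0] = rng.normal(0.0, math.sqrt(stat_var))
                for t in range(1, len(years)):
                    x[t] = phi * x[t - 1] + rng.normal(0.0, sd)
            # mean-correct so E[exp(x - c)] = 1 at stationarity
            latent[sp.name] = np.exp(x - stat_var / 2.0)

        for yi, year in enumerate(years):
            n = config.n_surveys(basin, year)
            if n == 0:
                continue
            months = rng.integers(1, 13, size=n)
            days = rng.integers(1, 29, size=n)
            violate = rng.random(n) < config.filter_violation_rate
            start_h = rng.integers(7, 20, size=n)
            start_m = rng.integers(0, 60, size=n)
            duration = rng.integers(30, 71, size=n).astype(float)
            habitat = rng.choice(GOOD_HABITATS, size=n).astype(object)
            # deliberately break one inclusion rule on flagged surveys
            kind = rng.integers(0, 3, size=n)
            bad_time = violate & (kind == 0)
            bad_dur = violate & (kind == 1)
            bad_hab = violate & (kind == 2)
            start_h[bad_time] = rng.integers(0, 4, size=int(bad_time.sum()))
            duration[bad_dur] = rng.choice([10.0, 15.0, 90.0, 120.0], size=int(bad_dur.sum()))
            habitat[bad_hab] = rng.choice(BAD_HABITATS, size=int(bad_hab.sum()))

            base = pd.DataFrame({
                "survey_id": [f"{basin}-{year}-{i:05d}" for i in range(n)],
                "basin": basin,
                "date": [f"{year}-{m:02d}-{d:02d}" for m, d in zip(months, days)],
                "start_time": [f"{h:02d}:{m:02d}" for h, m in zip(start_h, start_m)],
                "duration_min": duration,
                "habitat": habitat,
            })
            for sp in config.species:
                mean = sp.baseline_mean_count * latent[sp.name][yi]
                if year >= sp.epidemic_start_year:
                    mean *= sp.epidemic_survival
                counts = _nb_counts(rng, mean, sp.overdispersion_k, n)
                sub = base.copy()
                sub["species"] = sp.name
                sub["abundance_category"] = [bin_count_to_category(c) for c in counts]
                frames.append(sub)

    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["survey_id", "basin", "date", "start_time", "duration_min",
                 "habitat", "species", "abundance_category"])
    return out


def generate_transect_surveys(
    config: TransectSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate strip-transect surveys and per-star observations.

    Returns ``(transects, stars)``: transects with columns transect_id,
    site, date, year, month, area_m2; stars with transect_id, taxon,
    sswd_status (healthy/case) plus year and month for convenience.
    """
    ss = np.random.SeedSequence(config.seed)
    site_seeds = ss.spawn(len(config.sites))
    t_rows: list[dict] = []
    s_rows: list[dict] = []
    for site, site_seed in zip(config.sites, site_seeds):
        rng = np.random.Generator(np.random.PCG64(site_seed))
        for year in config.years:
            for month in config.months:
                if month not in MONTH_NUMBERS:
                    raise ValueError(f"month outside configured set: {month}")
                for t in range(config.transects_per_site_month):
                    tid = f"{site}-{year}-{month}-{t}"
                    day = int(rng.integers(1, 29))
                    t_rows.append({
                        "transect_id": tid, "site": site,
                        "date": f"{year}-{MONTH_NUMBERS[month]:02d}-{day:02d}",
                        "year": year, "month": month,
                        "area_m2": config.transect_area_m2,
                    })
                    for taxon in config.taxa:
                        dens = taxon.density_2014
                        if year == 2015:
                            dens *= math.exp(taxon.log_density_change)
                        mean = config.transect_area_m2 / 100.0 * dens
                        count = int(rng.poisson(mean)) if mean > 0 else 0
                        if count == 0:
                            continue
                        p = config.prevalence.prob(taxon.name, month)
                        status = rng.random(count) < p
                        for case in status:
                            s_rows.append({
                                "transect_id": tid, "taxon": taxon.name,
                                "sswd_status": "case" if case else "healthy",
                                "year": year, "month": month,
                            })
    transects = pd.DataFrame(
        t_rows, columns=["transect_id", "site", "date", "year", "month", "area_m2"])
    stars = pd.DataFrame(
        s_rows, columns=["transect_id", "taxon", "sswd_status", "year", "month"])
    return transects, stars


def generate_count_calibration(
    n_surveys: int,
    count_distribution: int | Callable[[np.random.Generator, int], np.ndarray],
    seed: int = 0,
    species: str = "P. helianthoides",
) -> pd.DataFrame:
    """Simulate expert surveys recording exact counts.

    ``count_distribution`` is either a constant count or a callable
    ``f(rng, n) -> counts``.  Returns a frame (survey_id, species,
    count); ``n_surveys == 0`` yields an empty frame.
    """
    if n_surveys < 0:
        raise ValueError("n_surveys must be >= 0")
    rng = np.random.default_rng(seed)
    if callable(count_distribution):
        counts = np.asarray(count_distribution(rng, n_surveys), dtype=int)
    else:
        counts = np.full(n_surveys, int(count_distribution))
    if counts.shape != (n_surveys,):
        raise ValueError("count_distribution must return one count per survey")
    return pd.DataFrame({
        "survey_id": [f"CAL-{i:04d}" for i in range(n_surveys)],
        "species": species,
        "count": counts,
    })


def default_roving_config(seed: int = 0) -> RovingSimConfig:
    """Study-scale default: published survey effort, three focal species.

    Baselines reflect the study system: the sunflower star abundant
    pre-epidemic (~10 per survey) and nearly extirpated afterwards, the
    giant pink star rare and moderately reduced, the leather star
    common and unaffected.
    """
    return RovingSimConfig(
        basins=tuple(reference.SURVEY_EFFORT),
        years=(2006, 2015),
        surveys_per_basin_year=reference.SURVEY_EFFORT,
        species=(
            SpeciesSim("P. helianthoides", baseline_mean_count=9.9,
                       epidemic_survival=0.05),
            SpeciesSim("P. brevispinus", baseline_mean_count=0.6,
                       epidemic_survival=0.3),
            SpeciesSim("D. imbricata", baseline_mean_count=2.0,
                       epidemic_survival=1.0),
        ),
        seed=seed,
        filter_violation_rate=0.1,
    )


def default_transect_config(seed: int = 0) -> TransectSimConfig:
    """Study-scale default: 8 sites, published 2014/2015 taxon densities,
    month-ramped prevalence with the published logistic effects."""
    taxa = []
    for name, (d14, d15) in reference.TAXON_DENSITIES.items():
        if d14 > 0 and d15 > 0:
            change = math.log(d15 / d14)
        elif d14 > 0:
            change = -5.0  # effectively absent in 2015
        else:
            d14, change = 0.01, math.log(max(d15, 0.01) / 0.01)
        taxa.append(TaxonSim(name, d14, change))
    est = reference.PREVALENCE_ESTIMATES
    prev = PrevalenceLogit(
        intercept=est["intercept"]["estimate"],
        species_effects={
            "E. troschelii": est["E. troschelii"]["estimate"],
            "P. helianthoides": est["P. helianthoides"]["estimate"],
        },
        month_effects={
            "June": est["June"]["estimate"],
            "July": est["July"]["estimate"],
            "August": est["August"]["estimate"],
        },
    )
    return TransectSimConfig(
        sites=("Bell Island", "FHL Dock", "Lab 11 Beach", "Reuben Tarte",
               "Rosario", "Shaw House", "Strathmann's", "Yellow Island"),
        taxa=tuple(taxa),
        prevalence=prev,
        seed=seed,
    )
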