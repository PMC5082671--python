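"""Roving-diver abundance indices.

Volunteer scuba surveys record, per dive, every positively identified
species together with a four-level abundance category: Single (1
individual), Few (2-10), Many (11-100) and Abundant (>100).  An explicit
absence level (category ``0``) completes the dataset so that the
proportion of surveys on which a species was reported — the Sighting
Frequency (SF) — is well defined.

For a species x basin x year cell with ``nS, nF, nM, nA`` surveys per
category out of ``n`` total surveys::

    SF            = (nS + nF + nM + nA) / n
    density score = (1*nS + 2*nF + 3*nM + 4*nA) / (nS + nF + nM + nA)
    abundance     = density score * SF

The density score lives in [1, 4] when at least one sighting exists and
is undefined otherwise; the abundance score lives in [0, 4] and is 0
exactly when SF is 0.  A category-to-count transform (1 for Single, the
calibration median of 2-10 for Few, the median of 11-100 for Many, and
the lower bound 101 for Abundant) converts the ordinal scale to an
approximate mean count per survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid abundance categories; "0" is the explicit absence level.
CATEGORIES = ("0", "S", "F", "M", "A")

#: Ordinal code used in the density score for each sighting category.
CATEGORY_CODES = {"S": 1, "F": 2, "M": 3, "A": 4}

ROVING_COLUMNS = [
    "survey_id", "basin", "date", "start_time", "duration_min",
    "habitat", "species", "abundance_category",
]


@dataclass(frozen=True)
class FilterConfig:
    """Survey-level inclusion rules for roving-diver data.

    Defaults follow the study protocol: drop artificial reefs, sandy
    bottom, eelgrass beds and mud/silt bottoms, keep dives started
    between 04:00 and 22:00 local time lasting 20-80 minutes
    (both windows closed).
    """

    excluded_habitats: frozenset[str] = frozenset(
        {"artificial reef", "sandy bottom", "eelgrass bed", "mud/silt bottom"}
    )
    time_window: tuple[str, str] = ("04:00", "22:00")
    duration_window: tuple[float, float] = (20.0, 80.0)

    def __post_init__(self) -> None:
        lo, hi = self.duration_window
        if not lo <= hi:
            raise ValueError("duration_window must be a non-empty interval")
        t0, t1 = (_parse_clock(t, where="time_window") for t in self.time_window)
        if not t0 <= t1:
            raise ValueError("time_window must be a non-empty interval")


@dataclass(frozen=True)
class CountTransform:
    """Representative count for each abundance category.

    ``median_few``/``median_many`` default to the band midpoints
    (6, 55.5); supply calibration-derived medians via
    :func:`category_medians` when actual-count surveys are available.
    """

    median_few: float = 6.0
    median_many: float = 55.5
    single: float = 1.0
    abundant: float = 101.0
    absence: float = 0.0

    def __post_init__(self) -> None:
        if not 2 <= self.median_few <= 10:
            raise ValueError("median_few must lie in the Few band [2, 10]")
        if not 11 <= self.median_many <= 100:
            raise ValueError("median_many must lie in the Many band [11, 100]")

    def value(self, category: str) -> float:
        return {
            "0": self.absence, "S": self.single, "F": self.median_few,
            "M": self.median_many, "A": self.abundant,
        }[category]


@dataclass(frozen=True)
class BasinYearScore:
    """Scores for one species x basin x year cell.

    ``density_score`` is None when the species was never sighted in the
    cell (SF = 0), in which case the abundance score is 0 by definition.
    """

    species: str
    basin: str
    year: int
    n_surveys: int
    nS: int
    nF: int
    nM: int
    nA: int
    SF: float
    density_score: float | None
    abundance_score: float
    mean_count: float


class EmptyCellError(ValueError):
    """Raised when a species x basin x year cell contains no surveys."""


def _parse_clock(value: str, *, where: str = "start_time") -> float:
    """Clock string 'HH:MM' -> minutes after midnight."""
    try:
        hh, mm = str(value).split(":")
        h, m = int(hh), int(mm)
        if not (0 <= h <= 23 and 0 <= m <= 59):
            raise ValueError
    except (ValueError, AttributeError):
        raise ValueError(f"malformed clock time in {where}: {value!r}") from None
    return 60 * h + m


def filter_surveys(records: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the habitat, start-time and duration inclusion rules.

    Returns the retained rows (original order, index reset).  Malformed
    start-time strings are reported with their row index.
    """
    cfg = cfg or FilterConfig()
    if records.empty:
        return records.copy()

    minutes = []
    for idx, value in records["start_time"].items():
        try:
            minutes.append(_parse_clock(value))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from None
    minutes = np.asarray(minutes)

    t_lo, t_hi = (_parse_clock(t) for t in cfg.time_window)
    d_lo, d_hi = cfg.duration_window
    duration = records["duration_min"].to_numpy(dtype=float)
    keep = (
        ~records["habitat"].isin(cfg.excluded_habitats).to_numpy()
        & (minutes >= t_lo) & (minutes <= t_hi)
        & (duration >= d_lo) & (duration <= d_hi)
    )
    return records.loc[keep].reset_index(drop=True)


def complete_absences(records: pd.DataFrame, species_list: Sequence[str]) -> pd.DataFrame:
    """Add explicit absence rows (category "0") for unreported species.

    Every survey present in ``records`` gains one row per species in
    ``species_list`` it lacks; the result has exactly
    ``n_surveys * len(species_list)`` rows for those species.
    Duplicate survey x species rows in the input are an error.
    """
    species_list = list(species_list)
    if records.duplicated(subset=["survey_id", "species"]).any():
        dups = records[records.duplicated(subset=["survey_id", "species"], keep=False)]
        raise ValueError(
            "duplicate survey x species rows: "
            f"{dups[['survey_id', 'species']].drop_duplicates().to_dict('records')}"
        )

    surveys = records.drop_duplicates("survey_id")[
        ["survey_id", "basin", "date", "start_time", "duration_min", "habitat"]
    ]
    full = surveys.merge(pd.DataFrame({"species": species_list}), how="cross")
    out = full.merge(
        records[["survey_id", "species", "abundance_category"]],
        on=["survey_id", "species"], how="left",
    )
    out["abundance_category"] = out["abundance_category"].fillna("0")
    # keep any rows for species outside species_list untouched
    extra = records[~records["species"].isin(species_list)]
    if len(extra):
        out = pd.concat([out, extra[out.columns]], ignore_index=True)
    return out.reset_index(drop=True)


def bin_count_to_category(count: int) -> str:
    """Map an actual count to the ordinal abundance category."""
    count = int(count)
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return "0"
    if count == 1:
        return "S"
    if count <= 10:
        return "F"
    if count <= 100:
        return "M"
    return "A"


def category_medians(
    calibration: pd.DataFrame,
    *,
    default_few: float = 6.0,
    default_many: float = 55.5,
    count_column: str = "count",
) -> tuple[float, float]:
    """Medians of calibration counts within the Few and Many bands.

    Counts outside 2-10 / 11-100 are ignored for the respective band.
    An empty band falls back to the configured default and is logged.
    """
    counts = calibration[count_column].to_numpy(dtype=float) if len(calibration) else np.array([])
    few = counts[(counts >= 2) & (counts <= 10)]
    many = counts[(counts >= 11) & (counts <= 100)]
    if len(few):
        median_few = float(np.median(few))
    else:
        logger.warning("no calibration counts in 2-10; using default %s", default_few)
        median_few = default_few
    if len(many):
        median_many = float(np.median(many))
    else:
        logger.warning("no calibration counts in 11-100; using default %s", default_many)
        median_many = default_many
    return median_few, median_many


def score_basin_year(
    records: pd.DataFrame,
    species: str,
    basin: str,
    year: int,
    transform: CountTransform | None = None,
) -> BasinYearScore:
    """Score one species x basin x year cell of filtered, absence-completed data.

    Mean count averages the transform's representative values over ALL
    surveys in the cell, absences contributing 0.
    """
    transform = transform or CountTransform()
    years = pd.to_datetime(records["date"]).dt.year
    cell = records[
        (records["species"] == species) & (records["basin"] == basin) & (years == year)
    ]
    n = len(cell)
    if n == 0:
        raise EmptyCellError(f"no surveys for {species} / {basin} / {year}")

    cats = cell["abundance_category"]
    bad = set(cats) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown abundance categories: {sorted(bad)}")
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    n_sight = n - counts["0"]
    sf = n_sight / n
    if n_sight:
        density = sum(CATEGORY_CODES[c] * counts[c] for c in CATEGORY_CODES) / n_sight
    else:
        density = None
    abundance = density * sf if density is not None else 0.0
    mean_count = float(np.mean([transform.value(c) for c in cats]))
    return BasinYearScore(
        species=species, basin=basin, year=int(year), n_surveys=n,
        nS=counts["S"], nF=counts["F"], nM=counts["M"], nA=counts["A"],
        SF=sf, density_score=density, abundance_score=abundance,
        mean_count=mean_count,
    )


def score_all(
    records: pd.DataFrame, transform: CountTransform | None = None
) -> pd.DataFrame:
    """Score every species x basin x year cell present in the data.

    Returns a tidy frame (species, basin, year, n_surveys, nS..nA, SF,
    density_score, abundance_score, mean_count); density_score is NaN
    for cells without sightings.
    """
    records = records.copy()
    records["_year"] = pd.to_datetime(records["date"]).dt.year
    rows = []
    for (sp, basin, year), _ in records.groupby(["species", "basin", "_year"]):
        s = score_basin_year(records.drop(columns="_year"), sp, basin, int(year), transform)
        rows.append({
            "species": s.species, "basin": s.basin, "year": s.year,
            "n_surveys": s.n_surveys, "nS": s.nS, "nF": s.nF, "nM": s.nM,
            "nA": s.nA, "SF": s.SF,
            "density_score": np.nan if s.density_score is None else s.density_score,
            "abundance_score": s.abundance_score, "mean_count": s.mean_count,
        })
    return pd.DataFrame(rows).sort_values(["species", "basin", "year"]).reset_index(drop=True)


def annual_series(
    scores: pd.DataFrame,
    species: str,
    basin: str,
    value: str = "abundance_score",
) -> pd.Series:
    """Ordered yearly sequence for one species x basin.

    Years run from the first to the last observed year; missing years
    are flagged as NaN, never interpolated.
    """
    cell = scores[(scores["species"] == species) & (scores["basin"] == basin)]
    if cell.empty:
        return pd.Series(dtype=float, name=value)
    cell = cell.sort_values("year")
    years = np.arange(cell["year"].min(), cell["year"].max() + 1)
    series = cell.set_index("year")[value].reindex(years)
    series.index.name = "year"
    series.name = value
    missing = series.index[series.isna()].tolist()
    if missing:
        logger.warning("%s / %s: missing years %s", species, basin, missing)
    return series
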