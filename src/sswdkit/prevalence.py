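"""Disease prevalence estimation and the species + month logistic model.

Each star observed on a strip transect is classified against the
wasting-disease case definition — white lesions of exposed tissue
and/or recent arm loss, with doubtful animals scored healthy — and
prevalence is the proportion of cases per group.  Between-species and
between-month differences in the likelihood of disease are modelled by
a logistic regression

    logit(p_i) = a0 + b1*Etro_i + b2*Phel_i + b3*Jun_i + b4*Jul_i + b5*Aug_i

with Henricia sp. and May as reference levels.  Fitting is by maximum
likelihood (statsmodels binomial GLM / IRLS); alternative covariate
sets are compared by AIC, and pairwise differences in log odds within
the species family (3 pairs) and the month family (6 pairs) are tested
with Bonferroni-corrected z contrasts at overall alpha 0.05.  Odds
ratios carry Wald intervals exp(estimate +- z * se).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

SPECIES_LEVELS = ("Henricia spp.", "E. troschelii", "P. helianthoides")
MONTH_LEVELS = ("May", "June", "July", "August")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in the logistic fit."""


@dataclass
class PrevalenceFit:
    """ML logistic fit with named coefficients and covariance.

    ``coefficients`` maps term name (intercept, non-reference species
    and month levels) to the log-odds estimate; ``covariance`` is the
    matching variance-covariance frame.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    aic: float
    n_obs: int
    species_levels: tuple[str, ...]
    month_levels: tuple[str, ...]

    def se(self, term: str) -> float:
        return math.sqrt(float(self.covariance.loc[term, term]))


@dataclass(frozen=True)
class ContrastResult:
    level_a: str
    level_b: str
    estimate: float  # log-odds difference a - b
    se: float
    z: float
    p_raw: float
    p_adjusted: float
    family_size: int


def classify_star(
    lesions: bool, recent_arm_loss: bool, uncertain: bool = False
) -> str:
    """Apply the case definition; doubtful animals are scored healthy."""
    if uncertain:
        return "healthy"
    return "case" if (lesions or recent_arm_loss) else "healthy"


def prevalence(
    stars: pd.DataFrame,
    group_by: Sequence[str] = ("taxon", "month"),
    status_column: str = "sswd_status",
) -> pd.DataFrame:
    """Proportion of cases per group, with counts.

    Groups present in the data always have total >= 1; combinations
    with no stars simply do not appear (absence of a row, not a zero).
    """
    if stars.empty:
        return pd.DataFrame(columns=[*group_by, "cases", "total", "prevalence"])
    g = stars.groupby(list(group_by), sort=True, observed=True)[status_column]
    out = g.agg(
        cases=lambda s: int((s == "case").sum()),
        total="size",
    ).reset_index()
    out["prevalence"] = out["cases"] / out["total"]
    return out


def _design(stars: pd.DataFrame, species_levels, month_levels):
    taxa = stars["taxon"].astype(str)
    months = stars["month"].astype(str)
    unknown_sp = set(taxa) - set(species_levels)
    if unknown_sp:
        raise ValueError(f"taxa outside the modelled set: {sorted(unknown_sp)}")
    unknown_m = set(months) - set(month_levels)
    if unknown_m:
        raise ValueError(f"months outside the modelled set: {sorted(unknown_m)}")
    cols = {"intercept": np.ones(len(stars))}
    for sp in species_levels[1:]:
        cols[sp] = (taxa == sp).to_numpy(dtype=float)
    for m in month_levels[1:]:
        cols[m] = (months == m).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=stars.index)


def fit_prevalence_model(
    stars: pd.DataFrame,
    species_levels: Sequence[str] = SPECIES_LEVELS,
    month_levels: Sequence[str] = MONTH_LEVELS,
    include_species: bool = True,
    include_months: bool = True,
    status_column: str = "sswd_status",
) -> PrevalenceFit:
    """Maximum-likelihood logistic fit of disease status on species + month.

    The first entry of each level sequence is the reference.  Raises on
    a single-class outcome and reports complete separation (detected as
    fitted probabilities collapsing to 0/1).
    """
    y = (stars[status_column] == "case").to_numpy(dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError("outcome must contain both healthy stars and cases")
    sp_levels = tuple(species_levels) if include_species else tuple(species_levels[:1])
    mo_levels = tuple(month_levels) if include_months else tuple(month_levels[:1])
    X = _design(stars, tuple(species_levels), tuple(month_levels))
    keep = ["intercept"]
    if include_species:
        keep += list(species_levels[1:])
    if include_months:
        keep += list(month_levels[1:])
    X = X[keep]
    absent = [c for c in X.columns if c != "intercept" and X[c].sum() == 0]
    if absent:
        warnings.warn(f"levels absent from the data, dropped: {absent}",
                      stacklevel=2)
        X = X.drop(columns=absent)

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    mu = np.asarray(res.fittedvalues, dtype=float)
    eps = 1e-8
    if np.any(mu < eps) or np.any(mu > 1 - eps):
        raise SeparationError(
            "fitted probabilities collapsed to 0/1: complete or "
            "quasi-complete separation in the design")
    k = X.shape[1]
    loglik = float(res.llf)
    return PrevalenceFit(
        coefficients=pd.Series(np.asarray(res.params, dtype=float), index=X.columns),
        covariance=pd.DataFrame(np.asarray(res.cov_params(), dtype=float),
                                index=X.columns, columns=X.columns),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n_obs=len(y),
        species_levels=sp_levels,
        month_levels=mo_levels,
    )


def log_odds_to_or(
    estimate: float, se: float | None = None, level: float = 0.95
) -> dict:
    """Odds ratio with a Wald interval from a log-odds estimate."""
    out = {"odds_ratio": math.exp(estimate)}
    if se is not None:
        z = float(sps.norm.ppf(0.5 + level / 2.0))
        out["lower"] = math.exp(estimate - z * se)
        out["upper"] = math.exp(estimate + z * se)
    return out


def _level_vector(fit: PrevalenceFit, level: str) -> pd.Series:
    """Coefficient-space indicator of a factor level (reference -> 0)."""
    v = pd.Series(0.0, index=fit.coefficients.index)
    if level in v.index:
        v[level] = 1.0
    return v


def pairwise_contrasts(
    fit: PrevalenceFit,
    family: str = "species",
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """All pairwise log-odds contrasts within one factor family.

    ``family`` is "species" (3 pairs), "months" (6 pairs) or "combined"
    (both families with a single Bonferroni size of 9).  SEs come from
    the delta rule c'Vc on the fitted covariance.
    """
    if family == "species":
        groups = [tuple(fit.species_levels)]
    elif family == "months":
        groups = [tuple(fit.month_levels)]
    elif family == "combined":
        groups = [tuple(fit.species_levels), tuple(fit.month_levels)]
    else:
        raise ValueError("family must be species, months or combined")
    pairs = [p for g in groups for p in itertools.combinations(g, 2)]
    m = len(pairs)
    results = []
    for a, b in pairs:
        c = _level_vector(fit, a) - _level_vector(fit, b)
        est = float(c @ fit.coefficients)
        var = float(c @ fit.covariance @ c)
        se = math.sqrt(max(var, 0.0))
        z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
        p_raw = 2.0 * float(sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        results.append(ContrastResult(
            level_a=a, level_b=b, estimate=est, se=se, z=z,
            p_raw=p_raw, p_adjusted=min(1.0, m * p_raw), family_size=m,
        ))
    return results


def compare_models(fits: Mapping[str, PrevalenceFit]) -> pd.DataFrame:
    """AIC comparison table with delta-AIC relative to the best model."""
    rows = [{"model": name, "aic": f.aic, "loglik": f.loglik,
             "k": len(f.coefficients)} for name, f in fits.items()]
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table


def coefficient_table(fit: PrevalenceFit, level: float = 0.95) -> pd.DataFrame:
    """Reporting table: estimate, OR with Wald CI, SE, z, p per term."""
    rows = []
    for term, est in fit.coefficients.items():
        se = fit.se(term)
        orci = log_odds_to_or(est, se, level)
        z = est / se if se > 0 else math.nan
        rows.append({
            "term": term, "estimate": est,
            "odds_ratio": orci["odds_ratio"],
            "or_lower": orci["lower"], "or_upper": orci["upper"],
            "se": se, "z": z, "p": 2.0 * float(sps.norm.sf(abs(z))),
        })
    return pd.DataFrame(rows)
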