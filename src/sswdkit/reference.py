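"""Published reference values from the Salish Sea SSWD impact study.

These are printed inputs — survey-effort counts by basin and year, and
the coefficient table of the published prevalence logistic model — used
to parameterise realistic simulations and to verify reporting
arithmetic (odds-ratio exponentiation, effort totals).  Nothing here is
computed by this package.
"""

from __future__ import annotations

import pandas as pd

#: Number of roving-diver surveys analysed per basin and year, 2006-2015.
SURVEY_EFFORT: dict[str, dict[int, int]] = {
    "Strait of Georgia":  {2006: 188, 2007: 137, 2008: 106, 2009: 183, 2010: 212,
                           2011: 183, 2012: 326, 2013: 459, 2014: 361, 2015: 358},
    "Northern Straits":   {2006: 182, 2007: 213, 2008: 227, 2009: 303, 2010: 330,
                           2011: 198, 2012: 258, 2013: 322, 2014: 302, 2015: 309},
    "Central Basin":      {2006: 46, 2007: 62, 2008: 98, 2009: 113, 2010: 136,
                           2011: 84, 2012: 95, 2013: 104, 2014: 96, 2015: 144},
    "Hood Canal":         {2006: 123, 2007: 155, 2008: 96, 2009: 132, 2010: 256,
                           2011: 187, 2012: 212, 2013: 100, 2014: 140, 2015: 87},
    "South Puget Sound":  {2006: 27, 2007: 38, 2008: 43, 2009: 45, 2010: 67,
                           2011: 42, 2012: 43, 2013: 39, 2014: 37, 2015: 21},
    "WA Outer Coast":     {2006: 0, 2007: 6, 2008: 8, 2009: 12, 2010: 11,
                           2011: 10, 2012: 10, 2013: 12, 2014: 2, 2015: 1},
}


def survey_effort_frame() -> pd.DataFrame:
    """Survey effort as a tidy frame (basin, year, n_surveys)."""
    rows = [
        {"basin": basin, "year": year, "n_surveys": n}
        for basin, years in SURVEY_EFFORT.items()
        for year, n in years.items()
    ]
    return pd.DataFrame(rows)


def total_surveys() -> int:
    """Total analysed surveys implied by the per-basin effort table."""
    return int(survey_effort_frame()["n_surveys"].sum())


#: Published prevalence logistic-model log-odds estimates and SEs
#: (reference levels: Henricia sp. for species, May for month).
PREVALENCE_ESTIMATES: dict[str, dict[str, float]] = {
    "intercept":        {"estimate": -6.876, "se": 0.715},
    "E. troschelii":    {"estimate": 2.329, "se": 0.509},
    "P. helianthoides": {"estimate": 3.484, "se": 0.520},
    "June":             {"estimate": 1.508, "se": 0.556},
    "July":             {"estimate": 2.642, "se": 0.562},
    "August":           {"estimate": 4.056, "se": 0.694},
}

#: Published posterior means of the density-change model hyperparameters.
DENSITY_MODEL_POSTERIOR_MEANS: dict[str, float] = {
    "mu_alpha": -6.561,
    "mu_beta": -1.258,
    "sigma_alpha": 2.893,
    "sigma_beta": 2.801,
    "rho": -0.384,
}

#: Published taxon densities (stars per 100 m^2) in 2014 and 2015
#: on the strip transects.
TAXON_DENSITIES: dict[str, tuple[float, float]] = {
    "P. helianthoides": (5.5, 0.18),
    "E. troschelii": (2.82, 0.78),
    "Henricia spp.": (7.42, 5.32),
    "P. ochraceus": (0.3, 0.05),
    "P. brevispinus": (0.25, 0.0),
    "O. koehleri": (0.25, 0.0),
    "S. stimpsoni": (0.34, 0.0),
    "L. hexactis": (0.0, 0.05),
    "Mediaster spp.": (0.0, 0.15),
    "D. imbricata": (0.03, 0.22),
}
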