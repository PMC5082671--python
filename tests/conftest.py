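import numpy as np
import pandas as pd
import pytest

import sswdkit as sk


def make_roving_frame(rows):
    """Build a roving-diver record frame from (survey_id, basin, date,
    start_time, duration, habitat, species, category) tuples."""
    return pd.DataFrame(
        rows,
        columns=["survey_id", "basin", "date", "start_time", "duration_min",
                 "habitat", "species", "abundance_category"],
    )


@pytest.fixture(scope="session")
def small_roving():
    """Nine hand-written survey x species rows covering every filter rule."""
    return make_roving_frame([
        ("s1", "A", "2010-06-01", "09:00", 45, "wall", "star", "F"),
        ("s2", "A", "2010-06-02", "10:30", 60, "kelp forest", "star", "M"),
        ("s3", "A", "2010-06-03", "03:30", 45, "wall", "star", "S"),      # too early
        ("s4", "A", "2010-06-04", "09:00", 15, "wall", "star", "A"),      # too short
        ("s5", "A", "2010-06-05", "09:00", 90, "wall", "star", "F"),      # too long
        ("s6", "A", "2010-06-06", "09:00", 45, "sandy bottom", "star", "F"),
        ("s7", "A", "2010-06-07", "22:00", 80, "pinnacle", "star", "0"),  # boundary: keep
        ("s8", "A", "2010-06-08", "04:00", 20, "wall", "star", "S"),      # boundary: keep
        ("s9", "A", "2010-06-09", "09:00", 45, "eelgrass bed", "star", "M"),
    ])


@pytest.fixture(scope="session")
def sim_transects():
    cfg = sk.TransectSimConfig(
        sites=("X", "Y"),
        taxa=(sk.TaxonSim("P. helianthoides", 5.0, -2.0),
              sk.TaxonSim("Henricia spp.", 7.0, -0.3),
              sk.TaxonSim("E. troschelii", 3.0, -1.0)),
        prevalence=sk.PrevalenceLogit(
            intercept=-4.0,
            species_effects={"E. troschelii": 2.3, "P. helianthoides": 3.5},
            month_effects={"June": 1.5, "July": 2.6, "August": 4.0}),
        transects_per_site_month=3,
        seed=42,
    )
    return sk.generate_transect_surveys(cfg)
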