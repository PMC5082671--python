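"""Case classification, prevalence and the logistic model."""

import math

import numpy as np
import pandas as pd
import pytest

import sswdkit as sk
from sswdkit.prevalence import (
    MONTH_LEVELS,
    SPECIES_LEVELS,
    SeparationError,
    coefficient_table,
)


def make_stars(cells, seed=None):
    """Build a star table from (taxon, month, n_cases, n_healthy) cells."""
    rows = []
    for taxon, month, n_case, n_healthy in cells:
        rows += [{"transect_id": "t0", "taxon": taxon, "month": month,
                  "year": 2014, "sswd_status": "case"}] * n_case
        rows += [{"transect_id": "t0", "taxon": taxon, "month": month,
                  "year": 2014, "sswd_status": "healthy"}] * n_healthy
    return pd.DataFrame(rows)


class TestClassifyStar:
    @pytest.mark.parametrize("lesions,arm_loss,uncertain,expected", [
        (True, False, False, "case"),
        (False, True, False, "case"),
        (True, True, False, "case"),
        (True, False, True, "healthy"),   # doubt overrides signs
        (False, False, False, "healthy"),
    ])
    def test_case_definition(self, lesions, arm_loss, uncertain, expected):
        assert sk.classify_star(lesions, arm_loss, uncertain) == expected


class TestPrevalence:
    def test_simple_proportion(self):
        stars = make_stars([("Henricia spp.", "May", 5, 5)])
        out = sk.prevalence_table(stars)
        assert out["prevalence"].iloc[0] == pytest.approx(0.5)

    def test_zero_cases(self):
        stars = make_stars([("Henricia spp.", "May", 0, 20)])
        out = sk.prevalence_table(stars)
        assert out["prevalence"].iloc[0] == 0
        assert out["total"].iloc[0] == 20

    def test_published_july_proportion(self):
        stars = make_stars([("P. helianthoides", "July", 36, 64)])
        out = sk.prevalence_table(stars)
        assert out["prevalence"].iloc[0] == pytest.approx(0.36)

    def test_empty_groups_absent_not_zero(self):
        stars = make_stars([("Henricia spp.", "May", 1, 9)])
        out = sk.prevalence_table(stars)
        assert len(out) == 1  # no phantom rows for unobserved cells


class TestFitPrevalenceModel:
    def test_two_by_two_matches_cross_product_ratio(self):
        a, b, c, d = 12, 38, 5, 45  # cases/healthy per species
        stars = make_stars([
            ("Henricia spp.", "May", c, d),
            ("E. troschelii", "May", a, b),
        ])
        fit = sk.fit_prevalence_model(
            stars, species_levels=("Henricia spp.", "E. troschelii"),
            include_months=False)
        fitted_or = math.exp(fit.coefficients["E. troschelii"])
        assert fitted_or == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6000):
            rows.append({
                "taxon": SPECIES_LEVELS[i % 3], "month": MONTH_LEVELS[i % 4],
                "year": 2014, "transect_id": "t",
                "sswd_status": "case" if rng.random() < 0.3 else "healthy"})
        fit = sk.fit_prevalence_model(pd.DataFrame(rows))
        for term in fit.coefficients.index:
            if term != "intercept":
                assert abs(fit.coefficients[term]) < 3 * fit.se(term)

    def test_duplication_sufficiency(self):
        stars = make_stars([
            ("Henricia spp.", "May", 2, 30), ("Henricia spp.", "June", 3, 27),
            ("E. troschelii", "May", 5, 28), ("E. troschelii", "June", 8, 25),
            ("P. helianthoides", "May", 9, 26), ("P. helianthoides", "June", 15, 20),
        ])
        fit1 = sk.fit_prevalence_model(stars)
        fit2 = sk.fit_prevalence_model(
            pd.concat([stars, stars], ignore_index=True))
        pd.testing.assert_series_equal(fit1.coefficients, fit2.coefficients,
                                       atol=1e-8)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-6)

    def test_single_class_outcome_rejected(self):
        stars = make_stars([("Henricia spp.", "May", 0, 10)])
        with pytest.raises(ValueError, match="both healthy"):
            sk.fit_prevalence_model(stars)

    def test_separation_detected(self):
        stars = make_stars([
            ("Henricia spp.", "May", 0, 40),
            ("P. helianthoides", "May", 40, 0),
        ])
        with pytest.raises(SeparationError):
            sk.fit_prevalence_model(
                stars,
                species_levels=("Henricia spp.", "P. helianthoides"),
                include_months=False)

    def test_score_equation_fitted_sum_equals_cases(self):
        stars = make_stars([
            ("Henricia spp.", "May", 2, 30), ("Henricia spp.", "August", 4, 22),
            ("E. troschelii", "May", 3, 29), ("E. troschelii", "June", 8, 25),
            ("P. helianthoides", "July", 15, 20), ("P. helianthoides", "May", 6, 30),
        ])
        fit = sk.fit_prevalence_model(stars)
        from sswdkit.prevalence import _design
        X = _design(stars, SPECIES_LEVELS, MONTH_LEVELS)[fit.coefficients.index]
        p = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        assert p.sum() == pytest.approx((stars["sswd_status"] == "case").sum(),
                                        rel=1e-6)
        assert ((p > 0) & (p < 1)).all()


class TestOddsRatios:
    @pytest.mark.parametrize("estimate,expected", [
        (3.484, 32.59), (1.508, 4.52), (2.642, 14.04),
    ])
    def test_published_log_odds_exponentiate(self, estimate, expected):
        assert sk.log_odds_to_or(estimate)["odds_ratio"] == pytest.approx(
            expected, abs=0.005)

    def test_zero_is_unity(self):
        assert sk.log_odds_to_or(0.0)["odds_ratio"] == 1.0

    def test_wald_interval_brackets(self):
        out = sk.log_odds_to_or(1.0, 0.5)
        assert out["lower"] < out["odds_ratio"] < out["upper"]
        assert out["lower"] == pytest.approx(math.exp(1 - 1.959964 * 0.5), rel=1e-6)


class TestContrasts:
    @pytest.fixture(scope="class")
    def fit(self):
        stars = make_stars([
            ("Henricia spp.", "May", 2, 48), ("E. troschelii", "May", 8, 40),
            ("P. helianthoides", "May", 20, 30),
            ("Henricia spp.", "June", 4, 46), ("E. troschelii", "July", 12, 38),
            ("P. helianthoides", "August", 30, 20),
        ])
        return sk.fit_prevalence_model(stars)

    def test_family_sizes(self, fit):
        assert len(sk.pairwise_contrasts(fit, "species")) == 3
        assert len(sk.pairwise_contrasts(fit, "months")) == 6
        assert len(sk.pairwise_contrasts(fit, "combined")) == 9

    def test_bonferroni_multiplier(self, fit):
        for c in sk.pairwise_contrasts(fit, "species"):
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_nonreference_contrast_is_coefficient_difference(self, fit):
        contrasts = {(c.level_a, c.level_b): c
                     for c in sk.pairwise_contrasts(fit, "species")}
        c = contrasts[("E. troschelii", "P. helianthoides")]
        expected = (fit.coefficients["E. troschelii"]
                    - fit.coefficients["P. helianthoides"])
        assert c.estimate == pytest.approx(expected)

    def test_reference_contrast_is_negated_coefficient(self, fit):
        contrasts = {(c.level_a, c.level_b): c
                     for c in sk.pairwise_contrasts(fit, "species")}
        c = contrasts[("Henricia spp.", "E. troschelii")]
        assert c.estimate == pytest.approx(-fit.coefficients["E. troschelii"])
        assert c.se == pytest.approx(fit.se("E. troschelii"))


class TestCompareModels:
    def test_identical_fits_zero_delta(self):
        stars = make_stars([
            ("Henricia spp.", "May", 5, 45), ("P. helianthoides", "June", 20, 30)])
        fit = sk.fit_prevalence_model(stars)
        table = sk.compare_models({"a": fit, "b": fit})
        assert (table["delta_aic"] == 0).all()

    def test_full_model_wins_on_strong_effects(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(4000):
            sp = SPECIES_LEVELS[i % 3]
            mo = MONTH_LEVELS[i % 4]
            logit = -3.0 + {"E. troschelii": 2.3, "P. helianthoides": 3.5}.get(sp, 0) \
                + {"June": 1.5, "July": 2.6, "August": 4.0}.get(mo, 0)
            p = 1 / (1 + math.exp(-logit))
            rows.append({"taxon": sp, "month": mo, "year": 2014, "transect_id": "t",
                         "sswd_status": "case" if rng.random() < p else "healthy"})
        stars = pd.DataFrame(rows)
        full = sk.fit_prevalence_model(stars)
        null_sp = sk.fit_prevalence_model(stars, include_species=False)
        null_mo = sk.fit_prevalence_model(stars, include_months=False)
        table = sk.compare_models({"species+month": full, "month": null_sp,
                                   "species": null_mo})
        assert table.iloc[0]["model"] == "species+month"

    def test_aic_penalty(self):
        # one extra parameter at equal log-likelihood costs exactly 2
        assert (-2 * -100.0 + 2 * 4) - (-2 * -100.0 + 2 * 3) == 2


class TestCoefficientTable:
    def test_columns_and_or_consistency(self):
        stars = make_stars([
            ("Henricia spp.", "May", 2, 48), ("P. helianthoides", "July", 20, 30)])
        fit = sk.fit_prevalence_model(stars)
        table = coefficient_table(fit)
        assert {"term", "estimate", "odds_ratio", "or_lower", "or_upper",
                "se", "z", "p"} <= set(table.columns)
        row = table.set_index("term").loc["P. helianthoides"]
        assert row["odds_ratio"] == pytest.approx(math.exp(row["estimate"]))
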