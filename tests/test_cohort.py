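"""Synthetic-cohort generator: covariate margins, outcome model,
prevalence calibration, determinism and round-tripping."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from suicohort import (
    calibrate_year_offsets,
    default_anchors,
    default_config,
    expected_prevalence,
    generate_cohort,
    linear_predictor,
)
from suicohort.coding import SCHOOL_YEARS, classify_k10, code_records
from suicohort.cohort import (
    CohortGenerator,
    PrevalenceAnchor,
    sample_covariates,
    sample_outcomes,
)


def _profile(**kw):
    base = {
        "school_year": "2013/2014",
        "gender": "male",
        "age_band_ml": "<18",
        "risk": "low",
        "era": "pre_corona",
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestLinearPredictor:
    def test_reference_profile_is_intercept(self):
        cfg = default_config()
        eta = linear_predictor(cfg.si_coefficients, _profile())
        assert eta[0] == pytest.approx(-3.52)

    def test_hand_sum_with_interaction(self):
        cfg = default_config()
        eta = linear_predictor(cfg.si_coefficients, _profile(risk="high"))
        assert eta[0] == pytest.approx(-3.52 + 3.76 + 0.24)

    def test_zero_model_gives_even_odds(self):
        eta = linear_predictor({"intercept": 0.0}, _profile())
        assert expit(eta[0]) == 0.5

    def test_unknown_term_errors(self):
        from suicohort.coding import CodingError

        with pytest.raises(CodingError):
            linear_predictor({"intercept": 0.0, "elderly": 1.0}, _profile())

    def test_year_offsets_added(self):
        eta = linear_predictor(
            {"intercept": -1.0}, _profile(), year_offsets={"2013/2014": 0.5}
        )
        assert eta[0] == pytest.approx(-0.5)


class TestSampleCovariates:
    def test_degenerate_gender(self):
        cfg = default_config(gender_probs={"male": 1.0, "female": 0.0})
        rng = np.random.default_rng(0)
        df = sample_covariates(cfg, 500, "2013/2014", rng)
        assert (df["gender"] == "male").all()

    def test_gender_risk_margins(self):
        # across the default year range the per-gender high-risk shares
        # should average to the study's per-gender margins
        cfg = default_config(n_per_year=10_000)
        raw = generate_cohort(cfg, seed=11)
        coded = code_records(raw)
        for gender, target in (("male", 0.1150), ("female", 0.2277)):
            share = (coded[coded["gender"] == gender]["risk"] == "high").mean()
            assert share == pytest.approx(target, abs=0.005)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            default_config(gender_probs={"male": 0.7, "female": 0.7})


class TestSampleOutcomes:
    def test_saturated_logit_all_false(self):
        cfg = default_config(si_coefficients={"intercept": -50.0})
        rng = np.random.default_rng(0)
        raw = sample_covariates(cfg, 200, "2013/2014", rng)
        out = sample_outcomes(cfg, raw, rng)
        assert (out["si"] == "never").all()

    def test_even_odds_proportion(self):
        cfg = default_config(si_coefficients={"intercept": 0.0})
        rng = np.random.default_rng(1)
        raw = sample_covariates(cfg, 10_000, "2013/2014", rng)
        out = sample_outcomes(cfg, raw, rng)
        assert (out["si"] != "never").mean() == pytest.approx(0.5, abs=0.02)

    def test_high_risk_subgroup_rate_matches_inverse_logit(self):
        # male, <18, high risk, pre-corona: eta = -3.52+3.76+0.24 = 0.48
        cfg = default_config(
            gender_probs={"male": 1.0, "female": 0.0},
            age_band_probs={"15-17": 1.0, "18-20": 0.0, "21-23+": 0.0},
        )
        rng = np.random.default_rng(2)
        raw = sample_covariates(cfg, 40_000, "2013/2014", rng)
        out = sample_outcomes(cfg, raw, rng)
        high = out[out["k10_score"] >= 30]
        assert (high["si"] != "never").mean() == pytest.approx(
            expit(0.48), abs=0.02
        )


class TestCalibration:
    def test_fixed_point_offset_zero(self):
        cfg = default_config(years=("2013/2014",))
        p0 = expected_prevalence(cfg, "2013/2014", "si", offset=0.0)
        offs = calibrate_year_offsets(
            cfg, [PrevalenceAnchor("2013/2014", p0, 0.02)], "si"
        )
        assert offs["2013/2014"] == pytest.approx(0.0, abs=1e-8)

    def test_anchor_recovered_analytically(self):
        cfg = default_config(years=("2013/2014", "2022/2023"))
        calibrate_year_offsets(cfg, default_anchors(cfg.years), "si")
        for year, target in (("2013/2014", 0.177), ("2022/2023", 0.230)):
            assert expected_prevalence(cfg, year, "si") == pytest.approx(
                target, abs=1e-8
            )

    def test_offsets_monotone_in_anchor(self):
        cfg = default_config(years=("2013/2014", "2014/2015"))
        # identical covariate mixtures, increasing anchors
        cfg.risk_probs_by_gender_year = {
            (g, y): cfg.risk_probs_by_gender_year[(g, "2013/2014")]
            for g, y in cfg.risk_probs_by_gender_year
        }
        offs = calibrate_year_offsets(
            cfg,
            [PrevalenceAnchor("2013/2014", 0.177, 0.02),
             PrevalenceAnchor("2014/2015", 0.230, 0.02)],
            "si",
        )
        assert offs["2014/2015"] > offs["2013/2014"]

    def test_missing_anchor_errors(self):
        cfg = default_config(years=("2013/2014", "2014/2015"))
        with pytest.raises(ValueError):
            calibrate_year_offsets(
                cfg, [PrevalenceAnchor("2013/2014", 0.2, 0.02)], "si"
            )

    def test_anchor_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PrevalenceAnchor("2013/2014", 1.2, 0.02)


class TestGenerateCohort:
    def test_empty_config(self):
        cfg = default_config(n_per_year=0, years=("2013/2014",))
        df = generate_cohort(cfg, seed=0)
        assert len(df) == 0
        assert list(df.columns) == ["school_year", "age", "gender", "k10_score", "si", "sa"]

    def test_seed_determinism(self):
        cfg = default_config(n_per_year=500, years=SCHOOL_YEARS[:3])
        a = generate_cohort(cfg, seed=42)
        b = generate_cohort(cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(cfg, seed=43)
        assert not a.equals(c)

    def test_round_trip_through_coding(self):
        cfg = default_config(n_per_year=1_000, years=SCHOOL_YEARS[:2])
        raw = generate_cohort(cfg, seed=5)
        coded = code_records(raw)
        # risk band reproduces the generating band exactly
        assert (coded["risk"] == raw["k10_score"].map(classify_k10)).all()
        assert coded["age_band3"].notna().all()
        assert coded["era"].notna().all()

    def test_generator_wrapper_reports_calibration(self):
        gen = CohortGenerator(default_config(n_per_year=100, years=("2013/2014",)))
        gen.calibrate()
        rep = gen.calibration_["2013/2014"]
        assert rep["si"]["achieved"] == pytest.approx(0.177, abs=1e-8)
        assert rep["sa"]["achieved"] == pytest.approx(0.023, abs=1e-8)
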