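"""Generator behavior: determinism, composition, and effect recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotspred import simulate
from cotspred.simulate import COVER_CATEGORIES, ConfigError, SurveyConfig


class TestSurvey:
    def test_same_seed_identical_different_seed_not(self):
        a = simulate.generate_survey(SurveyConfig(seed=3))
        b = simulate.generate_survey(SurveyConfig(seed=3))
        c = simulate.generate_survey(SurveyConfig(seed=4))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_study_design_shape(self, survey_default):
        """Default design mirrors the field survey: 54/6/56 transects with
        120 m^2 transects in south/central and 40 m^2 in the north."""
        n = survey_default.groupby("region").size()
        assert n["south"] == 54 and n["central"] == 6 and n["north"] == 56
        areas = survey_default.groupby("region")["area_m2"].unique()
        assert set(areas["south"]) == {120.0}
        assert set(areas["north"]) == {40.0}

    def test_cover_sums_to_one(self, survey_default):
        cover = survey_default[[f"cover_{c}" for c in COVER_CATEGORIES]].sum(axis=1)
        assert np.allclose(cover, 1.0, atol=1e-9)

    def test_counts_nonnegative_integers(self, survey_default):
        for t in ("s_aspera", "portunidae", "xanthidae", "epialtidae"):
            col = survey_default[f"count_{t}"]
            assert (col >= 0).all() and col.dtype.kind == "i"

    def test_null_model_decouples_rubble_and_thickness(self):
        """With every path coefficient zero, rubble cover and bed thickness
        are independent: |r| < 0.05 at n = 10,000."""
        cfg = SurveyConfig(
            regions=("south",),
            sites_per_reef=20,
            transects_per_site=500,
            transect_area_m2=120.0,
            path_coefficients={},
            seed=11,
        )
        df = simulate.generate_survey(cfg)
        assert len(df) == 10_000
        r = np.corrcoef(df["cover_rubble"], df["rubble_thickness_cm"])[0, 1]
        assert abs(r) < 0.05
        r2 = np.corrcoef(
            df["count_s_aspera"] * 100 / df["area_m2"], df["cots_index"]
        )[0, 1]
        assert abs(r2) < 0.05

    def test_configured_predation_path_recovered(self):
        """s_aspera -> CoTS coefficient -0.5 is recovered as the empirical
        standardized regression slope within +-0.05 at n = 5,000."""
        paths = dict(simulate.DEFAULT_PATHS)
        paths[("s_aspera", "cots")] = -0.5
        cfg = SurveyConfig(
            regions=("south",),
            sites_per_reef=10,
            transects_per_site=500,
            transect_area_m2=120.0,
            path_coefficients=paths,
            seed=5,
        )
        df = simulate.generate_survey(cfg)
        dens = df["count_s_aspera"] * 100 / df["area_m2"]
        zx = (dens - dens.mean()) / dens.std()
        zy = (df["cots_index"] - df["cots_index"].mean()) / df["cots_index"].std()
        slope = float(np.polyfit(zx, zy, 1)[0])
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_bad_cover_weights_rejected(self):
        weights = dict(simulate.DEFAULT_COVER_WEIGHTS)
        weights["rubble"] += 0.1
        with pytest.raises(ConfigError, match="sum to 1"):
            SurveyConfig(cover_weights=weights)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_cover_composition_closed_under_any_seed(self, seed):
        cfg = SurveyConfig(
            regions=("south",), sites_per_reef=2, transects_per_site=3,
            transect_area_m2=120.0, seed=seed,
        )
        df = simulate.generate_survey(cfg)
        cover = df[[f"cover_{c}" for c in COVER_CATEGORIES]].to_numpy()
        assert np.allclose(cover.sum(axis=1), 1.0, atol=1e-9)
        assert (cover >= 0).all()


class TestFeedingTrials:
    def test_default_design_has_16_records(self, trials_fixture):
        assert len(trials_fixture) == 16
        per_hour = trials_fixture.groupby("hours_post_ingestion").size().to_dict()
        assert per_hour == {1.0: 3, 3.0: 5, 9.0: 2, 12.0: 3, 48.0: 3}

    def test_flat_decay_at_p0_one_detects_everything(self):
        df = simulate.generate_feeding_trials(
            decay_params={"p0": 1.0, "slope": 0.0}, seed=1
        )
        assert df["detected"].all()
        assert (df[["rep1_positive", "rep2_positive"]].sum(axis=1) >= 1).all()

    def test_tuned_48h_fraction_matches_decay_curve(self):
        """Decay tuned so p(48) = 1/3 produces a positive fraction within
        +-0.03 of 1/3 among 3,000 specimens at 48 h."""
        from scipy.optimize import brentq

        slope = 0.09
        half = brentq(
            lambda h: simulate.detection_probability(48.0, 1.0, h, slope) - 1 / 3,
            1.0, 47.9,
        )
        params = {"p0": 1.0, "halftime_h": half, "slope": slope}
        df = simulate.generate_feeding_trials(params, design={48.0: 3000}, seed=8)
        assert df["detected"].mean() == pytest.approx(1 / 3, abs=0.03)

    def test_detection_consistent_with_droplets(self, trials_fixture):
        any_pos = (trials_fixture["rep1_positive"] > 0) | (trials_fixture["rep2_positive"] > 0)
        assert (any_pos == trials_fixture["detected"]).all()

    def test_copy_numbers_peak_between_9_and_12h(self):
        t = np.linspace(0.5, 48, 400)
        m = simulate._log_copies_mean(t)
        assert 9.0 <= t[np.argmax(m)] <= 12.0

    def test_empty_design_rejected(self):
        with pytest.raises(ConfigError):
            simulate.generate_feeding_trials(design={}, seed=0)


class TestSpecimenScreen:
    def test_exact_counts_reproduce_screening_fixture(self, screen_fixture):
        by = screen_fixture.groupby("region")["detected"].agg(["sum", "count"])
        assert by.loc["south", "sum"] == 2 and by.loc["south", "count"] == 12
        assert by.loc["north", "sum"] == 7 and by.loc["north", "count"] == 63

    def test_zero_positivity_means_no_copies(self):
        df = simulate.generate_specimen_screen(
            {"south": {"n": 10, "p_pos": 0.0}}, seed=2
        )
        assert (~df["detected"]).all()
        assert (df["copies_per_sample"] == 0).all()

    def test_full_positivity_all_detected_with_droplets(self):
        df = simulate.generate_specimen_screen(
            {"north": {"n": 10, "p_pos": 1.0}}, seed=2
        )
        assert df["detected"].all() and len(df) == 10
        assert (df[["rep1_positive", "rep2_positive"]].max(axis=1) >= 1).all()


class TestDroplets:
    def test_zero_concentration_gives_no_positives(self):
        assert simulate.simulate_droplets(0.0, 1000, 1) == (0, 1000)

    def test_saturating_concentration_fills_all_droplets(self):
        k, n = simulate.simulate_droplets(50.0, 2000, 1)
        assert k == n

    def test_poisson_occupancy_fraction(self):
        """At lambda = 1, the positive fraction approaches 1 - 1/e."""
        k, n = simulate.simulate_droplets(1.0, 100_000, 3)
        assert k / n == pytest.approx(1 - np.exp(-1), abs=0.005)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_droplets(-0.1, 100, 1)
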