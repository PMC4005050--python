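"""Conditions A-D, forecast modes, rainfall rules and the estimator API."""

import datetime as dt

import numpy as np
import pytest
from sklearn.base import clone

from mcda.classifier import (
    MCDAClassifier,
    MCDAParameters,
    RainfallSeries,
    classify,
    condition_a,
    condition_b,
    first_forecast,
    second_forecast,
    sowing_onset,
    water_deficit,
)
from mcda.composites import (
    CompositeImage,
    CompositeSeries,
    CropYearWindows,
    EmptyWindowError,
    EVIComposite,
)

PARAMS = MCDAParameters()  # Lmin 0.05, Umin 0.39, Amp 0.36


def image(kind, values):
    return CompositeImage(np.asarray(values, dtype=float), kind)


def dekads(start, amounts):
    return [
        (start + dt.timedelta(days=10 * i), mm) for i, mm in enumerate(amounts)
    ]


class TestParameters:
    def test_ordering_invariant(self):
        with pytest.raises(ValueError, match="Lmin"):
            MCDAParameters(lmin=0.4, umin=0.3)

    def test_amp_must_be_positive(self):
        with pytest.raises(ValueError, match="Amp"):
            MCDAParameters(amp=0.0)

    def test_immutable(self):
        with pytest.raises(AttributeError):
            PARAMS.amp = 0.5


class TestConditions:
    def test_condition_a_interval(self):
        img = image("min_mean", [[0.20, 0.02, 0.50]])
        np.testing.assert_array_equal(
            condition_a(img, PARAMS), [[True, False, False]]
        )

    def test_condition_a_closed_bounds(self):
        img = image("min_mean", [[0.05, 0.39]])
        assert condition_a(img, PARAMS).all()
        strict = MCDAParameters(strict_inequalities=True)
        assert not condition_a(img, strict).any()

    def test_condition_a_nodata_false(self):
        img = image("min_mean", [[np.nan]])
        assert not condition_a(img, PARAMS).any()

    def test_condition_b_threshold(self):
        img = image("amplitude", [[0.60, 0.36, 0.10]])
        np.testing.assert_array_equal(
            condition_b(img, PARAMS), [[True, True, False]]
        )

    def test_condition_b_strict_excludes_boundary(self):
        img = image("amplitude", [[0.36]])
        assert not condition_b(img, MCDAParameters(strict_inequalities=True)).any()

    def test_kind_checked(self):
        with pytest.raises(ValueError, match="min_mean"):
            condition_a(image("amplitude", [[0.2]]), PARAMS)
        with pytest.raises(ValueError, match="amplitude"):
            condition_b(image("min_mean", [[0.2]]), PARAMS)


class TestClassify:
    def setup_method(self):
        # pixel 0: soybean; pixel 1: steep soybean; pixel 2: forest
        self.min_img = image("min_mean", [[0.20, 0.20, 0.55]])
        self.max_img = image("max_mean", [[0.80, 0.80, 0.75]])

    def test_conjunction_of_conditions(self):
        terrain = np.array([[True, False, True]])
        result = classify(self.min_img, self.max_img, terrain_mask=terrain)
        np.testing.assert_array_equal(result.mask, [[True, False, False]])

    def test_mask_subset_of_terrain_and_management(self):
        rng = np.random.default_rng(5)
        terrain = rng.random((1, 3)) < 0.5
        management = rng.random((1, 3)) < 0.5
        result = classify(
            self.min_img, self.max_img, terrain_mask=terrain,
            management_mask=management,
        )
        assert not (result.mask & ~terrain).any()
        assert not (result.mask & ~management).any()

    def test_condition_masks_conjunction_invariant(self):
        result = classify(self.min_img, self.max_img)
        cm = result.condition_masks
        recomposed = cm["A"] & cm["B"] & cm["C"] & cm["D"] & ~result.nodata_mask
        np.testing.assert_array_equal(result.mask, recomposed)

    def test_deterministic_rerun(self):
        a = classify(self.min_img, self.max_img)
        b = classify(self.min_img, self.max_img)
        assert a.mask.tobytes() == b.mask.tobytes()

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify(self.min_img, image("max_mean", [[0.8, 0.8]]))

    def test_amp_monotonicity_never_adds_pixels(self):
        rng = np.random.default_rng(11)
        min_img = image("min_mean", rng.uniform(0, 0.5, (30, 30)))
        max_img = image("max_mean", rng.uniform(0.2, 0.9, (30, 30)))
        previous = None
        for amp in np.linspace(0.05, 0.7, 12):
            mask = classify(
                min_img, max_img, params=MCDAParameters(amp=amp)
            ).mask
            if previous is not None:
                assert not (mask & ~previous).any()
            previous = mask

    def test_narrowing_interval_never_adds_pixels(self):
        rng = np.random.default_rng(12)
        min_img = image("min_mean", rng.uniform(0, 0.5, (30, 30)))
        max_img = image("max_mean", rng.uniform(0.2, 0.9, (30, 30)))
        wide = classify(
            min_img, max_img, params=MCDAParameters(lmin=0.02, umin=0.45)
        ).mask
        narrow = classify(
            min_img, max_img, params=MCDAParameters(lmin=0.08, umin=0.35)
        ).mask
        assert not (narrow & ~wide).any()


class TestWaterDeficit:
    def test_forty_dry_days_is_deficit(self):
        rain = RainfallSeries("s1", dekads(dt.date(2006, 12, 1), [0, 5, 8, 2]))
        assert water_deficit(rain, dt.date(2006, 12, 1), dt.date(2007, 1, 9))

    def test_regular_events_prevent_deficit(self):
        rain = RainfallSeries("s1", dekads(dt.date(2006, 12, 1), [12] * 6))
        assert not water_deficit(rain, dt.date(2006, 12, 1), dt.date(2007, 1, 30))

    def test_mid_window_event_splits_dry_spell(self):
        # 25 dry days, one 15 mm event, 25 dry days -> no 30-day span
        records = [
            (dt.date(2006, 12, 1), 2.0),
            (dt.date(2006, 12, 11), 4.0),
            (dt.date(2006, 12, 21), 3.0),
            (dt.date(2006, 12, 26), 15.0),
            (dt.date(2007, 1, 5), 6.0),
            (dt.date(2007, 1, 15), 1.0),
        ]
        rain = RainfallSeries("s1", records)
        assert not water_deficit(rain, dt.date(2006, 12, 1), dt.date(2007, 1, 20))

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            water_deficit(
                RainfallSeries("s1", []), dt.date(2006, 12, 1), dt.date(2007, 1, 1)
            )

    def test_dates_must_increase(self):
        with pytest.raises(ValueError, match="increase"):
            RainfallSeries(
                "s1", [(dt.date(2006, 1, 11), 1.0), (dt.date(2006, 1, 1), 1.0)]
            )


class TestSowingOnset:
    def test_first_exceedance_after_september(self):
        rain = RainfallSeries("s1", dekads(dt.date(2006, 9, 1), [2, 5, 30, 40]))
        assert sowing_onset(rain, 2006) == dt.date(2006, 9, 21)

    def test_all_dry_season_undetermined(self):
        rain = RainfallSeries("s1", dekads(dt.date(2006, 9, 1), [2, 5, 3, 4]))
        assert sowing_onset(rain, 2006) is None

    def test_zero_threshold_returns_first_record(self):
        rain = RainfallSeries("s1", dekads(dt.date(2006, 9, 1), [2, 5, 30]))
        assert sowing_onset(rain, 2006, threshold_mm=0.0) == dt.date(2006, 9, 1)


def synthetic_two_year_series(prior_peak=0.8, current_peak=0.8, low=0.2):
    """Soybean-like single pixel covering crop years 2005 and 2006."""
    comps = []
    for year, peak in ((2005, prior_peak), (2006, current_peak)):
        for doy in range(225, 338, 16):
            comps.append(EVIComposite(np.full((1, 1), low), year, doy))
        comps.append(EVIComposite(np.full((1, 1), peak), year, 353))
        for doy in (1, 17, 33):
            comps.append(EVIComposite(np.full((1, 1), peak), year + 1, doy))
    return CompositeSeries(comps)


class TestForecastModes:
    def test_second_forecast_uses_current_year(self):
        series = synthetic_two_year_series()
        result = second_forecast(series, 2006)
        assert result.mask[0, 0]
        assert result.forecast_mode == "second"
        assert not result.fallback_used
        assert (2006, 353) in result.source_tags["max"]

    def test_first_forecast_uses_prior_year_peak(self):
        series = synthetic_two_year_series()
        result = first_forecast(series, 2006)
        assert result.mask[0, 0]
        assert result.fallback_used
        assert result.source_tags["max_crop_year"] == 2005
        assert (2005, 353) in result.source_tags["max"]

    def test_first_forecast_unavailable_for_earliest_year(self):
        series = synthetic_two_year_series()
        with pytest.raises(EmptyWindowError, match="first forecast unavailable"):
            first_forecast(series, 2005)

    def test_newly_converted_pixel_missed_by_first_forecast(self):
        # prior-year peak low (pasture converted to soybean this year)
        series = synthetic_two_year_series(prior_peak=0.25)
        assert not first_forecast(series, 2006).mask[0, 0]
        assert second_forecast(series, 2006).mask[0, 0]

    def test_modes_agree_when_peak_is_stationary(self):
        series = synthetic_two_year_series(prior_peak=0.8, current_peak=0.8)
        a = first_forecast(series, 2006)
        b = second_forecast(series, 2006)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_second_forecast_falls_back_without_current_peak(self):
        series = synthetic_two_year_series()
        trimmed = CompositeSeries(
            [c for c in series if not (c.year == 2006 and c.doy >= 353)
             and c.year != 2007]
        )
        result = second_forecast(trimmed, 2006)
        assert result.fallback_used
        assert result.mask[0, 0]

    def test_water_deficit_triggers_prior_year_substitution(self):
        series = synthetic_two_year_series(current_peak=0.3)  # drought-hit peak
        dry = RainfallSeries(
            "s1", dekads(dt.date(2006, 11, 1), [2.0] * 12)
        )
        result = second_forecast(series, 2006, rain=dry)
        assert result.fallback_used
        assert result.mask[0, 0]  # prior normal year substitutes
        wet = RainfallSeries("s1", dekads(dt.date(2006, 11, 1), [20.0] * 12))
        assert not second_forecast(series, 2006, rain=wet).mask[0, 0]


class TestEstimatorAPI:
    def test_pinned_parameters_predict(self):
        clf = MCDAClassifier(calibrate=False).fit(np.empty((0, 2)))
        X = [[0.20, 0.80], [0.55, 0.70], [0.01, 0.60], [0.20, 0.40]]
        np.testing.assert_array_equal(clf.predict(X), [1, 0, 0, 0])
        assert clf.params_.lmin == 0.05

    def test_get_set_params_and_clone(self):
        clf = MCDAClassifier(amp=0.4)
        assert clf.get_params()["amp"] == 0.4
        clf.set_params(amp=0.3)
        cloned = clone(clf)
        assert cloned.get_params()["amp"] == 0.3

    def test_fit_calibrates_from_two_population_scatter(self):
        rng = np.random.default_rng(21)
        n = 4000
        crop = np.column_stack(
            [rng.normal(0.2, 0.03, n), rng.normal(0.8, 0.04, n)]
        )
        savanna = np.column_stack([rng.normal(0.5, 0.03, n)] * 2)
        savanna[:, 1] += rng.normal(0, 0.01, n)
        X = np.vstack([crop, savanna])
        clf = MCDAClassifier().fit(X)
        assert 0.35 <= clf.umin_ <= 0.5
        assert clf.lmin_ < 0.2
        assert 0.1 <= clf.amp_ <= 0.55
        # recovered thresholds separate the populations
        assert clf.predict(crop).mean() > 0.95
        assert clf.predict(savanna).mean() < 0.05

    def test_predict_requires_fit(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            MCDAClassifier().predict([[0.2, 0.8]])
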