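import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenospring import (
    CalibrationGrid,
    DataError,
    DailyTemperatureSeries,
    PhenoObservation,
    SpeciesModelParams,
    StationRecord,
    adjust_to_station_elevation,
    calibrate_species,
    cross_validate,
    daily_gdh,
    daylength,
    diurnal_temperatures,
    predict_onset,
    predict_onsets_multi,
)
from phenospring.phenomodel import UnusableStationYear


def daylength_oracle(lat_deg, doy, year_length=365.0):
    """Independent re-implementation of the declination daylength."""
    decl = math.radians(-23.44 * math.cos(2 * math.pi * (doy + 10) / year_length))
    x = -math.tan(math.radians(lat_deg)) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 * math.acos(x) / math.pi


def gdh_oracle(tmin, tmax, t_base):
    """Brute-force hourly accumulation through the public diurnal curve."""
    return sum(max(0.0, t - t_base) for t in diurnal_temperatures(tmin, tmax))


def constant_series(year, t):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31")
    n = len(dates)
    return DailyTemperatureSeries(
        "C", pd.DataFrame({"tmin": np.full(n, t), "tmax": np.full(n, t)},
                          index=dates))


class TestDaylength:
    def test_equator_always_12h(self):
        assert np.allclose(daylength(0.0, np.arange(1, 366)), 12.0)

    def test_midlatitude_solstice_matches_oracle(self):
        got = daylength(46.0, 172)
        assert got == pytest.approx(daylength_oracle(46.0, 172), abs=1e-12)
        assert got == pytest.approx(15.6, abs=0.15)

    def test_polar_day_clamps_to_24(self):
        assert daylength(80.0, 172) == 24.0

    def test_polar_night_clamps_to_0(self):
        assert daylength(-80.0, 172) == 0.0

    @given(lat=st.floats(-89, 89), doy=st.integers(1, 365))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_everywhere(self, lat, doy):
        assert daylength(lat, doy) == pytest.approx(
            daylength_oracle(lat, doy), abs=1e-10)


class TestDiurnal:
    def test_constant_day(self):
        assert np.allclose(diurnal_temperatures(5.0, 5.0), 5.0)

    def test_endpoints_and_mean(self):
        t = diurnal_temperatures(0.0, 10.0)
        assert t[0] == pytest.approx(0.0)
        assert t[12] == pytest.approx(10.0)
        assert t.mean() == pytest.approx(5.0)

    def test_quarter_period_is_midpoint(self):
        assert diurnal_temperatures(-3.0, 7.0)[6] == pytest.approx(2.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(DataError):
            diurnal_temperatures(3.0, 1.0)


class TestDailyGDH:
    def test_constant_exceedance(self):
        assert daily_gdh(6.0, 6.0, 5.0) == pytest.approx(24.0)

    def test_no_forcing_below_base(self):
        assert daily_gdh(-5.0, 4.0, 5.0) == 0.0

    def test_partially_clipped_day_matches_hourly_oracle(self):
        assert daily_gdh(0.0, 10.0, 5.0) == pytest.approx(
            gdh_oracle(0.0, 10.0, 5.0), abs=1e-9)

    @given(tmin=st.floats(-20, 15), spread=st.floats(0, 15),
           t_base=st.floats(-5, 10))
    @settings(max_examples=60, deadline=None)
    def test_closed_form_when_base_below_tmin(self, tmin, spread, t_base):
        tmax = tmin + spread
        if t_base <= tmin:
            expected = 24.0 * ((tmin + tmax) / 2.0 - t_base)
            assert daily_gdh(tmin, tmax, t_base) == pytest.approx(
                expected, abs=1e-8)

    def test_annual_closed_form(self, rng):
        tmin = rng.uniform(2, 10, 365)
        tmax = tmin + rng.uniform(0, 10, 365)
        total = daily_gdh(tmin, tmax, 1.0).sum()
        assert total == pytest.approx(
            24.0 * ((tmin + tmax) / 2 - 1.0).sum(), rel=1e-12)


class TestPredictOnset:
    def test_constant_temperature_closed_form(self):
        params = SpeciesModelParams("dandelion", t_base=2.0, f_star=1000.0,
                                    k_photo=0.0)
        series = constant_series(2019, 7.0)  # forcing 24*5 = 120 per day
        pred = predict_onset(series, 46.0, params, 2019)
        assert pred.predicted_doy == math.ceil(1000.0 / 120.0)

    def test_threshold_never_reached(self):
        params = SpeciesModelParams("dandelion", t_base=2.0, f_star=1e9)
        pred = predict_onset(constant_series(2019, 7.0), 46.0, params, 2019)
        assert pred.predicted_doy is None and not pred.reached

    def test_forcing_trace_is_nondecreasing(self):
        params = SpeciesModelParams("dandelion", t_base=2.0, f_star=1000.0)
        pred = predict_onset(constant_series(2019, 7.0), 46.0, params, 2019,
                             keep_trace=True)
        assert (np.diff(pred.cumulative_forcing_trace) >= 0).all()

    def test_unusable_year_raises_skip_signal(self):
        s = constant_series(2019, 7.0)
        s.data.iloc[:40] = np.nan
        params = SpeciesModelParams("dandelion", t_base=2.0, f_star=1000.0)
        with pytest.raises(UnusableStationYear):
            predict_onset(s, 46.0, params, 2019)

    def test_warming_never_delays_onset(self, small_climate, small_network):
        params = SpeciesModelParams("dandelion", t_base=2.0, f_star=4200.0,
                                    k_photo=1.0)
        st0 = small_network[0]
        series = small_climate[st0.station_id]
        base = predict_onsets_multi(series, st0.latitude, params,
                                    years=list(range(1995, 2005)))
        warmed_df = series.data + 2.0
        warmed = DailyTemperatureSeries(st0.station_id, warmed_df)
        warm = predict_onsets_multi(warmed, st0.latitude, params,
                                    years=list(range(1995, 2005)))
        for y in base:
            if base[y] is not None and warm[y] is not None:
                assert warm[y] <= base[y]

    def test_larger_threshold_never_advances(self, small_climate, small_network):
        st0 = small_network[0]
        series = small_climate[st0.station_id]
        lo = SpeciesModelParams("dandelion", t_base=2.0, f_star=3000.0, k_photo=1.0)
        hi = SpeciesModelParams("dandelion", t_base=2.0, f_star=5000.0, k_photo=1.0)
        a = predict_onsets_multi(series, st0.latitude, lo, years=[2000, 2001, 2002])
        b = predict_onsets_multi(series, st0.latitude, hi, years=[2000, 2001, 2002])
        for y in a:
            if a[y] is not None and b[y] is not None:
                assert b[y] >= a[y]

    def test_zero_photoperiod_equals_thermal_time_model(self, small_climate,
                                                        small_network, rng):
        """k_photo = 0 must reduce to a pure degree-hour model, checked
        against an independent implementation on random station-years."""
        params = SpeciesModelParams("dandelion", t_base=3.0, f_star=2500.0,
                                    k_photo=0.0)
        for _ in range(20):
            st0 = small_network[rng.integers(len(small_network))]
            series = small_climate[st0.station_id]
            year = int(rng.integers(1975, 2019))
            try:
                got = predict_onset(series, st0.latitude, params, year).predicted_doy
            except UnusableStationYear:
                continue
            from phenospring.climate_io import year_frame
            yf = year_frame(series, year)
            acc, expected = 0.0, None
            for i, (tn, tx) in enumerate(zip(yf["tmin"], yf["tmax"]), start=1):
                acc += gdh_oracle(tn, tx, 3.0)
                if acc >= 2500.0:
                    expected = i
                    break
            assert got == expected

    def test_higher_elevation_never_flowers_earlier(self):
        """Lapse-cooled copies of one series must onset no earlier than
        the lowland original (median over years, all three species)."""
        from phenospring import default_true_params
        cfg_dates = pd.date_range("1996-01-01", "2005-12-31")
        n = len(cfg_dates)
        rng = np.random.default_rng(5)
        doy = cfg_dates.dayofyear.to_numpy(float)
        mean = 12 - 10 * np.cos(2 * np.pi * (doy - 15) / 365.25) \
            + np.convolve(rng.normal(0, 3, n), np.ones(5) / 5, mode="same")
        base = DailyTemperatureSeries(
            "L", pd.DataFrame({"tmin": mean - 4, "tmax": mean + 4},
                              index=cfg_dates))
        for params in default_true_params().values():
            medians = []
            for elev in (0.0, 300.0, 600.0, 900.0):
                s = adjust_to_station_elevation(base, 0.0, elev)
                onsets = [v for v in predict_onsets_multi(s, 46.0, params).values()
                          if v is not None]
                medians.append(np.median(onsets))
            assert all(b >= a for a, b in zip(medians, medians[1:]))


class TestCalibration:
    def test_zero_noise_recovers_generating_parameters(self, noiseless_config,
                                                       noiseless_data):
        stations, climate, observations = noiseless_data
        for species, true in noiseless_config.true_params.items():
            obs = [o for o in observations if o.species == species]
            fit = calibrate_species(obs, climate, stations)
            assert fit.params.t_base == true.t_base
            assert fit.params.k_photo == true.k_photo
            assert fit.rmse_days == 0.0

    def test_single_observation_fits_exactly(self, noiseless_data):
        stations, climate, observations = noiseless_data
        obs = [o for o in observations if o.species == "dandelion"][:1]
        fit = calibrate_species(obs, climate, stations)
        assert fit.rmse_days == 0.0 and fit.n == 1

    def test_noisy_recovery_bounded_by_twice_noise_sd(self):
        from phenospring import (SyntheticConfig, generate_network,
                                 generate_observations, generate_observed_climate)
        cfg = SyntheticConfig(n_stations=5, years_observed=(1991, 2012),
                              obs_noise_sd_days=3.0, missing_rate=0.0, seed=21)
        stations = generate_network(cfg)
        climate = generate_observed_climate(cfg, stations)
        observations = [o for o in generate_observations(cfg, stations, climate)
                        if o.species == "dandelion"]
        assert len(observations) >= 100
        fit = calibrate_species(observations, climate, stations)
        assert fit.rmse_days <= 2 * 3.0

    def test_mixed_species_rejected(self, noiseless_data):
        stations, climate, observations = noiseless_data
        with pytest.raises(DataError, match="one species"):
            calibrate_species(observations, climate, stations)

    def test_no_usable_pairs_rejected(self, noiseless_data):
        stations, climate, _ = noiseless_data
        with pytest.raises(DataError):
            calibrate_species([], climate, stations)


class TestCrossValidation:
    def test_zero_noise_heldout_rmse_near_zero(self, noiseless_data):
        stations, climate, observations = noiseless_data
        obs = [o for o in observations if o.species == "hazel_catkins"]
        reports = cross_validate(obs, climate, stations, n_folds=4)
        assert reports and all(r.rmse_days <= 1.0 for r in reports)

    def test_single_fold_rejected(self, noiseless_data):
        stations, climate, observations = noiseless_data
        obs = [o for o in observations if o.species == "dandelion"]
        with pytest.raises(DataError):
            cross_validate(obs, climate, stations, n_folds=1)

    def test_more_folds_than_years_rejected(self, noiseless_data):
        stations, climate, observations = noiseless_data
        obs = [o for o in observations if o.species == "dandelion"]
        with pytest.raises(DataError):
            cross_validate(obs, climate, stations, n_folds=999)

    def test_shuffled_labels_have_no_skill(self, noiseless_data, rng):
        stations, climate, observations = noiseless_data
        obs = [o for o in observations if o.species == "dandelion"]
        doys = np.array([o.onset_doy for o in obs])
        rng.shuffle(doys)
        shuffled = [PhenoObservation(o.station_id, o.species, o.year, int(d))
                    for o, d in zip(obs, doys)]
        reports = cross_validate(shuffled, climate, stations, n_folds=3)
        rhos = [r.spearman_rho for r in reports if r.spearman_rho is not None]
        assert rhos and abs(np.mean(rhos)) < 0.35


class TestParamsSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        p = SpeciesModelParams("lilac", t_base=4.0, f_star=5600.0, k_photo=1.0)
        path = tmp_path / "params.yaml"
        p.save(path, provenance={"n": 10})
        assert SpeciesModelParams.load(path) == p

    @pytest.mark.parametrize("kw", [dict(f_star=-1.0), dict(k_photo=-0.5),
                                    dict(start_doy=0)])
    def test_invalid_params_rejected(self, kw):
        base = dict(species="lilac", t_base=4.0, f_star=100.0, k_photo=1.0)
        base.update(kw)
        with pytest.raises(DataError):
            SpeciesModelParams(**base)
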