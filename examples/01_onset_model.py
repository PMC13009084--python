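"""Predict one station-year's spring onset with the degree-hour model.

Builds a single synthetic station, runs the photoperiod-weighted growing
degree-hour model for dandelion and prints the forcing ingredients and
the predicted flowering day.
"""

from phenospring import (
    SyntheticConfig,
    daily_gdh,
    daylength,
    default_true_params,
    generate_network,
    generate_observed_climate,
    predict_onset,
)

cfg = SyntheticConfig(n_stations=2, years_observed=(2000, 2000), seed=1,
                      missing_rate=0.0)
station = generate_network(cfg)[0]
series = generate_observed_climate(cfg, [station])[station.station_id]
params = default_true_params()["dandelion"]

print(f"station {station.station_id}: {station.elevation:.0f} m a.s.l., "
      f"lat {station.latitude:.2f} N")
print(f"daylength on Apr 1 (DOY 91): {daylength(station.latitude, 91):.2f} h")
d = 90  # April 1
print(f"Apr 1 tmin/tmax: {series.tmin[d]:.1f}/{series.tmax[d]:.1f} degC -> "
      f"GDH above {params.t_base:.0f} degC: "
      f"{daily_gdh(series.tmin[d], series.tmax[d], params.t_base):.0f} degC*h")

pred = predict_onset(series, station.latitude, params, 2000)
print(f"dandelion onset 2000: DOY {pred.predicted_doy} "
      f"(forcing threshold {params.f_star:.0f} degC*h, "
      f"photoperiod exponent {params.k_photo})")
# The predicted DOY is the first day the accumulated daylength-weighted
# degree hours reach the species threshold.
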