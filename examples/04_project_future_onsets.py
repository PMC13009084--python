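"""Project spring onsets to 2100 under two warming scenarios.

Generates a small biased warming ensemble (6 members per scenario),
bias-corrects every member against the observed climate, runs the onset
model for all three species over 1981-2100 and prints the period
deviations from the 1981-2010 reference.
"""

from phenospring import (
    SyntheticConfig,
    apply_qm,
    fit_qm,
    generate_network,
    generate_observed_climate,
    generate_projection_ensemble,
)
from phenospring.trends import period_deviations_table, project_onsets

cfg = SyntheticConfig(n_stations=4, seed=9)
stations = generate_network(cfg)
climate = generate_observed_climate(cfg, stations)
ensemble = generate_projection_ensemble(cfg, stations)

corrected = {}
for scenario, members in ensemble.items():
    corrected[scenario] = {}
    for member, by_station in members.items():
        corrected[scenario][member] = {
            sid: apply_qm(fit_qm(series, climate[sid]), series)
            for sid, series in by_station.items()
        }

proj = project_onsets(corrected, cfg.true_params, stations)
table = period_deviations_table(proj)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:7.2f}"))
# mean_dev is the signed shift in days of the period-mean onset relative
# to 1981-2010 (negative = earlier flowering); rate_per_decade converts
# it through the period-midpoint separation. Advances grow through the
# century and are larger under the high-forcing scenario.
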