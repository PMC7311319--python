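# A rare phage-resistant strain (5% of founders) invading a susceptible
# biofilm after a single 120-virion pulse, at desk scale.

[space]
x_max_um = 300.0
y_max_um = 90.0
dl_um = 3.0

[nutrient]
N_max_mg_per_l = 8.0

[pulse]
mode = "point"
count = 120
height_threshold_um = 20.0

[sim]
dt_min = 7.5
seed = 1
initial_resistant_fraction = 0.05
endpoint_days_after_infection = 10.0

[strains.susceptible]
resistance_mode = "susceptible"
cost_c = 0.0
interaction_rate_I = 0.09

[strains.resistant]
resistance_mode = "surface"
cost_c = 0.05
interaction_rate_I = 0.09
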