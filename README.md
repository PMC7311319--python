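# phagefilm

Individual-based simulation of lytic bacteriophage attack on bacterial
biofilms containing phage-susceptible and phage-resistant strains.

Biofilms protect bacteria from phages in ways well-mixed cultures do not:
the matrix and the cells themselves impede virion diffusion, so whether a
phage ever reaches a susceptible host depends on who its neighbors are.
`phagefilm` is built for researchers in microbial ecology and evolution who
want to study that interplay quantitatively — in particular the question of
*invasibility*: does a resistant strain increase in frequency when rare, and
decrease when common?  A yes to both is negative frequency-dependent
selection and predicts stable coexistence of resistant and susceptible cells
rather than fixation of either.

## The model

Discrete bacteria grow on a lattice of 3-µm nodes (lateral boundaries
periodic, solid substratum below, open top).  A growth substrate diffuses
from a bulk layer above the biofilm front and is consumed with Monod
kinetics, solved to quasi-steady state each iteration:

    D_N ∇²N = q_max B(x) N/(K_N + N),   µ = (1−c) µ_s N/(K_N + N)

where `c` is the fitness cost of resistance.  Cells divide at twice the
single-cell mass, are redistributed by shoving when a node exceeds the
maximum biomass density S_max·dV, erode from the front with hazard
∝ δ_E·y², and detach when disconnected from the substratum.

Each virion performs an impeded random walk: n = D_P·Δt/(2·dl²) lattice
steps per iteration, staying in place with probability erf(1/√(2aπ)) per
step (a = 1 in 2D, 4 in 3D), removed by fluid advection off the biofilm
with hazard dtp·d²·δ_P, and sorbing to biomass with hazard dtp·(I_s+I_t)
built from the per-cell sorption rates I_x = Σ mᵢIᵢ.  A sorbed virion
attempts infection of a co-resident cell (host drawn ∝ mᵢIᵢ, firing with
hazard γ·dtr); infected cells lyse after the latent period τ, releasing β
virions.  Resistant strains can block adsorption (surface modification),
destroy phage and self (abortive infection), or sequester virions
(phage-neutralizing).  All parameters default to measured values for
*E. coli* and phage T7 (µ_s = 14.1 day⁻¹, τ = 28.8 min, β = 120,
D_P = 3.82×10⁻⁷ cm² s⁻¹, …); `docs/methods.md` has the full table and every
modeling decision.

## Worked example

A rare resistant strain (5% of founders, 5% growth-rate cost) invading a
susceptible biofilm after a single 120-virion pulse at 20 µm front height
([examples/rare_resistant_invasion.toml](examples/rare_resistant_invasion.toml)):

```
$ phagefilm run -c examples/rare_resistant_invasion.toml -o out
{
  "seed": 1,
  "exit_status": "fixation_resistant",
  "f_inoculated": 0.05,
  "f_before": 0.03487179487179487,
  "f_after": 1.0,
  "peak_phage": 27745,
  "infection_time_h": 19.375,
  "end_time_h": 28.25
}
```

The biofilm reached the pulse height after 19.4 h, at which point drift had
taken the resistant frequency to 0.035 (`f_before`).  The pulse amplified
through the susceptible majority to a peak of 27,745 virions, the epidemic
destroyed every susceptible lineage, and the run ended 8.9 h later with the
resistant strain fixed (`f_after = 1.0`): strong positive selection on
resistance when rare.  Running the same configuration with
`sim.initial_resistant_fraction = 0.90` instead typically ends at the 10-day
endpoint with the resistant frequency *below* its pulse-time value — the few
susceptible cells are shielded by resistant neighbors that trap virions, and
their growth-rate advantage then erodes the resistant majority.  Together
the two regimes are the frequency-dependence that drives coexistence.

`out/timeseries.csv` holds the per-iteration populations, front height, and
event counts; the same API is available in Python:

```python
import phagefilm as pf
result = pf.run_replicate(pf.desk_config(), seed=1)
print(result.exit_status, result.f_before, result.f_after)
```

Parameter sweeps over nutrient level, initial frequency, cost, sorption and
removal rates (`phagefilm sweep -c config.toml`) write a per-replicate table
and a heatmap of the mean resistant-frequency change Δf = f_after − f_before
over retained replicates (replicates whose pulse never amplified past 150
virions are trimmed), classified POSITIVE / NEGATIVE / NEUTRAL for
invasibility analysis.  `phagefilm validate` prints the analytic self-checks
(stay probabilities, hazard forms, the growth identity µ_s = q_max·Y).

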