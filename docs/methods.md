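# Model and methods

`phagefilm` is an individual-based simulation of a two-strain bacterial
biofilm under attack by a lytic bacteriophage.  It tracks every bacterium and
every virion on a lattice of 3-µm cubic nodes and reproduces, at desktop
scale, the central population-dynamic result of such systems: negative
frequency-dependent selection on phage resistance, and hence stable
coexistence of resistant and susceptible cells.

## Space and boundary conditions

The domain is a 2D box (3D is supported by the same code paths) of
`dl`-sided nodes: axis x is lateral and periodic, axis y is vertical with a
solid substratum below row 0 and an open top.  Agents live in nodes; physical
positions are node centers at (i+½)·dl.  Phage walkers may overshoot the top
into a small virtual pad of empty rows; anything still off the biofilm at the
end of an iteration is removed by advection anyway.

## Nutrient field

A single growth-limiting substrate diffuses from a well-mixed bulk layer
sitting a boundary-layer height `h` above the biofilm front and is consumed
by live biomass with Monod kinetics:

    D_N ∇²N = q_max · B(x) · N/(K_N + N)

with Dirichlet N = N_max on every row at or above (front height + h) — a flat
boundary at the global front maximum — no-flux at the substratum, and lateral
periodicity.  Because substrate diffusion equilibrates over 150 µm in seconds
while one iteration is 7.5 min, the field is solved to quasi-steady state
each iteration (relative tolerance 1e-6) rather than co-integrated in time.
The nonlinear sink is handled by semi-implicit Picard iteration; the sparse
LU factorization is reused across Picard steps and across iterations (the
Monod coefficient change is folded into the right-hand side), refactorizing
only when convergence stalls.  B(x) counts only actively growing cells,
weighted by (1−c), so the field's sink is exactly the substrate that the
growth step books as consumed (consumption = Δbiomass / Y).

When the biofilm front grows so high that no bulk row fits inside the box,
the Dirichlet condition degenerates to a ghost row above the open top.

## Bacteria

Each cell has a strain, a mass, a node, and an infection state.

* **Growth**: Δm = (1−c)·µ_s·N/(K_N+N)·m·Δt, explicit Euler.  Infected and
  growth-halted cells neither grow nor consume (the infected class exists
  only to lyse after the latent period).
* **Division**: at mass ≥ 2·m_s a cell splits into two equal halves in the
  same node; the threshold-and-symmetric-split rule is the simplest one that
  conserves m_s as the nominal single-cell mass.
* **Shoving**: no node may exceed S_max·dV = 5.4 pg of biomass.  Over-capacity
  nodes repeatedly push one randomly chosen whole cell to their least-full
  lattice neighbor (ties uniform at random; never into the substratum; a
  top-row node may push a cell out of the open top, where it is lost to the
  flow).  Whole-cell moves can defeat the local rule — two adjacent nodes
  jointly above twice the capacity trade a cell forever, and a lattice
  saturated to the top thrashes — so a stalled relaxation escalates to
  gradient descent on a distance-to-spare-capacity field (spare means room
  for any single cell, 2·m_s), the path-shoving of classic lattice biofilm
  models.  Counts and mass are conserved exactly except for ledgered losses
  through the open top.
* **Erosion**: the front speed δ_E·y² (units (m·h)⁻¹·m² = m/h) is converted
  to a per-cell removal hazard min(1, δ_E·y²·Δt/dl) applied to cells in front
  nodes (biomass nodes with at least one empty von Neumann neighbor; the
  space above the top row counts as liquid, the substratum as solid).
* **Detachment**: connected components of biomass nodes (von Neumann
  adjacency, periodic laterally) that do not touch the substratum row are
  removed entirely.

## Phages

Phage transport is an impeded lattice random walk.  Per iteration each free
virion takes up to n = D_P·Δt/(2·dl²) steps of duration dtp = 2·dl²/D_P
(n = 955, dtp = 0.47 s at the default parameters).  Each step:

1. off the biofilm (distance d > 0 to the nearest biomass, Euclidean
   node-center distance, periodic in x) the virion is removed by advection
   with probability 1 − exp(−dtp·d²·δ_P);
2. it stays in its node with probability erf(1/√(2aπ)) (0.427 in 2D, 0.222 in
   3D — the Gaussian step kernel integrated over a node-sized disc),
   otherwise picks one of the 2·dim axis directions uniformly (substratum and
   pad-top moves spend the step in place);
3. it sorbs to biomass with probability 1 − exp(−dtp·(I_s+I_t)), where the
   node sorption rate is I_x = Σᵢ mᵢ·Iᵢ with mᵢ in units of m_s — one
   single-cell-mass bacterium at I = 0.09 contributes 0.09 s⁻¹, so a full
   node (≈ 5.4 pg) yields ≈ 0.5 s⁻¹ and entry into dense biomass leads to
   sorption within a few steps;
4. a sorbed virion ceases motion for the iteration, recording the s steps
   taken.

All hazards use the survival form 1 − exp(−x).  The walk is vectorized
across the whole population.

A stopped virion attempts infection of one co-resident cell drawn with
probability ∝ mᵢIᵢ, firing with probability 1 − exp(−γ·dtr), where the
contact time is dtr = Δt·s/n by default (the walk time spent before
sorption; the complementary Δt·(n−s)/n is available as
`phage.dtr_mode = "remaining"`).  Outcomes by host resistance mode:
susceptible → infected (phage consumed; a second hit on an already-infected
host consumes the phage without resetting its clock); abortive → host and
phage both destroyed; surface-modification → both intact (optionally halting
host growth, the `halt_on_contact` flag); phage-neutralizing → phage
consumed, host unharmed.  An infected cell lyses τ = 28.8 min after
infection, releasing β = 120 virions into its node.  At the end of every
iteration all virions in nodes without live biomass are swept out by
advection.

**Sorbed-phage behavior.**  By default (`phage.sorbed_behavior = "stay"`) a
virion that sorbed without firing stays attached — it skips subsequent walks
and retries infection each iteration with the full Δt as contact time — until
it fires, is consumed, or its node loses its biomass.  This is what produces
the virion *trapping* on resistant cell surfaces that shields rare
susceptible cells.  The alternative (`"resume"`, one extra config switch)
releases sorbed virions each iteration; in that regime phages explore the
whole desk-scale lattice within the post-pulse window and no shielding
survives, which is measurably incompatible with the frequency-dependence
benchmark the model targets.

## Iteration cycle and events

Each iteration executes exactly: nutrient diffusion → growth and division →
lysis/burst → erosion → phage movement → biomass detachment → phage
infection → shoving → phage detachment, then advances time by Δt = 7.5 min.
The pulse event runs before stage 1: when the global front height first
reaches the threshold, either 120 virions are placed at the highest node
containing susceptible biomass (`point`, the default; if no susceptible
biomass exists anywhere the highest biomass node is used and the fallback is
logged) or 300 virions are sprayed at uniformly random columns 9 µm (3 rows)
above each column's front (`spray`).  `pulse.duration_iterations = -1`
repeats the pulse every iteration, the continuous-exposure regime.  A run
ends at fixation of either strain (infected cells count as live susceptible),
at `infection time + endpoint` (10 days by default), or at the optional
`sim.max_duration_days` cap — the cap exists because phage-free control runs
otherwise have no timeout.

An event ledger (births, erosion, detachment, overflow, lysis, abortive
kills; pulses, bursts, consumptions, advection, sweeps) is audited against
the population counts after every iteration; any imbalance raises.

## Parameters

All defaults are the measured values for E. coli and phage T7 used by this
class of models:

| symbol | default | units | meaning |
|---|---|---|---|
| x_max × y_max | 900 × 150 | µm | domain (desk scale: 300 × 90) |
| dl | 3 | µm | node edge |
| N_max | 8 | mg/L | bulk substrate (study range 1.1–8) |
| D_N | 2.3e-6 | cm²/s | substrate diffusivity |
| h | 15 | µm | boundary-layer height |
| K_N | 1.18 | mg/L | half-saturation |
| q_max | 28.5 | g/(g·day) | max specific uptake |
| Y | 0.495 | – | yield; µ_s = q_max·Y = 14.1/day |
| S_max | 200 | g/L | max biomass density |
| δ_E | 20 | (m·h)⁻¹ | erosion constant |
| m_s | 1e-12 | g | single-cell mass |
| D_P | 3.82e-7 | cm²/s | phage diffusivity |
| I | 0.09 | (m_s·µm³)⁻¹s⁻¹ | sorption rate (measured range 0.067–0.12) |
| δ_P | 5 | (µm²·h)⁻¹ | advective removal rate (printed range 0.001–10) |
| γ | 2.92 | h⁻¹ | infection rate |
| τ | 28.8 | min | latent period |
| β | 120 | – | burst size |
| c | 0.05 | – | resistance cost (resistant strain) |
| Δt | 7.5 | min | iteration duration |

µ_s = q_max·Y is enforced at configuration load to the printed precision of
the parameter table (28.5 × 0.495 = 14.1075 ≈ 14.1, relative tolerance 1e-3).

Two defaults deserve comment because the sources state only ranges.  The
sorption rate I uses the midpoint 0.09 of the measured 0.067–0.12 interval,
combined with the literal node-rate formula I_x = Σ mᵢIᵢ; this places the
model in the regime where dense biomass impedes virions essentially on
contact, which is the described behavior of the upper end of the measured
range and the regime in which resistant cell groups actually block phage
transport.  The removal rate δ_P uses 5, the arithmetic midpoint of the
four-decade 0.001–10 range; at this value a virion in the liquid is removed
within roughly one node of lateral travel, so burst progeny stay local and
phage spread between distant susceptible clusters is rare — the containment
that underlies protection of minorities.  Much weaker removal (e.g. 0.1)
lets every burst seed the entire 300-µm desk lattice within one iteration
and no shielding survives.

## Desk-scale study conditions

`desk_config()` keeps every biological parameter and the 10-day
post-infection endpoint but shrinks the lattice to 300 × 90 µm and triggers
the pulse at 20 µm front height.  One founder cell per substratum node is
inoculated, independently resistant with probability f₀.  Phage-free
controls run with a zero-count pulse and a 3-day total cap.  Replicate
trimming follows the 150-virion rule: a 120-virion pulse that produced zero
infections never exceeds 150 phages and the replicate is excluded from
heatmap means.

At this scale a biofilm reaches the pulse height in roughly half a day at
N_max = 8 mg/L; a full 10-day replicate takes tens of seconds on one CPU.
The full-scale 900 × 150 µm domain and the 21 × 21 × 100-replicate sweep
grids are configuration-reachable but sized for a cluster.

## What the scaled-down conditions do and do not show

The desk lattice holds ~100 founder lineages instead of ~300, so drift is
stronger and sector geometry coarser than at full scale; with ~10 susceptible
founders at f₀ = 0.9, some replicates lose every susceptible lineage to the
initial epidemic by chance, which is why the frequency-dependence benchmark
is stated over a majority of replicates rather than per run.  The finite
90-µm height is reached within the 10-day window; growth then continues with
biomass leaving through the open top (ledgered), an artifact of the short box
that preserves front-level competition but compresses late-time dynamics.
Passing tests therefore demonstrate the qualitative selection pattern and
exact bookkeeping, not the quantitative heatmap values of a full-scale sweep.

## Numerical choices

* Nutrient solver: relative tolerance 1e-6, iteration cap 1e4, M-matrix
  linearization guarantees 0 ≤ N ≤ N_max; field clipped only against
  rounding.
* Walk step count n is rounded to the nearest integer; the n·dtp ≈ Δt
  identity holds to one step.
* The sorbing step counts as taken (s includes it), so a phage stopped on its
  first step still has dtr = Δt/n > 0.
* Stage 7 processes stopped phages in index order; nodes containing
  abortive-mode cells use a strictly sequential path (a host death changes
  the draw weights); all other nodes are resolved in one vectorized draw,
  which is distributionally identical because nothing a non-abortive outcome
  does changes the weights.
* Erosion heights use node centers, (j+½)·dl; front heights use (1+top
  occupied index)·dl.
* Determinism: one `numpy` PCG64 generator per run, seeded from the
  replicate seed; identical configuration and seed give bit-identical output.
  Sweep seeds derive from `SeedSequence(base, spawn_key=(cell, replicate))`,
  injective across the grid.

## Known limitations

* No ongoing mutation between strains, no lysogeny or phage host-range
  evolution, no starvation/dormancy refuges — matching the scope of the
  modeled system.
* A single substrate; no pH, oxygen, or waste fields.
* Flow is implicit (erosion, phage advection); there is no hydrodynamic
  solver.
* 3D lattices are supported by the geometry, walk, and solver code paths,
  but the shipped study conditions are 2D.
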