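"""The simulation engine: nine-stage iteration cycle, events, exit conditions.

Each iteration advances the system by ``dt`` through a fixed stage order:

    1. diffusion of the nutrient substrate      (quasi-steady field solve)
    2. biomass growth and division
    3. lysis of infected bacteria, phage burst
    4. erosion of biomass
    5. phage movement                           (the impeded random walk)
    6. detachment of biomass
    7. phage infection
    8. biofilm relaxation ("shoving")
    9. detachment of bacteriophage              (advective sweep of free phages)

One-time events -- inoculation and the phage pulse -- sit outside the cycle;
the pulse fires when the biofilm front first reaches a threshold height.  The
engine keeps an exact event ledger (births, removals, infections, bursts) and
audits population counts against it after every iteration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bacteria as bact
from . import nutrients as nutr
from . import phage as phg
from .bacteria import BacterialPopulation, StrainTable
from .params import Config
from .phage import TOP_PAD, PhagePopulation
from .space import Grid, build_grid, distance_field, front_height

__all__ = ["ExitStatus", "RunResult", "Simulation", "LedgerError", "run_replicate",
           "STAGE_ORDER"]

STAGE_ORDER = (
    "nutrient_diffusion",
    "growth_division",
    "lysis_burst",
    "erosion",
    "phage_movement",
    "biomass_detachment",
    "phage_infection",
    "shoving",
    "phage_detachment",
)


class ExitStatus(enum.Enum):
    CONTINUE = "continue"
    FIXATION_SUSCEPTIBLE = "fixation_susceptible"
    FIXATION_RESISTANT = "fixation_resistant"
    TIMEOUT = "timeout"


class LedgerError(RuntimeError):
    """Population counts diverged from the event ledger."""


@dataclass
class RunResult:
    """Summary of one replicate run."""

    seed: int
    exit_status: ExitStatus
    f_inoculated: float
    f_before: float  # resistant frequency when the pulse fires (nan if never)
    f_after: float   # resistant frequency at exit
    peak_phage: int
    infection_time_h: float  # nan if the pulse never fired
    end_time_h: float
    history: pd.DataFrame
    snapshots: list = field(default_factory=list)


class Simulation:
    """One replicate of the phage-biofilm system."""

    def __init__(self, config: Config, seed: int | None = None):
        self.config = config
        self.seed = int(config.sim.seed if seed is None else seed)
        self.rng = np.random.default_rng(self.seed)
        self.grid: Grid = build_grid(config.space)
        self.strain_table = StrainTable(config.strains, config.bacteria)
        self.bacteria = BacterialPopulation(
            self.strain_table, self.grid.dimension, config.bacteria.m_s_g
        )
        self.phages = PhagePopulation(self.grid.dimension)
        self.time_h = 0.0
        self.iteration = 0
        self.infection_time_h = float("nan")
        self.f_before = float("nan")
        self.peak_phage = 0
        self._pulses_remaining = 0
        self._pulse_triggered = False
        self._nutrient_field: np.ndarray | None = None
        self._nutrient_cache: dict = {}
        self._shove_escalated = False
        self._history: list[dict] = []
        self.snapshots: list[pd.DataFrame] = []
        self.event_log: list[dict] = []

        # derived walk constants
        sp, ph = config.space, config.phage
        self.n_steps = phg.steps_per_iteration(ph.D_P_um2_per_s, config.sim.dt_s, sp.dl_um)
        self.dtp_s = (phg.step_time(ph.D_P_um2_per_s, sp.dl_um)
                      if ph.D_P_um2_per_s > 0 else 0.0)
        self.capacity_g = config.bacteria.capacity_g(sp.dV_l)

    # -- events -------------------------------------------------------------

    def inoculate(self, resistant_fraction: float | None = None,
                  founders_per_node: int | None = None) -> None:
        """Seed founder cells of mass m_s on every substratum node.

        Each founder is independently resistant with probability
        ``resistant_fraction``.  Requires exactly one susceptible and one
        resistant strain code to draw between.
        """
        f = (self.config.sim.initial_resistant_fraction
             if resistant_fraction is None else resistant_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError("resistant_fraction must lie in [0, 1]")
        per_node = (self.config.bacteria.founders_per_node
                    if founders_per_node is None else founders_per_node)
        st = self.strain_table
        sus_codes = np.flatnonzero(st.susceptible)
        res_codes = np.flatnonzero(~st.susceptible)
        if sus_codes.size != 1 or res_codes.size != 1:
            raise ValueError(
                "inoculation draws between exactly one susceptible and one "
                "resistant strain"
            )
        lateral_shape = tuple(
            n for ax, n in enumerate(self.grid.shape) if ax != 1
        )
        cols = np.indices(lateral_shape).reshape(len(lateral_shape), -1).T
        cols = np.repeat(cols, per_node, axis=0)
        pos = np.insert(cols, 1, 0, axis=1)
        resistant = self.rng.random(pos.shape[0]) < f
        strain = np.where(resistant, res_codes[0], sus_codes[0]).astype(np.int8)
        self.bacteria.add(pos, strain)

    def maybe_trigger_pulse(self) -> int:
        """Fire the phage pulse when the front first reaches the threshold.

        Returns the number of phages added this iteration.  Repeats for
        ``pulse.duration_iterations`` consecutive iterations (-1 = forever).
        """
        pulse = self.config.pulse
        if not self._pulse_triggered:
            _, front_max = front_height(
                self.bacteria.node_mass(self.grid.shape), self.grid.dl
            )
            if front_max >= pulse.height_threshold_um - 1e-9:
                self._pulse_triggered = True
                self.infection_time_h = self.time_h
                self.f_before = self.resistant_frequency()
                self._pulses_remaining = (
                    -1 if pulse.duration_iterations == -1 else pulse.duration_iterations
                )
        if not self._pulse_triggered or self._pulses_remaining == 0:
            return 0
        if self._pulses_remaining > 0:
            self._pulses_remaining -= 1
        added = self._add_pulse(pulse.mode, pulse.count)
        self.peak_phage = max(self.peak_phage, len(self.phages))
        return added

    def _add_pulse(self, mode: str, count: int) -> int:
        if count == 0:
            return 0
        shape = self.grid.shape
        node_mass = self.bacteria.node_mass(shape)
        if mode == "point":
            sus = self.strain_table.susceptible[self.bacteria.strain]
            target_mass = self.bacteria.node_mass(shape, weights=sus.astype(float))
            if not (target_mass > 0).any():
                target_mass = node_mass  # fallback: highest biomass node
                self.event_log.append(
                    {"iteration": self.iteration, "event": "pulse_fallback_no_susceptible"}
                )
            occ = target_mass > 0
            ny = shape[1]
            rows = np.arange(ny).reshape((1, ny) + (1,) * (occ.ndim - 2))
            col_top = np.max(np.where(occ, rows, -1), axis=1)
            best_col = np.unravel_index(np.argmax(col_top), col_top.shape)
            node = (best_col[0], int(col_top[best_col])) + tuple(best_col[1:])
            self.phages.add(np.tile(node, (count, 1)))
            return count
        # spray: each phage at a uniformly random column, 9 um (3 rows) above
        # that column's front
        heights, _ = front_height(node_mass, self.grid.dl)
        front_rows = (heights / self.grid.dl).astype(np.int64)
        lateral_shape = front_rows.shape
        flat = self.rng.integers(0, front_rows.size, size=count)
        cols = np.array(np.unravel_index(flat, lateral_shape)).T
        rows = front_rows.ravel()[flat] + 2
        rows = np.minimum(rows, shape[1] + TOP_PAD - 1)
        pos = np.insert(cols, 1, rows, axis=1)
        self.phages.add(pos)
        return count

    # -- frequency bookkeeping ----------------------------------------------

    def live_counts(self) -> dict:
        return self.bacteria.counts()

    def resistant_frequency(self) -> float:
        c = self.live_counts()
        total = c["n_susceptible"] + c["n_resistant"] + c["n_infected"]
        return c["n_resistant"] / total if total else float("nan")

    # -- the nine-stage cycle ------------------------------------------------

    def _stage_nutrient_diffusion(self, ev: dict) -> None:
        self._nutrient_field = nutr.solve_nutrient_field(
            self.grid,
            self.bacteria.active_sink_mass(self.grid.shape),
            self.config.nutrient,
            warm_start=self._nutrient_field,
            cache=self._nutrient_cache,
        )

    def _stage_growth_division(self, ev: dict) -> None:
        grown, consumed = bact.grow_cells(
            self.bacteria, self._nutrient_field,
            self.config.nutrient.K_N_mg_per_l, self.config.nutrient.Y,
            self.config.sim.dt_h,
        )
        ev["grown_mass"] = grown
        ev["consumed_substrate"] = consumed
        ev["births"] = bact.divide_cells(self.bacteria, self.rng)

    def _stage_lysis_burst(self, ev: dict) -> None:
        n, m = phg.lyse_cells(
            self.bacteria, self.phages, self.time_h,
            self.config.phage.tau_h, self.config.phage.beta,
        )
        ev["lysed"] = n
        ev["lysed_mass"] = m
        ev["burst_added"] = n * self.config.phage.beta
        # the post-burst population is the within-iteration peak
        self.peak_phage = max(self.peak_phage, len(self.phages))

    def _stage_erosion(self, ev: dict) -> None:
        n, m = bact.erode(
            self.bacteria, self.grid, self.config.bacteria.delta_E_per_m_h,
            self.config.sim.dt_h, self.rng,
        )
        ev["eroded"] = n
        ev["eroded_mass"] = m

    def _stage_phage_movement(self, ev: dict) -> None:
        self.phages.reset_iteration(
            self.config.phage.sorbed_behavior, self.n_steps
        )
        node_mass = self.bacteria.node_mass(self.grid.shape)
        ix = phg.interaction_rate_field(self.bacteria, self.grid.shape)
        pad = [(0, 0)] * ix.ndim
        pad[1] = (0, TOP_PAD)
        ix_ext = np.pad(ix, pad)
        dist_ext = distance_field(
            node_mass, self.grid.dl, self.grid.lateral_axes, pad_top=TOP_PAD
        )
        ev["advected"] = phg.random_walk(
            self.phages, self.grid, ix_ext, dist_ext,
            self.n_steps, self.dtp_s,
            self.config.phage.delta_P_per_um2_h, self.rng,
        )

    def _stage_biomass_detachment(self, ev: dict) -> None:
        n, m = bact.detach_disconnected(self.bacteria, self.grid)
        ev["detached"] = n
        ev["detached_mass"] = m

    def _stage_phage_infection(self, ev: dict) -> None:
        counts = phg.infection_stage(
            self.phages, self.bacteria, self.grid, self.config.phage,
            self.config.sim.dt_h, self.n_steps, self.time_h, self.rng,
        )
        ev.update(counts)

    def _stage_shoving(self, ev: dict) -> None:
        moves, n_over, m_over, self._shove_escalated = bact.shove_relax(
            self.bacteria, self.grid, self.capacity_g, self.rng,
            start_escalated=self._shove_escalated,
        )
        ev["shove_moves"] = moves
        ev["overflow"] = n_over
        ev["overflow_mass"] = m_over

    def _stage_phage_detachment(self, ev: dict) -> None:
        node_mass = self.bacteria.node_mass(self.grid.shape)
        pad = [(0, 0)] * node_mass.ndim
        pad[1] = (0, TOP_PAD)
        occupied_ext = np.pad(node_mass > 0, pad, constant_values=False)
        ev["swept"] = phg.sweep_free_phages(self.phages, occupied_ext)

    def iterate(self) -> dict:
        """One full iteration: pulse event, the nine stages in order, audit."""
        n_bact_before = len(self.bacteria)
        n_phage_before = len(self.phages)
        ev: dict = {"iteration": self.iteration}
        ev["pulsed"] = self.maybe_trigger_pulse()
        n_phage_before += ev["pulsed"]
        for name in STAGE_ORDER:
            getattr(self, f"_stage_{name}")(ev)
        self.time_h += self.config.sim.dt_h
        self.iteration += 1
        self.peak_phage = max(self.peak_phage, len(self.phages))
        self._audit(n_bact_before, n_phage_before, ev)
        self._record(ev)
        return ev

    def _audit(self, n_bact_before: int, n_phage_before: int, ev: dict) -> None:
        expect_bact = (n_bact_before + ev["births"] - ev["lysed"] - ev["eroded"]
                       - ev["detached"] - ev["abortive_kills"] - ev["overflow"])
        if expect_bact != len(self.bacteria):
            raise LedgerError(
                f"bacterial ledger mismatch at iteration {ev['iteration']}: "
                f"expected {expect_bact}, have {len(self.bacteria)}"
            )
        expect_phage = (n_phage_before + ev["burst_added"] - ev["advected"]
                        - ev["swept"] - ev["infections"] - ev["superinfections"]
                        - ev["abortive_kills"] - ev["neutralized"])
        if expect_phage != len(self.phages):
            raise LedgerError(
                f"phage ledger mismatch at iteration {ev['iteration']}: "
                f"expected {expect_phage}, have {len(self.phages)}"
            )

    def _record(self, ev: dict) -> None:
        counts = self.live_counts()
        _, front_max = front_height(
            self.bacteria.node_mass(self.grid.shape), self.grid.dl
        )
        row = {
            "time_h": self.time_h,
            **counts,
            "n_phage": len(self.phages),
            "front_height_um": front_max,
        }
        row.update({k: v for k, v in ev.items() if k != "iteration"})
        self._history.append(row)
        every = self.config.sim.snapshot_every_iterations
        if every and self.iteration % every == 0:
            self.snapshots.append(self._snapshot())

    def _snapshot(self) -> pd.DataFrame:
        shape = self.grid.shape
        records = []
        node_mass = self.bacteria.node_mass(shape)
        phage_count = np.zeros(shape, dtype=np.int64)
        inside = self.phages.pos[:, 1] < shape[1]
        np.add.at(phage_count, tuple(self.phages.pos[inside].T), 1)
        per_strain = [
            self.bacteria.node_mass(
                shape, weights=(self.bacteria.strain == code).astype(float)
            ) > 0
            for code in range(len(self.strain_table))
        ]
        nutrient = (self._nutrient_field if self._nutrient_field is not None
                    else np.full(shape, self.config.nutrient.N_max_mg_per_l))
        for idx in np.argwhere((node_mass > 0) | (phage_count > 0)):
            t = tuple(idx)
            rec = {
                "iteration": self.iteration,
                "x_idx": t[0],
                "y_idx": t[1],
                "phage_count": int(phage_count[t]),
                "nutrient_mg_l": float(nutrient[t]),
            }
            for sid, occ in zip(self.strain_table.ids, per_strain):
                rec[f"{sid}_present"] = bool(occ[t])
            records.append(rec)
        return pd.DataFrame.from_records(records)

    # -- exit conditions ----------------------------------------------------

    def check_exit(self) -> ExitStatus:
        c = self.live_counts()
        n_sus = c["n_susceptible"] + c["n_infected"]
        n_res = c["n_resistant"]
        if n_sus == 0 and n_res > 0:
            return ExitStatus.FIXATION_RESISTANT
        if n_res == 0 and n_sus > 0:
            return ExitStatus.FIXATION_SUSCEPTIBLE
        sim = self.config.sim
        if (np.isfinite(self.infection_time_h)
                and self.time_h >= self.infection_time_h
                + sim.endpoint_days_after_infection * 24.0 - 1e-9):
            return ExitStatus.TIMEOUT
        if (sim.max_duration_days is not None
                and self.time_h >= sim.max_duration_days * 24.0 - 1e-9):
            return ExitStatus.TIMEOUT
        return ExitStatus.CONTINUE

    # -- driver -------------------------------------------------------------

    def run(self, max_iterations: int | None = None) -> RunResult:
        """Inoculate (if empty), iterate to an exit condition, summarize."""
        if len(self.bacteria) == 0:
            self.inoculate()
        f_inoc = self.resistant_frequency()
        status = self.check_exit()
        while status is ExitStatus.CONTINUE:
            if max_iterations is not None and self.iteration >= max_iterations:
                status = ExitStatus.TIMEOUT
                break
            self.iterate()
            status = self.check_exit()
        history = pd.DataFrame(self._history)
        return RunResult(
            seed=self.seed,
            exit_status=status,
            f_inoculated=f_inoc,
            f_before=self.f_before,
            f_after=self.resistant_frequency(),
            peak_phage=self.peak_phage,
            infection_time_h=self.infection_time_h,
            end_time_h=self.time_h,
            history=history,
            snapshots=self.snapshots,
        )


def run_replicate(config: Config, seed: int | None = None,
                  max_iterations: int | None = None) -> RunResult:
    """Convenience wrapper: build, inoculate, and run one replicate."""
    sim = Simulation(config, seed=seed)
    return sim.run(max_iterations=max_iterations)
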