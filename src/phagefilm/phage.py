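"""Individual virions: impeded lattice random walk, infection, and burst.

Each phage performs, per simulation iteration, up to ``n = D_P dt / (2 dl^2)``
lattice steps of duration ``dtp = 2 dl^2 / D_P``.  Every step it (i) risks
advective removal when off the biofilm with hazard dtp * d^2 * delta_P (d the
distance to the nearest biomass), (ii) stays in its node with probability
erf(1/sqrt(2 a pi)) or else picks one of the 2*dim axis directions uniformly,
(iii) tests for sorption to biomass with hazard dtp * (I_s + I_t) built from
the source and target node interaction rates, and (iv) on sorption ceases
motion for the iteration; otherwise it moves.  A stopped phage then attempts
infection of one co-resident cell drawn with probability proportional to its
mass-weighted sorption rate, firing with hazard gamma * dtr where
dtr = dt * s / n and s is the number of steps taken.

All hazard probabilities share the survival form p = 1 - exp(-x); the walk is
vectorized across the whole phage population.
"""

from __future__ import annotations

import enum
import math

import numpy as np
from scipy.special import erf

from .bacteria import BacterialPopulation, MODE_CODE
from .params import PhageParams, ResistanceMode
from .space import Grid

__all__ = [
    "PhagePopulation",
    "InfectionOutcome",
    "stay_probability",
    "steps_per_iteration",
    "step_time",
    "node_interaction_rate",
    "interaction_rate_field",
    "removal_probability",
    "removal_check",
    "interaction_probability",
    "interaction_check",
    "remaining_time",
    "random_walk",
    "attempt_infection",
    "infection_stage",
    "lyse_cells",
    "sweep_free_phages",
]

#: virtual empty rows above the open top through which walkers may overshoot
TOP_PAD = 8


class InfectionOutcome(enum.Enum):
    NONE = "none"
    INFECTED = "infected"
    SUPERINFECTION = "superinfection"
    ABORTIVE_KILL = "abortive_kill"
    PHAGE_NEUTRALIZED = "phage_neutralized"
    PASS_THROUGH = "pass_through"


# ---------------------------------------------------------------------------
# scalar building blocks

def stay_probability(dimension_constant_a: int) -> float:
    """Probability that a phage remains in its node during one walk step.

    Integrating the normalized Gaussian step kernel over a disc of the node's
    area gives erf(1/sqrt(2 a pi)): 0.427 in 2D (a=1), 0.222 in 3D (a=4).
    """
    if dimension_constant_a not in (1, 4):
        raise ValueError("dimension constant a must be 1 (2D) or 4 (3D)")
    return float(erf(1.0 / math.sqrt(2.0 * dimension_constant_a * math.pi)))


def steps_per_iteration(D_P_um2_s: float, dt_s: float, dl_um: float) -> int:
    """n = round(D_P dt / (2 dl^2)): potential walk steps per iteration."""
    if dl_um <= 0:
        raise ValueError("dl must be positive")
    return int(round(D_P_um2_s * dt_s / (2.0 * dl_um**2)))


def step_time(D_P_um2_s: float, dl_um: float) -> float:
    """dtp = 2 dl^2 / D_P: duration of one walk step, seconds."""
    if D_P_um2_s <= 0:
        raise ValueError("step time undefined for non-positive diffusivity")
    return 2.0 * dl_um**2 / D_P_um2_s


def node_interaction_rate(masses_g, rate_I, m_s_g: float) -> float:
    """Total sorption rate I_x of a node's biomass, s^-1.

    I_x = sum_i m_i * I_i with the cell mass m_i expressed in units of the
    single-cell mass m_s and I_i the strain's sorption rate in
    (m_s um^3)^-1 s^-1 (the um^3 normalizes a cell's biomass to the node
    volume it occupies, so one cell of mass m_s contributes I_i to the node
    rate).  Additive in individuals; a fully packed node of ~5 cells yields
    I_x ~ 0.5 s^-1, making entry into dense biomass a near-certain sorption
    within a few walk steps -- the impedance regime the model is built around.
    """
    masses_g = np.asarray(masses_g, dtype=float)
    rate_I = np.broadcast_to(np.asarray(rate_I, dtype=float), masses_g.shape)
    return float(np.sum(masses_g / m_s_g * rate_I))


def interaction_rate_field(pop: BacterialPopulation, shape) -> np.ndarray:
    """Per-node sorption rate I_x (s^-1) over the whole lattice."""
    out = np.zeros(shape)
    if len(pop):
        w = pop.mass / pop.m_s * pop.strains.rate_I[pop.strain]
        np.add.at(out, tuple(pop.pos.T), w)
    return out


def removal_probability(d_um, delta_P_per_um2_h: float, dtp_h: float):
    """Advective removal hazard per step: p = 1 - exp(-dtp * d^2 * delta_P)."""
    if delta_P_per_um2_h == 0.0:
        return np.zeros_like(np.asarray(d_um, dtype=float)) if np.ndim(d_um) else 0.0
    return -np.expm1(-dtp_h * np.square(d_um) * delta_P_per_um2_h)


def removal_check(d_um: float, delta_P_per_um2_h: float, dtp_h: float,
                  rng: np.random.Generator) -> bool:
    return bool(rng.random() < removal_probability(d_um, delta_P_per_um2_h, dtp_h))


def interaction_probability(I_source, I_target, dtp_s: float):
    """Sorption hazard per step: p = 1 - exp(-dtp * (I_s + I_t))."""
    return -np.expm1(-dtp_s * (np.asarray(I_source, dtype=float) + I_target))


def interaction_check(I_source: float, I_target: float, dtp_s: float,
                      rng: np.random.Generator) -> bool:
    return bool(rng.random() < interaction_probability(I_source, I_target, dtp_s))


def remaining_time(dt_h: float, s, n: int, mode: str = "elapsed"):
    """Contact-time budget dtr for the infection attempt of a stopped phage.

    "elapsed" gives dtr = dt * s / n, the walk time spent before sorption;
    "remaining" gives dt * (n - s) / n, the time left in the iteration.
    n = 0 yields 0.
    """
    if n == 0:
        return np.zeros_like(np.asarray(s, dtype=float)) if np.ndim(s) else 0.0
    s = np.asarray(s, dtype=float)
    frac = s / n if mode == "elapsed" else (n - s) / n
    out = dt_h * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population container

class PhagePopulation:
    """Struct-of-arrays container for live virions.

    ``pos`` may extend up to TOP_PAD rows above the grid (the off-top zone);
    ``s`` counts walk steps taken this iteration and ``stopped`` marks phages
    sorbed to biomass (they resume walking next iteration).
    """

    def __init__(self, dim: int):
        self.dim = dim
        self.pos = np.empty((0, dim), dtype=np.int64)
        self.s = np.empty(0, dtype=np.int64)
        self.stopped = np.empty(0, dtype=bool)

    def __len__(self) -> int:
        return self.pos.shape[0]

    def add(self, pos) -> None:
        pos = np.atleast_2d(np.asarray(pos, dtype=np.int64))
        self.pos = np.concatenate([self.pos, pos])
        self.s = np.concatenate([self.s, np.zeros(pos.shape[0], dtype=np.int64)])
        self.stopped = np.concatenate([self.stopped, np.zeros(pos.shape[0], dtype=bool)])

    def remove(self, mask: np.ndarray) -> int:
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        keep = ~mask
        self.pos = self.pos[keep]
        self.s = self.s[keep]
        self.stopped = self.stopped[keep]
        return n

    def reset_iteration(self, sorbed_behavior: str = "stay", n_steps: int = 0) -> None:
        """Prepare the population for a new iteration's walk.

        With ``sorbed_behavior="resume"`` every phage is released and walks
        again.  With ``"stay"`` previously sorbed phages remain attached; they
        skip the walk and their contact time for the next infection attempt is
        the whole iteration (s = n).
        """
        if sorbed_behavior == "resume":
            self.s[:] = 0
            self.stopped[:] = False
        else:
            free = ~self.stopped
            self.s[free] = 0
            self.s[self.stopped] = n_steps


# ---------------------------------------------------------------------------
# the walk

def random_walk(
    phages: PhagePopulation,
    grid: Grid,
    ix_ext: np.ndarray,
    dist_ext_um: np.ndarray,
    n_steps: int,
    dtp_s: float,
    delta_P_per_um2_h: float,
    rng: np.random.Generator,
) -> int:
    """Advance every live phage by up to ``n_steps`` walk steps.

    ``ix_ext`` and ``dist_ext_um`` are the node interaction-rate and
    distance-to-biofilm fields extended by TOP_PAD empty rows above the grid.
    Phages that sorb to biomass stop (``stopped`` set, ``s`` recorded, the
    sorbing step counts as taken); phages advected away are removed.  Moves
    into the substratum, or beyond the padded top, spend the step in place.
    Returns the number of phages removed by advection.
    """
    P = len(phages)
    if P == 0 or n_steps == 0:
        return 0
    shape = ix_ext.shape
    dim = phages.dim
    p_stay = stay_probability(grid.config.dimension_constant_a)
    dtp_h = dtp_s / 3600.0
    pos = phages.pos
    s = phages.s
    stopped = phages.stopped
    dead = np.zeros(P, dtype=bool)
    active = np.flatnonzero(~stopped)

    for _ in range(n_steps):
        if active.size == 0:
            break
        p = pos[active]
        # (i) advective removal while off the biofilm
        if delta_P_per_um2_h > 0.0:
            d = dist_ext_um[tuple(p.T)]
            off = d > 0
            if off.any():
                u = rng.random(active.size)
                rem = off & (u < removal_probability(d, delta_P_per_um2_h, dtp_h))
                if rem.any():
                    dead[active[rem]] = True
                    active = active[~rem]
                    p = p[~rem]
        k = active.size
        if k == 0:
            break
        # (ii) stay or pick a direction
        tgt = p.copy()
        move = rng.random(k) >= p_stay
        nm = int(move.sum())
        if nm:
            dirs = rng.integers(0, 2 * dim, size=nm)
            axis = dirs >> 1
            sign = np.where(dirs & 1, 1, -1)
            mt = tgt[move]
            mt[np.arange(nm), axis] += sign
            for ax in grid.lateral_axes:
                mt[:, ax] %= shape[ax]
            vy = mt[:, 1]
            blocked = (vy < 0) | (vy >= shape[1])
            if blocked.any():
                mt[blocked] = p[move][blocked]
            tgt[move] = mt
        # (iii) sorption test against source + target rates
        tot = ix_ext[tuple(p.T)] + ix_ext[tuple(tgt.T)]
        inter = rng.random(k) < -np.expm1(-dtp_s * tot)
        # (iv) stop or move; the step is taken either way
        s[active] += 1
        if inter.any():
            stopped[active[inter]] = True
        pos[active[~inter]] = tgt[~inter]
        active = active[~inter]

    n_advected = phages.remove(dead)
    return n_advected


# ---------------------------------------------------------------------------
# infection, lysis, detachment

def attempt_infection(
    bpop: BacterialPopulation,
    cell_indices: np.ndarray,
    dtr_h: float,
    gamma_per_h: float,
    now_h: float,
    rng: np.random.Generator,
) -> tuple[InfectionOutcome, int]:
    """One stopped phage attempts infection among the cells of its node.

    A host is drawn with probability proportional to m_i * I_i; the trigger
    fires with probability 1 - exp(-gamma * dtr).  The outcome depends on the
    host strain's resistance mode; a fired contact with an already-infected
    susceptible cell consumes the phage without resetting the host's clock.
    Returns (outcome, host index or -1).
    """
    cell_indices = np.asarray(cell_indices, dtype=np.int64)
    if cell_indices.size == 0:
        return InfectionOutcome.NONE, -1
    w = (bpop.mass[cell_indices] / bpop.m_s
         * bpop.strains.rate_I[bpop.strain[cell_indices]])
    total = w.sum()
    if total <= 0.0:
        return InfectionOutcome.NONE, -1
    pick = min(int(np.searchsorted(np.cumsum(w), rng.random() * total)),
               cell_indices.size - 1)
    host = int(cell_indices[pick])
    if not (rng.random() < -math.expm1(-gamma_per_h * dtr_h)):
        return InfectionOutcome.NONE, host
    mode = int(bpop.strains.mode[bpop.strain[host]])
    if mode == MODE_CODE[ResistanceMode.SUSCEPTIBLE]:
        if bpop.infected[host]:
            return InfectionOutcome.SUPERINFECTION, host
        bpop.infected[host] = True
        bpop.infection_time[host] = now_h
        return InfectionOutcome.INFECTED, host
    if mode == MODE_CODE[ResistanceMode.ABORTIVE]:
        return InfectionOutcome.ABORTIVE_KILL, host
    if mode == MODE_CODE[ResistanceMode.PHAGE_NEUTRALIZING]:
        return InfectionOutcome.PHAGE_NEUTRALIZED, host
    # surface-modification resistance: both parties intact
    if bpop.strains.halt_on_contact[bpop.strain[host]]:
        bpop.halted[host] = True
    return InfectionOutcome.PASS_THROUGH, host


def infection_stage(
    phages: PhagePopulation,
    bpop: BacterialPopulation,
    grid: Grid,
    phg: PhageParams,
    dt_h: float,
    n_steps: int,
    now_h: float,
    rng: np.random.Generator,
) -> dict:
    """Every stopped phage attempts one infection; applies all outcomes.

    Phages are processed in index order; a host killed by an abortive event is
    no longer available to later phages in the same node.  Returns event
    counts; consumed phages and killed hosts are removed from the populations.
    """
    counts = {
        "infections": 0,
        "superinfections": 0,
        "abortive_kills": 0,
        "neutralized": 0,
        "pass_through": 0,
        "killed_mass": 0.0,
    }
    stopped_idx = np.flatnonzero(phages.stopped)
    if stopped_idx.size == 0 or len(bpop) == 0:
        return counts

    shape = grid.shape
    key = bpop.node_key(shape)
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    cell_dead = np.zeros(len(bpop), dtype=bool)
    phage_dead = np.zeros(len(phages), dtype=bool)
    st = bpop.strains
    mode = st.mode[bpop.strain]
    abortive_code = MODE_CODE[ResistanceMode.ABORTIVE]
    neutral_code = MODE_CODE[ResistanceMode.PHAGE_NEUTRALIZING]
    sus_code = MODE_CODE[ResistanceMode.SUSCEPTIBLE]

    # phages outside the grid (off-top pad) cannot meet cells
    inside = np.all(
        (phages.pos[stopped_idx] >= 0)
        & (phages.pos[stopped_idx] < np.asarray(shape)), axis=1
    )
    stopped_idx = stopped_idx[inside]
    if stopped_idx.size == 0:
        return counts
    pkey = np.ravel_multi_index(tuple(phages.pos[stopped_idx].T), shape)

    # route phages whose node contains an abortive-mode cell through the
    # sequential path (host death there changes the draw weights); everywhere
    # else weights are static and the whole node can be handled in one shot
    abortive_nodes = np.zeros(int(np.prod(shape)), dtype=bool)
    abortive_nodes[key[mode == abortive_code]] = True
    seq = abortive_nodes[pkey]

    for pi in stopped_idx[seq]:
        flat = int(np.ravel_multi_index(tuple(phages.pos[pi]), shape))
        lo, hi = np.searchsorted(sorted_key, [flat, flat + 1])
        cells = order[lo:hi]
        cells = cells[~cell_dead[cells]]
        dtr = remaining_time(dt_h, int(phages.s[pi]), n_steps, phg.dtr_mode)
        outcome, host = attempt_infection(
            bpop, cells, dtr, phg.gamma_per_h, now_h, rng
        )
        if outcome is InfectionOutcome.INFECTED:
            counts["infections"] += 1
            phage_dead[pi] = True
        elif outcome is InfectionOutcome.SUPERINFECTION:
            counts["superinfections"] += 1
            phage_dead[pi] = True
        elif outcome is InfectionOutcome.ABORTIVE_KILL:
            counts["abortive_kills"] += 1
            counts["killed_mass"] += float(bpop.mass[host])
            cell_dead[host] = True
            phage_dead[pi] = True
        elif outcome is InfectionOutcome.PHAGE_NEUTRALIZED:
            counts["neutralized"] += 1
            phage_dead[pi] = True
        elif outcome is InfectionOutcome.PASS_THROUGH:
            counts["pass_through"] += 1

    vec_idx = stopped_idx[~seq]
    if vec_idx.size:
        dtr = remaining_time(dt_h, phages.s[vec_idx], n_steps, phg.dtr_mode)
        fired = rng.random(vec_idx.size) < -np.expm1(-phg.gamma_per_h * dtr)
        vec_idx = vec_idx[fired]
        vkey = pkey[~seq][fired]
        w_all = bpop.mass / bpop.m_s * st.rate_I[bpop.strain]
        for flat in np.unique(vkey):
            lo, hi = np.searchsorted(sorted_key, [flat, flat + 1])
            cells = order[lo:hi]
            w = w_all[cells]
            total = w.sum()
            group = vec_idx[vkey == flat]
            if cells.size == 0 or total <= 0.0:
                continue
            cum = np.cumsum(w)
            picks = np.minimum(
                np.searchsorted(cum, rng.random(group.size) * total),
                cells.size - 1,
            )
            hosts = cells[picks]
            hmode = mode[hosts]
            hit_sus = hmode == sus_code
            if hit_sus.any():
                sus_hosts = hosts[hit_sus]
                fresh = np.unique(sus_hosts[~bpop.infected[sus_hosts]])
                bpop.infected[fresh] = True
                bpop.infection_time[fresh] = now_h
                counts["infections"] += fresh.size
                counts["superinfections"] += int(hit_sus.sum()) - fresh.size
                phage_dead[group[hit_sus]] = True
            hit_neu = hmode == neutral_code
            if hit_neu.any():
                counts["neutralized"] += int(hit_neu.sum())
                phage_dead[group[hit_neu]] = True
            hit_surf = ~hit_sus & ~hit_neu
            if hit_surf.any():
                counts["pass_through"] += int(hit_surf.sum())
                halting = hosts[hit_surf][
                    st.halt_on_contact[bpop.strain[hosts[hit_surf]]]
                ]
                bpop.halted[halting] = True

    bpop.remove(cell_dead)
    phages.remove(phage_dead)
    return counts


def lyse_cells(
    bpop: BacterialPopulation,
    phages: PhagePopulation,
    now_h: float,
    tau_h: float,
    beta: int,
) -> tuple[int, float]:
    """Burst every infected cell whose incubation period has elapsed.

    A cell infected at time t lyses once now - t >= tau, releasing exactly
    beta phages into its node.  Returns (number lysed, mass removed).
    """
    due = bpop.infected & (now_h - bpop.infection_time >= tau_h - 1e-12)
    idx = np.flatnonzero(due)
    if idx.size:
        phages.add(np.repeat(bpop.pos[idx], beta, axis=0))
    return bpop.remove(due)


def sweep_free_phages(phages: PhagePopulation, occupied_ext: np.ndarray) -> int:
    """End-of-iteration advective sweep: remove every phage whose node holds
    no live bacterial mass (``occupied_ext`` covers the off-top pad)."""
    if len(phages) == 0:
        return 0
    free = ~occupied_ext[tuple(phages.pos.T)]
    return phages.remove(free)
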