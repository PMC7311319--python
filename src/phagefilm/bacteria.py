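"""Individual bacterial agents and their population-level operations.

Cells are discrete individuals with a strain identity, a mass, a lattice node,
and an infection state.  For speed the population is stored as parallel numpy
arrays (struct-of-arrays) rather than one object per cell; the operations
below are the module's public surface: growth, division, shoving relaxation,
height-dependent front erosion, and detachment of disconnected biomass.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .params import BacteriaParams, ResistanceMode, Strain
from .space import Grid

__all__ = [
    "StrainTable",
    "BacterialPopulation",
    "grow_cells",
    "divide_cells",
    "shove_relax",
    "erode",
    "detach_disconnected",
    "ShoveError",
]

MODE_CODE = {
    ResistanceMode.SUSCEPTIBLE: 0,
    ResistanceMode.ABORTIVE: 1,
    ResistanceMode.SURFACE: 2,
    ResistanceMode.PHAGE_NEUTRALIZING: 3,
}


class ShoveError(RuntimeError):
    """Shoving relaxation failed to terminate within its iteration cap."""


class StrainTable:
    """Per-strain parameter arrays indexed by a small integer strain code."""

    def __init__(self, strains: tuple[Strain, ...], bact: BacteriaParams):
        self.ids = [s.id for s in strains]
        self.mode = np.array([MODE_CODE[s.resistance_mode] for s in strains], dtype=np.int8)
        self.cost = np.array([s.cost_c for s in strains])
        self.rate_I = np.array([s.interaction_rate_I for s in strains])
        self.halt_on_contact = np.array([s.halt_on_contact for s in strains])
        #: realized maximum specific growth rate per strain, h^-1
        self.max_rate_h = (1.0 - self.cost) * bact.mu_s_per_h
        self.susceptible = self.mode == MODE_CODE[ResistanceMode.SUSCEPTIBLE]

    def code(self, strain_id: str) -> int:
        return self.ids.index(strain_id)

    def __len__(self) -> int:
        return len(self.ids)


class BacterialPopulation:
    """Struct-of-arrays container for every live cell."""

    def __init__(self, strain_table: StrainTable, dim: int, m_s_g: float):
        self.strains = strain_table
        self.dim = dim
        self.m_s = m_s_g
        self.pos = np.empty((0, dim), dtype=np.int64)
        self.mass = np.empty(0)
        self.strain = np.empty(0, dtype=np.int8)
        self.infected = np.empty(0, dtype=bool)
        self.infection_time = np.empty(0)
        self.halted = np.empty(0, dtype=bool)

    def __len__(self) -> int:
        return self.pos.shape[0]

    def add(self, pos, strain, mass=None, infected=False, infection_time=np.nan,
            halted=False) -> None:
        pos = np.atleast_2d(np.asarray(pos, dtype=np.int64))
        n = pos.shape[0]
        self.pos = np.concatenate([self.pos, pos])
        self.mass = np.concatenate([self.mass, np.broadcast_to(
            np.asarray(mass if mass is not None else self.m_s, dtype=float), n).copy()])
        self.strain = np.concatenate([self.strain, np.broadcast_to(
            np.asarray(strain, dtype=np.int8), n).copy()])
        self.infected = np.concatenate([self.infected, np.broadcast_to(
            np.asarray(infected, dtype=bool), n).copy()])
        self.infection_time = np.concatenate([self.infection_time, np.broadcast_to(
            np.asarray(infection_time, dtype=float), n).copy()])
        self.halted = np.concatenate([self.halted, np.broadcast_to(
            np.asarray(halted, dtype=bool), n).copy()])
        if np.any(self.infected & ~self.strains.susceptible[self.strain]):
            raise ValueError("only susceptible-strain cells can be infected")

    def remove(self, mask: np.ndarray) -> tuple[int, float]:
        """Drop cells where ``mask`` is True; returns (count, mass removed)."""
        mask = np.asarray(mask, dtype=bool)
        n, m = int(mask.sum()), float(self.mass[mask].sum())
        keep = ~mask
        self.pos = self.pos[keep]
        self.mass = self.mass[keep]
        self.strain = self.strain[keep]
        self.infected = self.infected[keep]
        self.infection_time = self.infection_time[keep]
        self.halted = self.halted[keep]
        return n, m

    # -- per-node aggregates ------------------------------------------------
    def node_key(self, shape) -> np.ndarray:
        return np.ravel_multi_index(tuple(self.pos.T), shape)

    def node_mass(self, shape, weights: np.ndarray | None = None) -> np.ndarray:
        out = np.zeros(shape)
        w = self.mass if weights is None else self.mass * weights
        np.add.at(out, tuple(self.pos.T), w)
        return out

    def active_sink_mass(self, shape) -> np.ndarray:
        """Cost-weighted mass of actively growing (uninfected, unhalted) cells.

        Weighting each cell by (1 - c) keeps the field's consumption identical
        to the substrate the growth step actually books (mu = (1-c) mu_s ...).
        """
        growing = (~self.infected) & (~self.halted)
        w = growing * (1.0 - self.strains.cost[self.strain])
        return self.node_mass(shape, weights=w)

    def counts(self) -> dict:
        sus = self.strains.susceptible[self.strain]
        return {
            "n_susceptible": int((sus & ~self.infected).sum()),
            "n_resistant": int((~sus).sum()),
            "n_infected": int(self.infected.sum()),
        }


# ---------------------------------------------------------------------------
# growth and division

def grow_cells(pop: BacterialPopulation, nutrient_field: np.ndarray,
               K_N: float, Y: float, dt_h: float) -> tuple[float, float]:
    """Grow every uninfected, unhalted cell for one time step.

    dm = mu * m * dt with mu = (1 - c) * mu_s * N / (K_N + N) evaluated at the
    cell's node.  Infected and growth-halted cells neither grow nor consume.
    Returns (total biomass added, total substrate consumed = dm / Y), in grams.
    """
    if len(pop) == 0:
        return 0.0, 0.0
    N = nutrient_field[tuple(pop.pos.T)]
    mu = pop.strains.max_rate_h[pop.strain] * N / (K_N + N)
    mu[pop.infected | pop.halted] = 0.0
    dm = mu * pop.mass * dt_h
    pop.mass = pop.mass + dm
    grown = float(dm.sum())
    return grown, grown / Y


def divide_cells(pop: BacterialPopulation, rng: np.random.Generator) -> int:
    """Split every uninfected cell whose mass reached 2 m_s into two equal halves.

    The daughter is placed in the same node (shoving resolves crowding).  Total
    mass is conserved exactly.  Returns the number of births.
    """
    births = 0
    while True:
        ready = np.flatnonzero((pop.mass >= 2.0 * pop.m_s) & ~pop.infected & ~pop.halted)
        if ready.size == 0:
            return births
        pop.mass[ready] *= 0.5
        pop.add(
            pop.pos[ready],
            pop.strain[ready],
            mass=pop.mass[ready],
            halted=pop.halted[ready],
        )
        births += ready.size


# ---------------------------------------------------------------------------
# shoving relaxation

def _neighbor_list(grid: Grid, node: tuple) -> list:
    """Valid shoving targets: lattice neighbors (periodic laterally, never into
    the substratum) plus, for top-row nodes, the open top (encoded as None)."""
    out = []
    for ax in range(grid.dimension):
        for step in (-1, 1):
            idx = list(node)
            idx[ax] += step
            if ax in grid.lateral_axes:
                idx[ax] %= grid.shape[ax]
            elif idx[ax] < 0:
                continue  # solid substratum
            elif idx[ax] >= grid.shape[ax]:
                out.append(None)  # open top: cell leaves the system
                continue
            out.append(tuple(idx))
    return out


def shove_relax(pop: BacterialPopulation, grid: Grid, capacity_g: float,
                rng: np.random.Generator, max_moves_per_cell: int = 50,
                start_escalated: bool = False):
    """Redistribute cells until no node's total mass exceeds ``capacity_g``.

    Repeatedly, every over-capacity node pushes one randomly chosen whole cell
    to its least-full lattice neighbor (ties broken uniformly at random; the
    substratum is never a target).  A top-row node may push a cell through the
    open upper boundary, in which case the cell is lost to the bulk flow.

    Because cells move whole, the least-full rule alone can fail to terminate:
    two adjacent nodes whose combined mass exceeds twice the capacity trade a
    cell back and forth indefinitely, and in a lattice saturated up to the
    open top the excess thrashes instead of propagating outward.  When a
    relaxation stalls (more moves than a small multiple of the over-capacity
    node count), it therefore escalates to gradient descent on a
    distance-to-spare-capacity field -- each over-capacity node pushes a cell
    toward the nearest node with room (the open top counts as room), which is
    the classic path-shoving of lattice biofilm models and terminates in one
    lattice-path length per excess cell.
    ``start_escalated`` begins directly in the escalated regime (callers pass
    the previous relaxation's state, since a saturated lattice stays
    saturated).  Returns (moves, overflow count, overflow mass, escalated).
    """
    shape = grid.shape
    node_mass = pop.node_mass(shape)
    moves = 0
    overflow_idx: list[int] = []
    lost = np.zeros(len(pop), dtype=bool)
    max_moves = max(max_moves_per_cell * max(len(pop), 1), 1000)
    tol = capacity_g * (1.0 + 1e-12)
    stall_budget = None  # set on the first pass
    escalated = bool(start_escalated)
    spare_dist = None

    while True:
        over = np.argwhere(node_mass > tol)
        if over.size == 0:
            break
        if stall_budget is None:
            stall_budget = 8 * max(len(over), 1) + 64
        if escalated:
            spare_dist = _spare_distance(node_mass, capacity_g, pop.m_s, grid)
        # node -> cells map for this pass
        key = pop.node_key(shape)
        order = np.argsort(key, kind="stable")
        sorted_key = key[order]
        moved_in: dict[tuple, list[int]] = {}  # arrivals during this pass

        def cells_at(node):
            flat = int(np.ravel_multi_index(node, shape))
            lo, hi = np.searchsorted(sorted_key, [flat, flat + 1])
            pool = [c for c in order[lo:hi]
                    if not lost[c] and tuple(pop.pos[c]) == node]
            pool.extend(c for c in moved_in.get(node, ()) if not lost[c]
                        and tuple(pop.pos[c]) == node)
            return pool

        for start in map(tuple, over):
            node = start
            # in escalated mode follow the displaced excess downhill until it
            # reaches room, so one pass fully drains each over-capacity node
            for _hop in range(sum(shape) + 4):
                if node_mass[node] <= tol:
                    break
                cells = cells_at(node)
                if not cells:
                    break
                cell = cells[rng.integers(len(cells))]
                targets = _neighbor_list(grid, node)
                if escalated:
                    if spare_dist is None:  # escalation happened mid-pass
                        spare_dist = _spare_distance(
                            node_mass, capacity_g, pop.m_s, grid)
                    # descend the distance-to-room field; the open top is room
                    score = np.array(
                        [-1.0 if t is None else spare_dist[t] for t in targets]
                    )
                else:
                    score = np.array(
                        [0.0 if t is None else node_mass[t] for t in targets]
                    )
                best = np.flatnonzero(score == score.min())
                target = targets[best[rng.integers(best.size)]]
                node_mass[node] -= pop.mass[cell]
                if target is None:
                    lost[cell] = True
                    overflow_idx.append(cell)
                    target_over = False
                else:
                    node_mass[target] += pop.mass[cell]
                    pop.pos[cell] = target
                    moved_in.setdefault(target, []).append(cell)
                    target_over = node_mass[target] > tol
                moves += 1
                if not escalated and moves > stall_budget:
                    escalated = True
                if moves > max_moves:
                    raise ShoveError(
                        f"shoving did not terminate within {max_moves} moves"
                    )
                if not escalated:
                    break  # spec rule: one move per over node per pass
                if node_mass[node] > tol:
                    continue  # drain this node first
                if target_over:
                    node = target
                else:
                    break
    mask = np.zeros(len(pop), dtype=bool)
    mask[overflow_idx] = True
    n_over, m_over = pop.remove(mask)
    return moves, n_over, m_over, escalated


def _spare_distance(node_mass: np.ndarray, capacity_g: float, m_s: float,
                    grid: Grid) -> np.ndarray:
    """Lattice distance from every node to the nearest node with room for any
    single cell (cell masses lie in [m_s, 2 m_s), so room means 2 m_s of
    spare capacity -- a descent sink that cannot be overshot by one arrival).
    The open top is room at distance 1 from the top row."""
    spare = node_mass <= capacity_g - 2.0 * m_s
    dist = np.where(spare, 0.0, np.inf)
    dist[:, -1] = np.minimum(dist[:, -1], 1.0)  # open top above the last row
    for _ in range(sum(grid.shape)):
        nd = np.full_like(dist, np.inf)
        for ax in grid.lateral_axes:
            nd = np.minimum(nd, np.roll(dist, 1, axis=ax))
            nd = np.minimum(nd, np.roll(dist, -1, axis=ax))
        up = np.full_like(dist, np.inf)
        up[:, :-1] = dist[:, 1:]
        dn = np.full_like(dist, np.inf)
        dn[:, 1:] = dist[:, :-1]
        nd = np.minimum(nd, np.minimum(up, dn)) + 1.0
        new = np.minimum(dist, nd)
        if np.array_equal(new, dist):
            break
        dist = new
    return dist


# ---------------------------------------------------------------------------
# erosion and detachment

def erode(pop: BacterialPopulation, grid: Grid, delta_E_per_m_h: float,
          dt_h: float, rng: np.random.Generator) -> tuple[int, float]:
    """Height-dependent erosion of the biofilm front.

    A front node is a biomass node with at least one empty von Neumann
    neighbor toward the liquid (the substratum is solid, the space above the
    top row counts as liquid).  Each cell in a front node at height y is
    removed with probability min(1, delta_E * y^2 * dt / dl): the erosion
    front speed delta_E*y^2 (units (m h)^-1 * m^2 = m/h) converted into a
    per-node removal hazard.  Returns (count, mass) removed.
    """
    if len(pop) == 0:
        return 0, 0.0
    shape = grid.shape
    occ = pop.node_mass(shape) > 0
    empty = ~occ
    exposed = np.zeros(shape, dtype=bool)
    # above: off-top is liquid
    exposed[:, :-1] |= empty[:, 1:]
    exposed[:, -1] = True
    # below: substratum is solid, so row 0 gains nothing from below
    exposed[:, 1:] |= empty[:, :-1]
    for ax in grid.lateral_axes:
        exposed |= np.roll(empty, 1, axis=ax)
        exposed |= np.roll(empty, -1, axis=ax)
    front = occ & exposed

    y_um = (pop.pos[:, 1] + 0.5) * grid.dl
    # (m h)^-1 * um^2 * 1e-12 m^2/um^2 * 1e6 um/m = 1e-6 um/h
    speed_um_h = delta_E_per_m_h * 1e-6 * y_um**2
    p = np.minimum(1.0, speed_um_h * dt_h / grid.dl)
    in_front = front[tuple(pop.pos.T)]
    hit = in_front & (rng.random(len(pop)) < p)
    return pop.remove(hit)


def detach_disconnected(pop: BacterialPopulation, grid: Grid) -> tuple[int, float]:
    """Remove connected biomass components that do not touch the substratum.

    Connectivity is von Neumann adjacency on occupied nodes, periodic along
    the lateral axes.  Returns (count, mass) removed.
    """
    if len(pop) == 0:
        return 0, 0.0
    shape = grid.shape
    occ = pop.node_mass(shape) > 0
    labels, n_lab = ndimage.label(occ)  # von Neumann structure by default
    if n_lab == 0:
        return 0, 0.0

    # merge labels across periodic lateral seams (union-find)
    parent = np.arange(n_lab + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ax in grid.lateral_axes:
        lo = np.take(labels, 0, axis=ax).ravel()
        hi = np.take(labels, shape[ax] - 1, axis=ax).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(int(a), int(b))

    roots = np.array([find(i) for i in range(n_lab + 1)])
    anchored_roots = set(roots[np.unique(labels[:, 0])]) - {0}
    node_root = roots[labels]
    anchored = np.isin(node_root, list(anchored_roots)) & occ
    detached_nodes = occ & ~anchored
    hit = detached_nodes[tuple(pop.pos.T)]
    return pop.remove(hit)
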