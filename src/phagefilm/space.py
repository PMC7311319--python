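"""Lattice geometry, boundary conditions, and spatial queries.

The simulation space is a box of cubic nodes of edge ``dl``.  Axis 0 (x) and,
in 3D, axis 2 (z) are lateral and periodic; axis 1 (y) is vertical with a
solid substratum below row 0 and an open top.  Occupancy-dependent queries
(biofilm front height, distance to the nearest biomass) take the per-node live
biomass array explicitly so they can be applied to any population snapshot.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .params import SpaceConfig

__all__ = [
    "BLOCKED",
    "Grid",
    "build_grid",
    "neighbor_index",
    "front_height",
    "distance_field",
    "distance_to_biofilm",
]


class _Blocked:
    """Sentinel for a move into the solid substratum."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "BLOCKED"


BLOCKED = _Blocked()

_DIRECTIONS_2D = ("+x", "-x", "+y", "-y")
_DIRECTIONS_3D = _DIRECTIONS_2D + ("+z", "-z")
_AXIS_OF = {"x": 0, "y": 1, "z": 2}


class Grid:
    """Lattice geometry and index bookkeeping (agents live in populations)."""

    def __init__(self, config: SpaceConfig):
        self.config = config
        self.shape: tuple[int, ...] = config.shape
        self.dl: float = config.dl_um
        self.dimension: int = config.dimension
        #: periodic axes; axis 1 (vertical) is bounded
        self.lateral_axes: tuple[int, ...] = (0,) if self.dimension == 2 else (0, 2)
        self.directions: tuple[str, ...] = (
            _DIRECTIONS_2D if self.dimension == 2 else _DIRECTIONS_3D
        )

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def ny(self) -> int:
        return self.shape[1]

    def contains(self, index) -> bool:
        """True if ``index`` lies inside the grid (off-top virtual nodes do not)."""
        return all(0 <= i < n for i, n in zip(index, self.shape))

    def node_centers_y_um(self) -> np.ndarray:
        """Physical height of each row's node centers: (j + 1/2) * dl."""
        return (np.arange(self.ny) + 0.5) * self.dl


def build_grid(config: SpaceConfig) -> Grid:
    """Construct an empty lattice from a validated space configuration."""
    return Grid(config)


def neighbor_index(grid: Grid, index, direction: str):
    """Neighbor of ``index`` along an axis direction.

    Lateral moves wrap periodically.  A move below the substratum returns
    :data:`BLOCKED`; a move above the top row returns coordinates in the
    virtual off-top zone (``grid.contains`` is False for them).
    """
    if direction not in grid.directions:
        raise ValueError(
            f"invalid direction {direction!r} for a {grid.dimension}D grid"
        )
    axis = _AXIS_OF[direction[1]]
    step = 1 if direction[0] == "+" else -1
    idx = list(index)
    idx[axis] += step
    if axis in grid.lateral_axes:
        idx[axis] %= grid.shape[axis]
    elif idx[axis] < 0:
        return BLOCKED
    return tuple(idx)


def front_height(node_mass: np.ndarray, dl: float):
    """Per-column biofilm height and the global front height.

    The height of a column is ``(1 + highest occupied row index) * dl`` and 0
    for columns holding no live biomass.  Returns ``(heights, max_height)``
    where ``heights`` has the lateral shape of the grid.
    """
    occ = node_mass > 0
    ny = occ.shape[1]
    rows = np.arange(ny).reshape((1, ny) + (1,) * (occ.ndim - 2))
    top = np.max(np.where(occ, rows, -1), axis=1)
    heights = (top + 1) * dl
    return heights, float(heights.max(initial=0.0))


def distance_field(
    node_mass: np.ndarray,
    dl: float,
    lateral_axes: tuple[int, ...] = (0,),
    pad_top: int = 0,
) -> np.ndarray:
    """Euclidean node-center distance from every node to the nearest biomass.

    Periodic along the lateral axes (implemented by tiling, exact because any
    minimal image lies within one lateral period).  ``pad_top`` appends that
    many empty virtual rows above the grid, for walkers that overshoot the
    domain.  If the grid holds no biomass the field is +inf everywhere.
    """
    occ = node_mass > 0
    if pad_top:
        pad = [(0, 0)] * occ.ndim
        pad[1] = (0, pad_top)
        occ = np.pad(occ, pad, constant_values=False)
    if not occ.any():
        return np.full(occ.shape, np.inf)
    reps = [1] * occ.ndim
    for ax in lateral_axes:
        reps[ax] = 3
    tiled = np.tile(occ, reps)
    dist = ndimage.distance_transform_edt(~tiled)
    sl = [slice(None)] * occ.ndim
    for ax in lateral_axes:
        n = occ.shape[ax]
        sl[ax] = slice(n, 2 * n)
    return dist[tuple(sl)] * dl


def distance_to_biofilm(grid: Grid, node_mass: np.ndarray, index) -> float:
    """Distance from one node to the nearest node containing live biomass."""
    return float(distance_field(node_mass, grid.dl, grid.lateral_axes)[tuple(index)])
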