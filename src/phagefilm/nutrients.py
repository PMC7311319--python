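"""Quasi-steady substrate field over the lattice.

Substrate diffuses from a well-mixed bulk layer that sits a boundary-layer
height ``h`` above the biofilm front and is consumed by live biomass with
Monod kinetics.  Because substrate diffusion equilibrates over the domain in
seconds while one simulation iteration is minutes, the field is re-solved to
steady state every iteration instead of being co-integrated in time:

    D_N * laplacian(N) = q_max * B(x) * N / (K_N + N)

with B the local density of actively consuming biomass, Dirichlet N = N_max on
all rows at or above (front height + h), no-flux at the substratum, and
lateral periodicity.  The nonlinear sink is handled by semi-implicit Picard
iteration (the sink is linearized as ``k/(K_N + N_prev) * N``), which keeps
the system an M-matrix and hence the solution within [0, N_max].
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .params import NutrientParams, SpaceConfig
from .space import Grid, front_height

__all__ = ["NutrientSolverError", "solve_nutrient_field", "local_growth_rate", "uptake_rate_field"]

#: relative convergence tolerance and iteration cap of the Picard loop
RTOL = 1e-6
MAX_ITER = 10_000


class NutrientSolverError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"nutrient solver did not converge in {iterations} iterations "
            f"(relative residual {residual:.3e})"
        )


def local_growth_rate(strain_max_rate: float, N, K_N: float):
    """Monod specific growth rate: mu = mu_max * N / (K_N + N)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("substrate concentration must be non-negative")
    return strain_max_rate * N / (K_N + N)


def uptake_rate_field(sink_mass: np.ndarray, space: SpaceConfig, nut: NutrientParams) -> np.ndarray:
    """Zero-order volumetric uptake coefficient per node, mg substrate / (L h).

    ``sink_mass`` is the actively consuming biomass per node in grams; the
    full sink is ``k * N / (K_N + N)`` with the returned ``k``.
    """
    # g/(g h) * g / L -> g/(L h) -> mg/(L h)
    return nut.q_max_per_h * (sink_mass / space.dV_l) * 1e3


def _dirichlet_row(front_max_um: float, space: SpaceConfig, nut: NutrientParams) -> int:
    """First row whose node center lies at or above front height + h."""
    y_boundary = front_max_um + nut.h_um
    j = int(np.ceil(y_boundary / space.dl_um - 0.5 - 1e-12))
    return max(j, 1)  # keep at least one interior row


def solve_nutrient_field(
    grid: Grid,
    sink_mass: np.ndarray,
    nut: NutrientParams,
    warm_start: np.ndarray | None = None,
    rtol: float = RTOL,
    max_iter: int = MAX_ITER,
    cache: dict | None = None,
) -> np.ndarray:
    """Quasi-steady substrate concentration per node (mg/L).

    ``sink_mass`` holds the actively consuming biomass per node (g).  Rows at
    or above the bulk boundary (front height + h) are clamped to N_max; if the
    biofilm front leaves no such row inside the grid, the bulk is imposed
    through a ghost row above the open top.
    """
    space = grid.config
    shape = grid.shape
    if not (sink_mass > 0).any():
        return np.full(shape, nut.N_max_mg_per_l)

    _, front_max = front_height(sink_mass, space.dl_um)
    # if the front leaves no bulk row inside the grid, the Dirichlet boundary
    # degenerates to a ghost row above the open top
    jb = min(_dirichlet_row(front_max, space, nut), grid.ny)

    # active (unknown) region: rows 0..jb-1, all lateral columns
    sub = (slice(None), slice(0, jb)) + (slice(None),) * (len(shape) - 2)
    k = uptake_rate_field(sink_mass, space, nut)[sub]
    active_shape = k.shape
    n_unknown = k.size
    D = nut.D_N_um2_per_h / space.dl_um**2
    N_max, K_N = nut.N_max_mg_per_l, nut.K_N_mg_per_l

    idx = np.arange(n_unknown).reshape(active_shape)
    rows_l, cols_l = [], []

    def couple(a, b):
        rows_l.append(a.ravel())
        cols_l.append(b.ravel())

    # lateral neighbors (periodic)
    for ax in grid.lateral_axes:
        couple(idx, np.roll(idx, 1, axis=ax))
        couple(idx, np.roll(idx, -1, axis=ax))
    # vertical neighbors inside the active region
    up = (slice(None), slice(0, jb - 1)) + (slice(None),) * (len(shape) - 2)
    dn = (slice(None), slice(1, jb)) + (slice(None),) * (len(shape) - 2)
    couple(idx[up], idx[dn])
    couple(idx[dn], idx[up])

    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    off = sparse.coo_matrix(
        (np.full(rows.size, -D), (rows, cols)), shape=(n_unknown, n_unknown)
    ).tocsr()

    # diagonal degree: lateral couplings + vertical couplings; bottom row is
    # no-flux (mirror ghost, no coupling), top active row couples to Dirichlet
    deg = np.full(active_shape, 2.0 * len(grid.lateral_axes))
    top_row = (slice(None), slice(jb - 1, jb)) + (slice(None),) * (len(shape) - 2)
    deg[up] += 1.0  # has neighbor above within region
    deg[dn] += 1.0  # has neighbor below within region
    deg[top_row] += 1.0  # Dirichlet (real row jb or ghost above open top)
    b = np.zeros(active_shape)
    b[top_row] = D * N_max

    N = (warm_start[sub].copy() if warm_start is not None
         else np.full(active_shape, N_max)).ravel()
    kflat = k.ravel()
    bflat = b.ravel()
    base_diag = D * deg.ravel()
    # one LU factorization per linearization point; between refactorizations
    # the change of the Monod coefficient is folded into the right-hand side
    # (A0 x = b + (c0 - c) x), which converges because |c0 - c| stays small
    # relative to the diagonal once the field is near its fixed point.  The
    # factorization is reused across successive calls (the field changes
    # little per simulation iteration) through the optional ``cache``.
    lu, c0 = None, None
    if cache is not None and cache.get("key") == (active_shape, jb):
        lu, c0 = cache["lu"], cache["c0"]
    err = np.inf
    for it in range(1, max_iter + 1):
        c = kflat / (K_N + N)
        if lu is None or it % 8 == 0:
            c0 = c
            A = off + sparse.diags(base_diag + c0)
            lu = splu(A.tocsc())
        N_new = lu.solve(bflat + (c0 - c) * N)
        err = float(np.max(np.abs(N_new - N))) / N_max
        N = N_new
        if err <= rtol:
            break
    else:
        raise NutrientSolverError(err, max_iter)
    if cache is not None:
        cache.update(key=(active_shape, jb), lu=lu, c0=c0)
    N = N.reshape(active_shape)

    field = np.full(shape, N_max)
    field[sub] = np.clip(N, 0.0, N_max)
    return field
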