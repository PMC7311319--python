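"""Parameter-sweep orchestration and frequency-change statistics.

A sweep runs replicate simulations over a grid of conditions (bulk nutrient,
initial resistant fraction, resistance cost, phage interaction rate, phage
removal rate), trims replicates in which the phage pulse never amplified
(peak phage count <= 150, i.e. the 120-virion pulse produced zero infections),
and aggregates the change in resistant-strain frequency after phage exposure
into heatmap cells for invasibility analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import Config, ConfigError, desk_config
from .simulation import RunResult, Simulation

__all__ = [
    "SweepSpec",
    "ReplicateRecord",
    "HeatmapCell",
    "trim_replicate",
    "frequency_change",
    "classify_selection",
    "run_sweep",
]

#: replicates whose peak phage count does not exceed this are trimmed
TRIM_THRESHOLD = 150


@dataclass(frozen=True)
class SweepSpec:
    """The condition grid of a sweep.

    The desk-scale default (5 x 5 conditions, 10 replicates, one cost /
    interaction / removal level) is a reduced version of the full study grid
    (21 nutrient values x 21 initial frequencies x 100 replicates, three cost
    and three interaction levels), which is reachable through configuration
    but sized for a cluster rather than a desk.
    """

    nutrient_values: tuple = tuple(np.linspace(1.1, 8.0, 5).round(3))
    initial_frequencies: tuple = tuple(np.linspace(0.05, 0.95, 5).round(3))
    cost_levels: tuple = (0.05,)
    interaction_levels: tuple = (0.09,)
    removal_levels: tuple = (5.0,)
    replicates_per_cell: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nutrient_values", "initial_frequencies", "cost_levels",
                     "interaction_levels", "removal_levels"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"sweep.{name} must be non-empty")
        if any(not 0.0 < f < 1.0 for f in self.initial_frequencies):
            raise ConfigError("sweep.initial_frequencies must lie in (0, 1)")
        if self.replicates_per_cell < 1:
            raise ConfigError("sweep.replicates_per_cell must be >= 1")

    @property
    def cells(self) -> list[tuple]:
        return list(itertools.product(
            self.nutrient_values, self.initial_frequencies, self.cost_levels,
            self.interaction_levels, self.removal_levels,
        ))

    @classmethod
    def from_dict(cls, data: dict) -> "SweepSpec":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown key(s) in section 'sweep': {sorted(bad)}")
        data = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in data.items()}
        return cls(**data)


@dataclass(frozen=True)
class ReplicateRecord:
    """One replicate's coordinates in the sweep grid and its outcome."""

    nutrient: float
    initial_frequency: float
    cost: float
    interaction: float
    removal: float
    replicate: int
    seed: int
    f_inoculated: float
    f_before: float
    f_after: float
    peak_phage: int
    exit_status: str

    @property
    def valid(self) -> bool:
        """False when a frequency is undefined (extinct population or no pulse)."""
        return np.isfinite(self.f_before) and np.isfinite(self.f_after)


@dataclass(frozen=True)
class HeatmapCell:
    nutrient: float
    initial_frequency: float
    cost: float
    interaction: float
    removal: float
    mean_df: float
    n_retained: int


def trim_replicate(record: ReplicateRecord, threshold: int = TRIM_THRESHOLD) -> bool:
    """Keep a replicate only if its phage pulse amplified at least once.

    A 120-virion pulse with zero infections never exceeds 150 phages; one
    burst (+120) does.  The boundary is strict: peak == threshold is trimmed.
    Invalid records (undefined frequencies) are always trimmed.
    """
    return record.valid and record.peak_phage > threshold


def frequency_change(record: ReplicateRecord) -> float:
    """Change in resistant frequency after phage exposure: f_after - f_before."""
    if not record.valid:
        raise ValueError("frequency change undefined for a flagged record")
    return record.f_after - record.f_before


def classify_selection(mean_df: float, epsilon: float = 0.02) -> str:
    """Sign of the mean frequency change with a neutrality band |df| < epsilon."""
    if mean_df > epsilon:
        return "POSITIVE"
    if mean_df < -epsilon:
        return "NEGATIVE"
    return "NEUTRAL"


def _replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _cell_config(base: Config, nutrient: float, f0: float, cost: float,
                 interaction: float, removal: float) -> Config:
    strains = tuple(
        replace(s, interaction_rate_I=interaction,
                cost_c=(cost if not s.resistance_mode.value == "susceptible" else s.cost_c))
        for s in base.strains
    )
    return base.with_overrides(
        nutrient=replace(base.nutrient, N_max_mg_per_l=nutrient),
        phage=replace(base.phage, delta_P_per_um2_h=removal),
        sim=replace(base.sim, initial_resistant_fraction=f0),
        strains=strains,
    )


def run_sweep(spec: SweepSpec, base_config: Config | None = None,
              epsilon: float = 0.02) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full sweep; returns (heatmap table, replicate table).

    Seeds derive injectively from (base_seed, cell index, replicate index), so
    the sweep is reproducible and no two runs share a generator stream.
    Individual replicate failures are logged in the replicate table (status
    ``error:...``) and excluded from aggregation, not fatal.
    """
    base = base_config if base_config is not None else desk_config()
    records: list[ReplicateRecord] = []
    heat_rows = []
    for ci, (nut, f0, cost, inter, remv) in enumerate(spec.cells):
        cfg = _cell_config(base, nut, f0, cost, inter, remv)
        kept_dfs = []
        for rep in range(spec.replicates_per_cell):
            seed = _replicate_seed(spec.base_seed, ci, rep)
            try:
                result: RunResult = Simulation(cfg, seed=seed).run()
                rec = ReplicateRecord(
                    nutrient=nut, initial_frequency=f0, cost=cost,
                    interaction=inter, removal=remv, replicate=rep, seed=seed,
                    f_inoculated=result.f_inoculated, f_before=result.f_before,
                    f_after=result.f_after, peak_phage=result.peak_phage,
                    exit_status=result.exit_status.value,
                )
            except Exception as exc:  # noqa: BLE001 -- logged, not fatal
                rec = ReplicateRecord(
                    nutrient=nut, initial_frequency=f0, cost=cost,
                    interaction=inter, removal=remv, replicate=rep, seed=seed,
                    f_inoculated=float("nan"), f_before=float("nan"),
                    f_after=float("nan"), peak_phage=0,
                    exit_status=f"error:{type(exc).__name__}",
                )
            records.append(rec)
            if trim_replicate(rec):
                kept_dfs.append(frequency_change(rec))
        mean_df = float(np.mean(kept_dfs)) if kept_dfs else float("nan")
        heat_rows.append({
            "nutrient": nut, "initial_frequency": f0, "cost": cost,
            "interaction": inter, "removal": remv,
            "mean_df": mean_df, "n_retained": len(kept_dfs),
            "selection": (classify_selection(mean_df, epsilon)
                          if kept_dfs else "UNDEFINED"),
        })

    replicates = pd.DataFrame([{
        **rec.__dict__,
        "delta_f": (frequency_change(rec) if rec.valid else float("nan")),
        "kept": trim_replicate(rec),
    } for rec in records])
    heatmap = pd.DataFrame(heat_rows)
    return heatmap, replicates
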