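"""Parameter containers, unit normalization, and configuration loading.

All quantities are stored in the units of the configuration keys (their names
carry the unit suffix) and exposed in the internal working units -- micrometre,
hour, gram, milligram per litre -- through derived properties.  Every physical
parameter of the model lives here, in one place, so the rest of the package
never performs ad-hoc unit conversions.
"""

from __future__ import annotations

import enum
import pathlib
import tomllib
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "ConfigError",
    "ResistanceMode",
    "SpaceConfig",
    "NutrientParams",
    "BacteriaParams",
    "PhageParams",
    "Strain",
    "PulseParams",
    "SimParams",
    "Config",
    "default_config",
    "desk_config",
    "load_config",
    "config_from_dict",
]

#: unit conversion factors
UM2_PER_H_PER_CM2_PER_S = 1e8 * 3600.0
LITRE_PER_UM3 = 1e-15


class ConfigError(ValueError):
    """Raised for invalid, inconsistent, or unknown configuration input."""


class ResistanceMode(enum.Enum):
    """How a strain responds to phage contact.

    SUSCEPTIBLE        -- phage adsorbs and injects; the cell becomes infected.
    ABORTIVE           -- infection kills both the cell and the phage without
                          producing progeny (abortive infection systems).
    SURFACE            -- receptor loss / surface modification: the phage cannot
                          adsorb productively and both parties stay intact.
    PHAGE_NEUTRALIZING -- the cell sequesters and inactivates the virion
                          (sorptive scavenging) while remaining unharmed.
    """

    SUSCEPTIBLE = "susceptible"
    ABORTIVE = "abortive"
    SURFACE = "surface"
    PHAGE_NEUTRALIZING = "phage_neutralizing"


def _check_multiple(value: float, dl: float, name: str) -> None:
    ratio = value / dl
    if value <= 0 or abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ConfigError(
            f"space.{name} ({value}) must be a positive integer multiple of dl ({dl})"
        )


@dataclass(frozen=True)
class SpaceConfig:
    """Lattice geometry: a 2D (x lateral-periodic, y vertical) or 3D
    (x, z lateral-periodic, y vertical) box of cubic nodes with edge ``dl``."""

    x_max_um: float = 900.0
    y_max_um: float = 150.0
    z_max_um: float | None = None
    dl_um: float = 3.0

    def __post_init__(self) -> None:
        if self.dl_um <= 0:
            raise ConfigError("space.dl_um must be positive")
        _check_multiple(self.x_max_um, self.dl_um, "x_max_um")
        _check_multiple(self.y_max_um, self.dl_um, "y_max_um")
        if self.z_max_um is not None:
            _check_multiple(self.z_max_um, self.dl_um, "z_max_um")

    @property
    def nx(self) -> int:
        return round(self.x_max_um / self.dl_um)

    @property
    def ny(self) -> int:
        return round(self.y_max_um / self.dl_um)

    @property
    def nz(self) -> int | None:
        return None if self.z_max_um is None else round(self.z_max_um / self.dl_um)

    @property
    def dimension(self) -> int:
        return 2 if self.z_max_um is None else 3

    @property
    def shape(self) -> tuple[int, ...]:
        if self.z_max_um is None:
            return (self.nx, self.ny)
        return (self.nx, self.ny, self.nz)  # type: ignore[arg-type]

    @property
    def dimension_constant_a(self) -> int:
        """Dimension constant of the step kernel: 1 in 2D, 4 in 3D."""
        return 1 if self.dimension == 2 else 4

    @property
    def dV_um3(self) -> float:
        """Node volume in um^3 (a dl-sided cube regardless of dimension)."""
        return self.dl_um**3

    @property
    def dV_l(self) -> float:
        """Node volume in litres (a dl-sided cube regardless of dimension)."""
        return self.dV_um3 * LITRE_PER_UM3


@dataclass(frozen=True)
class NutrientParams:
    """Growth substrate: bulk level, transport, and Monod uptake parameters."""

    N_max_mg_per_l: float = 8.0
    D_N_cm2_per_s: float = 2.3e-6
    h_um: float = 15.0
    K_N_mg_per_l: float = 1.18
    Y: float = 0.495
    q_max_g_per_g_day: float = 28.5

    def __post_init__(self) -> None:
        for name in (
            "N_max_mg_per_l",
            "D_N_cm2_per_s",
            "h_um",
            "K_N_mg_per_l",
            "Y",
            "q_max_g_per_g_day",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"nutrient.{name} must be positive")

    @property
    def D_N_um2_per_h(self) -> float:
        return self.D_N_cm2_per_s * UM2_PER_H_PER_CM2_PER_S

    @property
    def q_max_per_h(self) -> float:
        return self.q_max_g_per_g_day / 24.0

    @property
    def mu_max_per_day(self) -> float:
        """Maximum specific growth rate implied by uptake and yield, mu = q*Y."""
        return self.q_max_g_per_g_day * self.Y


@dataclass(frozen=True)
class BacteriaParams:
    m_s_g: float = 1e-12
    mu_s_per_day: float = 14.1
    S_max_g_per_l: float = 200.0
    delta_E_per_m_h: float = 20.0
    founders_per_node: int = 1

    def __post_init__(self) -> None:
        if self.m_s_g <= 0 or self.mu_s_per_day <= 0 or self.S_max_g_per_l <= 0:
            raise ConfigError("bacteria parameters must be positive")
        if self.delta_E_per_m_h < 0:
            raise ConfigError("bacteria.delta_E_per_m_h must be non-negative")
        if self.founders_per_node < 1:
            raise ConfigError("bacteria.founders_per_node must be >= 1")

    @property
    def mu_s_per_h(self) -> float:
        return self.mu_s_per_day / 24.0

    def capacity_g(self, dV_l: float) -> float:
        """Maximum live biomass a node can hold: S_max * dV."""
        return self.S_max_g_per_l * dV_l


@dataclass(frozen=True)
class PhageParams:
    D_P_cm2_per_s: float = 3.82e-7
    delta_P_per_um2_h: float = 5.0
    gamma_per_h: float = 2.92
    tau_min: float = 28.8
    beta: int = 120
    #: contact-time rule for a phage that sorbed after s of n walk steps:
    #: "elapsed" uses dtr = dt*s/n (the walk time spent reaching the contact),
    #: "remaining" uses dt*(n-s)/n (the time left in the iteration).
    dtr_mode: str = "elapsed"
    #: what a sorbed phage does after a contact that did not end in infection:
    #: "stay" keeps it attached (it skips subsequent walks and retries infection
    #: with the full iteration as contact time) until it infects, is consumed,
    #: or its node loses all biomass; "resume" releases it at the start of the
    #: next iteration.  Trapping of virions on resistant cell-cluster surfaces
    #: -- the sequestration that shields rare susceptibles -- requires "stay".
    sorbed_behavior: str = "stay"

    def __post_init__(self) -> None:
        if min(self.D_P_cm2_per_s, self.delta_P_per_um2_h, self.gamma_per_h, self.tau_min) < 0:
            raise ConfigError("phage parameters must be non-negative")
        if not (isinstance(self.beta, int) and self.beta > 0):
            raise ConfigError("phage.beta must be a positive integer")
        if self.dtr_mode not in ("elapsed", "remaining"):
            raise ConfigError("phage.dtr_mode must be 'elapsed' or 'remaining'")
        if self.sorbed_behavior not in ("stay", "resume"):
            raise ConfigError("phage.sorbed_behavior must be 'stay' or 'resume'")

    @property
    def D_P_um2_per_s(self) -> float:
        return self.D_P_cm2_per_s * 1e8

    @property
    def tau_h(self) -> float:
        return self.tau_min / 60.0


@dataclass(frozen=True)
class Strain:
    """One bacterial strain: identity, resistance mechanism, fitness cost ``c``
    (fractional reduction of the maximum growth rate), and the per-biomass
    phage sorption rate ``I`` in (m_s um^3)^-1 s^-1."""

    id: str
    resistance_mode: ResistanceMode = ResistanceMode.SUSCEPTIBLE
    cost_c: float = 0.0
    interaction_rate_I: float = 0.09
    halt_on_contact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cost_c < 1.0:
            raise ConfigError(f"strains.{self.id}.cost_c must lie in [0, 1)")
        if self.interaction_rate_I < 0:
            raise ConfigError(f"strains.{self.id}.interaction_rate_I must be >= 0")


@dataclass(frozen=True)
class PulseParams:
    mode: str = "point"  # "point" | "spray"
    count: int = 120
    height_threshold_um: float = 30.0
    #: number of consecutive iterations over which the pulse repeats once
    #: triggered; -1 pulses on every iteration for the rest of the run.
    duration_iterations: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("point", "spray"):
            raise ConfigError("pulse.mode must be 'point' or 'spray'")
        if self.count < 0:
            raise ConfigError("pulse.count must be >= 0")
        if self.height_threshold_um <= 0:
            raise ConfigError("pulse.height_threshold_um must be positive")
        if self.duration_iterations == 0 or self.duration_iterations < -1:
            raise ConfigError("pulse.duration_iterations must be >= 1 or -1")


@dataclass(frozen=True)
class SimParams:
    dt_min: float = 7.5
    seed: int = 0
    endpoint_days_after_infection: float = 10.0
    #: hard cap on total simulated time (days); None = uncapped.  Needed for
    #: phage-free control runs, which otherwise have no timeout condition.
    max_duration_days: float | None = None
    initial_resistant_fraction: float = 0.5
    #: emit a per-node snapshot every k iterations (0 = never).
    snapshot_every_iterations: int = 0

    def __post_init__(self) -> None:
        if self.dt_min <= 0:
            raise ConfigError("sim.dt_min must be positive")
        if not 0.0 <= self.initial_resistant_fraction <= 1.0:
            raise ConfigError("sim.initial_resistant_fraction must lie in [0, 1]")
        if self.endpoint_days_after_infection <= 0:
            raise ConfigError("sim.endpoint_days_after_infection must be positive")

    @property
    def dt_h(self) -> float:
        return self.dt_min / 60.0

    @property
    def dt_s(self) -> float:
        return self.dt_min * 60.0


@dataclass(frozen=True)
class Config:
    space: SpaceConfig = field(default_factory=SpaceConfig)
    nutrient: NutrientParams = field(default_factory=NutrientParams)
    bacteria: BacteriaParams = field(default_factory=BacteriaParams)
    phage: PhageParams = field(default_factory=PhageParams)
    pulse: PulseParams = field(default_factory=PulseParams)
    sim: SimParams = field(default_factory=SimParams)
    strains: tuple[Strain, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Cross-field consistency checks, applied at load time.

        The uptake/yield/growth-rate identity mu_s = q_max * Y is enforced to
        the printed precision of the parameter table (28.5 * 0.495 = 14.1075,
        quoted as 14.1), i.e. a relative tolerance of 1e-3.
        """
        mu_from_q = self.nutrient.mu_max_per_day
        mu = self.bacteria.mu_s_per_day
        if abs(mu_from_q - mu) > 1e-3 * mu:
            raise ConfigError(
                f"growth-rate inconsistency: q_max*Y = {mu_from_q:.4f}/day but "
                f"bacteria.mu_s_per_day = {mu}/day"
            )
        if not self.strains:
            raise ConfigError("at least one strain must be configured")
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ConfigError("strain ids must be unique")

    def strain(self, strain_id: str) -> Strain:
        for s in self.strains:
            if s.id == strain_id:
                return s
        raise KeyError(strain_id)

    def with_overrides(self, **sections) -> "Config":
        """Return a copy with whole sections or strain tuples replaced."""
        return replace(self, **sections)


def default_config(**overrides) -> Config:
    """Full-scale reference configuration.

    Space 900 x 150 um with 3-um nodes; substrate, growth, erosion, and phage
    parameters at their measured values for E. coli / phage T7; a susceptible
    and a surface-resistant strain (cost 5%, interaction rate 0.09, the middle
    of the measured 0.067-0.12 interval); a single 120-virion point pulse at
    30 um biofilm height; run endpoint 10 days after the pulse.
    """
    cfg = Config(
        strains=(
            Strain(id="susceptible", resistance_mode=ResistanceMode.SUSCEPTIBLE,
                   cost_c=0.0, interaction_rate_I=0.09),
            Strain(id="resistant", resistance_mode=ResistanceMode.SURFACE,
                   cost_c=0.05, interaction_rate_I=0.09),
        ),
    )
    return cfg.with_overrides(**overrides) if overrides else cfg


def desk_config(**overrides) -> Config:
    """Scaled-down configuration for desktop-sized experiments.

    Identical biology and run schedule to :func:`default_config` (including
    the 10-day post-infection endpoint) but on a 300 x 90 um lattice with the
    phage pulse triggered at 20 um biofilm height, which brings a replicate
    within desktop reach while preserving the pulse-to-biofilm geometry.
    """
    base = default_config()
    cfg = base.with_overrides(
        space=SpaceConfig(x_max_um=300.0, y_max_um=90.0, dl_um=3.0),
        pulse=replace(base.pulse, height_threshold_um=20.0),
    )
    return cfg.with_overrides(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# configuration files

_SECTION_KEYS = {
    "space": {"x_max_um", "y_max_um", "z_max_um", "dl_um"},
    "nutrient": {"N_max_mg_per_l", "D_N_cm2_per_s", "h_um", "K_N_mg_per_l",
                 "Y", "q_max_g_per_g_day"},
    "bacteria": {"m_s_g", "mu_s_per_day", "S_max_g_per_l", "delta_E_per_m_h",
                 "founders_per_node"},
    "phage": {"D_P_cm2_per_s", "delta_P_per_um2_h", "gamma_per_h", "tau_min",
              "beta", "dtr_mode", "sorbed_behavior"},
    "pulse": {"mode", "count", "height_threshold_um", "duration_iterations"},
    "sim": {"dt_min", "seed", "endpoint_days_after_infection",
            "max_duration_days", "initial_resistant_fraction",
            "snapshot_every_iterations"},
}
_STRAIN_KEYS = {"resistance_mode", "cost_c", "interaction_rate_I", "halt_on_contact"}
_SECTION_TYPES = {
    "space": SpaceConfig,
    "nutrient": NutrientParams,
    "bacteria": BacteriaParams,
    "phage": PhageParams,
    "pulse": PulseParams,
    "sim": SimParams,
}


def config_from_dict(data: dict) -> Config:
    """Build a :class:`Config` from a nested mapping; unknown keys are errors."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTION_KEYS) - {"strains", "sweep"}
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        raw = data.get(name, {})
        if not isinstance(raw, dict):
            raise ConfigError(f"section '{name}' must be a table")
        bad = set(raw) - _SECTION_KEYS[name]
        if bad:
            raise ConfigError(f"unknown key(s) in section '{name}': {sorted(bad)}")
        sections[name] = cls(**raw)

    strains = []
    for sid, raw in data.get("strains", {}).items():
        if not isinstance(raw, dict):
            raise ConfigError(f"strains.{sid} must be a table")
        bad = set(raw) - _STRAIN_KEYS
        if bad:
            raise ConfigError(f"unknown key(s) in strains.{sid}: {sorted(bad)}")
        raw = dict(raw)
        if "resistance_mode" in raw:
            try:
                raw["resistance_mode"] = ResistanceMode(raw["resistance_mode"])
            except ValueError:
                raise ConfigError(
                    f"strains.{sid}.resistance_mode must be one of "
                    f"{[m.value for m in ResistanceMode]}"
                ) from None
        strains.append(Strain(id=sid, **raw))
    if not strains:
        strains = list(default_config().strains)

    return Config(strains=tuple(strains), **sections)


def load_config(path: str | pathlib.Path) -> Config:
    """Load a TOML (or YAML) configuration file."""
    path = pathlib.Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return config_from_dict(data or {})


def sweep_section(path_or_data) -> dict:
    """Extract the raw ``[sweep]`` table from a config file or mapping."""
    if isinstance(path_or_data, dict):
        return dict(path_or_data.get("sweep", {}))
    path = pathlib.Path(path_or_data)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return dict((data or {}).get("sweep", {}))
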