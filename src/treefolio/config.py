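"""Declarative configuration for the planting-portfolio pipeline.

Every stochastic or economic assumption of the analysis is carried in one of
the dataclasses below, so a run is fully determined by a ``RunConfig`` plus a
master seed.  Configs round-trip losslessly through YAML, which is the
on-disk config format for the analysis scripts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: emissions pathways in ascending order of emissions (RCP-style labels)
PATHWAYS = ("rcp26", "rcp45", "rcp60", "rcp85")
#: climate-model ensemble members
MEMBERS = ("m01", "m02", "m03", "m04")

CONIFER = "conifer"
BROADLEAF = "broadleaf"

#: tCO2e per MtCO2e -- the single unit-conversion constant used everywhere
T_PER_MT = 1_000_000.0


class ConfigError(ValueError):
    """Raised for malformed configuration (e.g. min > max ranges)."""


@dataclass
class GridConfig:
    """Synthetic spatial grid parameters.

    The grid emulates a national planting domain: southern cells (low
    northing) are warmer and drier, northern cells cooler and wetter, and
    agricultural productivity rises with temperature.
    """

    n_cells: int = 60
    extent: float = 100.0               # planar grid units per axis
    temp_south: float = 15.5            # degC mean summer temperature, south edge
    temp_north: float = 10.0            # degC, north edge
    temp_noise_sd: float = 0.4          # degC cell-level noise
    precip_south: float = 650.0         # mm/yr, south edge
    precip_north: float = 1400.0        # mm/yr, north edge
    precip_noise_sd: float = 60.0       # mm/yr
    area_min_ha: float = 50.0           # plantable hectares per cell
    area_max_ha: float = 300.0
    farm_prod_floor: float = 0.2        # farm productivity index clip range
    farm_prod_ceiling: float = 1.0
    farm_prod_slope: float = 0.8        # per unit of normalised temperature
    farm_prod_intercept: float = 0.15
    farm_prod_noise_sd: float = 0.08

    def validate(self) -> None:
        if self.n_cells < 2:
            raise ConfigError("n_cells must be >= 2")
        if self.temp_south < self.temp_north:
            raise ConfigError("temp_south must be >= temp_north (south is warmer)")
        if self.area_min_ha > self.area_max_ha or self.area_min_ha <= 0:
            raise ConfigError("malformed plantable-area range")
        if self.precip_south > self.precip_north:
            raise ConfigError("precip_south must be <= precip_north (north is wetter)")
        if self.farm_prod_floor > self.farm_prod_ceiling:
            raise ConfigError("malformed farm productivity range")


@dataclass
class SpeciesConfig:
    """Growth and silvicultural parameters of one representative species."""

    name: str = CONIFER
    temp_opt: float = 9.5               # degC optimum of the bell response
    temp_tol: float = 3.0               # degC tolerance (bell width)
    precip_sens: float = 0.0004         # per mm deviation from precip_ref
    precip_ref: float = 900.0           # mm/yr reference precipitation
    peak_storage: float = 13.0          # tCO2e/ha/yr at maturity under ideal climate
    yield_coef: float = 10.0            # m3/ha/yr of merchantable volume per unit response
    maturity_years: int = 15            # years to reach the mature storage rate
    rotation_grid: tuple = tuple(range(20, 85, 5))
    planting_cost_per_ha: float = 2500.0  # GBP/ha incurred in year 1

    def validate(self) -> None:
        grid = tuple(self.rotation_grid)
        if not grid:
            raise ConfigError("rotation_grid must be non-empty")
        if any(t < 1 for t in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("rotation_grid must be strictly increasing, all >= 1")


def default_species() -> list[SpeciesConfig]:
    """The two-species set: a fast conifer and a slow broadleaf.

    The conifer (Sitka-spruce-like) prefers cool, wet sites and carries the
    higher peak storage and timber yield; the broadleaf (oak-like) prefers
    warm, drier sites, grows slowly and is harvested on long rotations.
    """
    conifer = SpeciesConfig()
    broadleaf = SpeciesConfig(
        name=BROADLEAF,
        temp_opt=13.5,
        temp_tol=4.0,
        precip_sens=0.0002,
        precip_ref=800.0,
        peak_storage=7.0,
        yield_coef=6.0,
        maturity_years=25,
        rotation_grid=tuple(range(40, 130, 10)),
        planting_cost_per_ha=3000.0,
    )
    return [conifer, broadleaf]


@dataclass
class CERConfig:
    """Parameters of the climate-economy realization (CER) generator.

    A CER is one internally consistent joint draw of: emissions pathway,
    climate-model member, a temperature-damage coefficient, the implied
    social-cost-of-carbon (SCC) path, timber and farm price paths, national
    climate anomaly paths with a north-south gradient, and a latent global
    shock common to all site returns.
    """

    pathways: tuple = PATHWAYS
    members: tuple = MEMBERS
    t_max: int = 150                    # years simulated; >= max rotation + horizon
    scc0: float = 40.0                  # GBP/tCO2e in year 1
    #: pathway-specific baseline SCC growth rates (per year, ascending emissions)
    scc_growth: tuple = (0.005, 0.010, 0.015, 0.020)
    damage_kappa: float = 0.01          # SCC growth added per unit damage draw
    damage_lognorm_mu: float = -0.125   # lognormal damage draw, mean ~= 1
    damage_lognorm_sd: float = 0.5
    #: pathway warming rates, degC per year of national summer-mean anomaly
    warm_rate: tuple = (0.012, 0.022, 0.030, 0.045)
    #: pathway drying rates, mm per year of annual-precipitation anomaly
    dry_rate: tuple = (0.3, 0.8, 1.3, 2.0)
    anomaly_plateau_year: int = 80      # anomalies grow linearly then level off
    member_scale: tuple = (0.8, 0.95, 1.05, 1.2)  # ensemble-member multiplier
    gradient_mean: float = 0.3          # N-S anomaly gradient coefficient
    gradient_sd: float = 0.1
    timber_price0: float = 40.0         # GBP/m3
    timber_drift: float = 0.002
    timber_sd: float = 0.03
    #: pathway drift of the farm price index (food prices rise with emissions)
    farm_drift: tuple = (0.000, 0.002, 0.004, 0.006)
    farm_sd: float = 0.04
    global_shock_sd: float = 0.2        # lognormal, mean 1
    farm_profit_per_ha: float = 900.0   # GBP/ha/yr at productivity 1, index 1
    soil_carbon_loss: float = 4.0       # tCO2e/ha/yr emitted in disturbance years
    soil_disturbance_years: int = 5
    timber_quality_sd: float = 0.1      # lognormal site-quality noise on volume

    def validate(self) -> None:
        if len(self.pathways) != 4 or len(self.members) != 4:
            raise ConfigError("exactly 4 pathways and 4 ensemble members required")
        for name in ("scc_growth", "warm_rate", "dry_rate", "farm_drift"):
            if len(getattr(self, name)) != len(self.pathways):
                raise ConfigError(f"{name} must have one entry per pathway")
        if len(self.member_scale) != len(self.members):
            raise ConfigError("member_scale must have one entry per member")
        if self.scc0 <= 0:
            raise ConfigError("scc0 must be positive")
        if min(self.scc_growth) < 0 or self.damage_kappa < 0:
            raise ConfigError("SCC growth components must be non-negative")


@dataclass
class ValuationConfig:
    rho: float = 0.035                  # annual discount rate
    horizon: int = 30                   # planning horizon, years

    def validate(self) -> None:
        if self.rho < 0:
            raise ConfigError("rho must be >= 0")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")


@dataclass
class OptimizationSpec:
    """One optimization problem statement.

    objective    : 'scenario_value' | 'expected_value' | 'cvar'
    target_q     : sequestration target, MtCO2e/yr (ensemble-mean constraint)
    beta         : CVaR tail parameter in (0, 1); worst (1-beta) share is the tail
    gamma        : alternative-technology cost, GBP per tCO2e/yr; None disables z
    value_form   : 'V_full' (NPV incl. carbon value) | 'V_prime' (cost lens)
    relaxation   : 'binary' | 'continuous'
    """

    objective: str = "expected_value"
    target_q: float = 0.0
    beta: float = 0.9
    gamma: Optional[float] = None
    value_form: str = "V_full"
    relaxation: str = "binary"
    mip_gap: float = 1e-6
    tie_eps: float = 1e-9
    z_max: Optional[float] = None       # MtCO2e/yr; defaults to target_q

    def validate(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ConfigError("beta must lie in (0, 1)")
        if self.target_q < 0:
            raise ConfigError("target_q must be >= 0")
        if self.objective not in ("scenario_value", "expected_value", "cvar"):
            raise ConfigError(f"unknown objective {self.objective!r}")
        if self.value_form not in ("V_full", "V_prime"):
            raise ConfigError(f"unknown value_form {self.value_form!r}")
        if self.relaxation not in ("binary", "continuous"):
            raise ConfigError(f"unknown relaxation {self.relaxation!r}")

    @property
    def z_enabled(self) -> bool:
        return self.gamma is not None

    @property
    def z_upper(self) -> float:
        if not self.z_enabled:
            return 0.0
        return self.target_q if self.z_max is None else self.z_max


@dataclass
class RunConfig:
    """Full pipeline configuration: one seeded end-to-end run."""

    seed: int = 20
    n_cer: int = 40
    grid: GridConfig = field(default_factory=GridConfig)
    cer: CERConfig = field(default_factory=CERConfig)
    species: list = field(default_factory=default_species)
    valuation: ValuationConfig = field(default_factory=ValuationConfig)
    target_q: float = 0.04              # MtCO2e/yr, desk scale
    beta: float = 0.9
    gamma_grid: tuple = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0)
    loss_threshold: float = 1.0e7       # GBP, "losses exceeding" reporting threshold
    sweep_value_form: str = "V_prime"   # cost lens for the technology sweep
    headline_value_form: str = "V_full"
    write_growth_tables: bool = False   # long per-year growth files are large

    def validate(self) -> None:
        self.grid.validate()
        self.cer.validate()
        self.valuation.validate()
        for sp in self.species:
            sp.validate()
        if self.n_cer < 1:
            raise ConfigError("n_cer must be >= 1")
        if len(self.species) != 2:
            raise ConfigError("exactly two species are analysed (J = 2)")
        if list(self.gamma_grid) != sorted(self.gamma_grid):
            raise ConfigError("gamma_grid must be ascending")
        max_rotation = max(max(sp.rotation_grid) for sp in self.species)
        if self.cer.t_max < max_rotation + self.valuation.horizon:
            raise ConfigError(
                "CER horizon t_max must cover the longest rotation plus the "
                f"planning horizon ({max_rotation} + {self.valuation.horizon})"
            )


# ---------------------------------------------------------------------------
# YAML round-trip

_SECTION_TYPES = {
    "grid": GridConfig,
    "cer": CERConfig,
    "valuation": ValuationConfig,
}


def _plain(obj):
    """dataclass -> YAML-safe nested structure (tuples become lists)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def to_dict(config: RunConfig) -> dict:
    return _plain(config)


def run_config_to_yaml(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=True)


def _coerce(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list) and f.name != "species":
            # dataclass defaults use tuples for immutable sequences
            default = getattr(cls(), f.name) if f.default is dataclasses.MISSING else f.default
            if isinstance(default, tuple):
                value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    for key, cls in _SECTION_TYPES.items():
        if key in data and isinstance(data[key], dict):
            data[key] = _coerce(cls, data[key])
    if "species" in data:
        data["species"] = [
            sp if isinstance(sp, SpeciesConfig) else _coerce(SpeciesConfig, sp)
            for sp in data["species"]
        ]
    cfg = _coerce(RunConfig, data)
    cfg.validate()
    return cfg


def run_config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def demo_config() -> RunConfig:
    """The packaged demonstration scenario: 60 cells, 40 CERs."""
    cfg = RunConfig()
    cfg.validate()
    return cfg


def costly_planting_config() -> RunConfig:
    """Demo-sized variant in which planting is a net cost everywhere.

    Foregone farm profits are raised so that no cell-species pair has
    positive expected non-carbon value; trees then enter a least-cost
    portfolio only to meet the sequestration constraint.  Used for the
    technology-sweep boundary demonstrations.
    """
    cfg = RunConfig()
    cfg.cer = dataclasses.replace(cfg.cer, farm_profit_per_ha=1200.0)
    cfg.validate()
    return cfg
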