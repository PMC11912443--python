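"""Synthetic spatial grid and climate-economy realization (CER) ensemble.

This module stands in for the integrated environment-economy data a national
analysis would use.  It generates:

* a planar grid of candidate planting cells with a north-south climate
  gradient and temperature-correlated agricultural productivity;
* an ensemble of CERs -- joint draws of emissions pathway, climate-model
  member, a temperature-damage coefficient (which drives the SCC path),
  timber/farm price paths, national climate-anomaly paths, and a latent
  global shock common to all site returns;
* per cell x species growth realizations: yearly net carbon storage from a
  bell-shaped temperature response, timber cash flows (planting cost in year
  1, harvest revenue at rotation end) and foregone farm profits.

All randomness flows from explicit integer seeds; per-CER substreams are
keyed by ``cer_id`` so an ensemble can be extended without changing earlier
draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CERConfig, ConfigError, GridConfig, SpeciesConfig, default_species

GRID_COLUMNS = [
    "cell_id", "easting", "northing", "area_ha",
    "base_temp", "base_precip", "farm_productivity",
]

_QUALITY_STREAM = 104729  # fixed sub-stream tag for site timber quality


# ---------------------------------------------------------------------------
# grid

def generate_grid(n_cells: int, seed: int, config: GridConfig | None = None) -> pd.DataFrame:
    """Generate ``n_cells`` candidate planting cells.

    Returns a DataFrame with columns ``GRID_COLUMNS``.  Southern cells (low
    northing) are warmer and drier; farm productivity increases with
    temperature, so the best agricultural land sits in the warm south.
    """
    config = config or GridConfig()
    config = dataclasses.replace(config, n_cells=int(n_cells))
    config.validate()
    rng = np.random.default_rng([int(seed), 0])

    easting = rng.uniform(0.0, config.extent, n_cells)
    northing = rng.uniform(0.0, config.extent, n_cells)
    lat = northing / config.extent  # 0 = south, 1 = north

    base_temp = (
        config.temp_south + (config.temp_north - config.temp_south) * lat
        + rng.normal(0.0, config.temp_noise_sd, n_cells)
    )
    base_temp = np.clip(base_temp, config.temp_north - 2.0, config.temp_south + 2.0)
    base_precip = (
        config.precip_south + (config.precip_north - config.precip_south) * lat
        + rng.normal(0.0, config.precip_noise_sd, n_cells)
    )
    base_precip = np.maximum(base_precip, 0.0)

    t_norm = (base_temp - config.temp_north) / max(config.temp_south - config.temp_north, 1e-9)
    farm_productivity = np.clip(
        config.farm_prod_intercept
        + config.farm_prod_slope * t_norm
        + rng.normal(0.0, config.farm_prod_noise_sd, n_cells),
        config.farm_prod_floor,
        config.farm_prod_ceiling,
    )
    area_ha = rng.uniform(config.area_min_ha, config.area_max_ha, n_cells)

    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1, dtype=np.int64),
            "easting": easting,
            "northing": northing,
            "area_ha": area_ha,
            "base_temp": base_temp,
            "base_precip": base_precip,
            "farm_productivity": farm_productivity,
        }
    )


# ---------------------------------------------------------------------------
# CER

@dataclass
class CER:
    """One climate-economy realization (years are indexed t = 1..t_max)."""

    cer_id: int
    pathway: str
    ensemble_member: str
    damage_coeff: float
    global_shock: float
    gradient: float                      # north-south anomaly gradient coefficient
    scc_path: np.ndarray                 # GBP/tCO2e, shape (t_max,)
    timber_price_path: np.ndarray        # GBP/m3
    farm_price_index_path: np.ndarray    # dimensionless
    temp_anomaly_path: np.ndarray        # degC national mean-summer anomaly
    precip_anomaly_path: np.ndarray      # mm/yr anomaly (negative = drier)

    @property
    def t_max(self) -> int:
        return len(self.scc_path)


def scc_baseline(config: CERConfig, pathway: str) -> np.ndarray:
    """Zero-damage SCC path for one pathway: SCC0 * (1 + g_path)^t."""
    k = list(config.pathways).index(pathway)
    t = np.arange(1, config.t_max + 1)
    return config.scc0 * (1.0 + config.scc_growth[k]) ** t


def draw_cer(cer_id: int, seed: int, config: CERConfig | None = None) -> CER:
    """Draw one CER.  Deterministic given ``(cer_id, seed, config)``.

    The pathway and ensemble member are uniform and independent; the SCC path
    grows at the pathway base rate plus ``damage_kappa * damage_coeff``, so
    higher-emissions pathways and larger damage draws both raise the SCC.
    """
    config = config or CERConfig()
    config.validate()
    rng = np.random.default_rng([int(seed), int(cer_id)])

    k_path = int(rng.integers(len(config.pathways)))
    k_member = int(rng.integers(len(config.members)))
    damage = float(np.exp(rng.normal(config.damage_lognorm_mu, config.damage_lognorm_sd)))
    gradient = float(rng.normal(config.gradient_mean, config.gradient_sd))
    shock = float(np.exp(rng.normal(-0.5 * config.global_shock_sd**2, config.global_shock_sd)))

    t = np.arange(1, config.t_max + 1)
    growth = config.scc_growth[k_path] + config.damage_kappa * damage
    scc = config.scc0 * (1.0 + growth) ** t

    ramp = np.minimum(t, config.anomaly_plateau_year).astype(float)
    m = config.member_scale[k_member]
    temp_anom = config.warm_rate[k_path] * m * ramp
    precip_anom = -config.dry_rate[k_path] * m * ramp

    timber_steps = rng.normal(
        config.timber_drift - 0.5 * config.timber_sd**2, config.timber_sd, config.t_max
    )
    timber_price = config.timber_price0 * np.exp(np.cumsum(timber_steps))
    farm_steps = rng.normal(
        config.farm_drift[k_path] - 0.5 * config.farm_sd**2, config.farm_sd, config.t_max
    )
    farm_index = np.exp(np.cumsum(farm_steps))

    return CER(
        cer_id=int(cer_id),
        pathway=config.pathways[k_path],
        ensemble_member=config.members[k_member],
        damage_coeff=damage,
        global_shock=shock,
        gradient=gradient,
        scc_path=scc,
        timber_price_path=timber_price,
        farm_price_index_path=farm_index,
        temp_anomaly_path=temp_anom,
        precip_anomaly_path=precip_anom,
    )


# ---------------------------------------------------------------------------
# growth realizations

@dataclass
class GrowthRealization:
    """Per cell x species outcomes under one CER.

    ``g`` holds the yearly net carbon storage of the whole cell over the full
    simulated horizon; rotation-dependent quantities are carried as families
    over each species' admissible rotation grid, so the valuation layer can
    choose the timber-optimal rotation afterwards.
    """

    cer_id: int
    species_names: list                  # length J
    rotation_grids: list                 # length J, each an int array of candidates
    g: np.ndarray                        # (N, J, t_max) tCO2e net storage per cell-year
    harvest_revenue: list                # length J, each (N, K_j) GBP at rotation end
    planting_cost: np.ndarray            # (N, J) GBP incurred in year 1
    farm_profit: np.ndarray              # (N, horizon_max) GBP/yr foregone farm profits

    @property
    def n_cells(self) -> int:
        return self.g.shape[0]


def _response(grid: pd.DataFrame, species: SpeciesConfig, cer: CER) -> np.ndarray:
    """Bell-shaped climate response in [0, ~1.5], shape (N, t_max)."""
    lat = (grid["northing"].to_numpy() / max(grid["northing"].max(), 1e-9))[:, None]
    south_weight = 1.0 + cer.gradient * (0.5 - lat)   # south warms/dries more
    eff_temp = grid["base_temp"].to_numpy()[:, None] + cer.temp_anomaly_path[None, :] * south_weight
    eff_precip = np.maximum(
        grid["base_precip"].to_numpy()[:, None] + cer.precip_anomaly_path[None, :] * south_weight,
        0.0,
    )
    bell = np.exp(-0.5 * ((eff_temp - species.temp_opt) / species.temp_tol) ** 2)
    wet = np.clip(1.0 + species.precip_sens * (eff_precip - species.precip_ref), 0.0, 1.5)
    return bell * wet


def simulate_growth(
    grid: pd.DataFrame,
    species: list[SpeciesConfig],
    cer: CER,
    seed: int,
    config: CERConfig | None = None,
    horizon: int = 30,
) -> GrowthRealization:
    """Simulate carbon, timber and farm outcomes for every cell and species.

    Net storage is ``area * (peak * response * maturity - soil pulse)``: young
    stands store little, soil disturbance emits carbon in the first years, and
    poorly matched sites can be net emitters.  Timber volume accumulates with
    the mean response over the rotation; all monetary flows scale with the
    CER's global shock.
    """
    config = config or CERConfig()
    max_rot = max(max(sp.rotation_grid) for sp in species)
    if cer.t_max < max_rot + horizon:
        raise ValueError(
            f"CER horizon {cer.t_max} shorter than longest rotation {max_rot} "
            f"plus planning horizon {horizon}"
        )
    n = len(grid)
    j_count = len(species)
    t = np.arange(1, cer.t_max + 1)
    area = grid["area_ha"].to_numpy()

    quality_rng = np.random.default_rng([int(seed), _QUALITY_STREAM])
    quality = np.exp(
        quality_rng.normal(-0.5 * config.timber_quality_sd**2, config.timber_quality_sd, (n, j_count))
    )

    g = np.empty((n, j_count, cer.t_max))
    harvest_revenue = []
    planting_cost = np.empty((n, j_count))
    for j, sp in enumerate(species):
        resp = _response(grid, sp, cer)                     # (N, t_max)
        maturity = np.minimum(t / sp.maturity_years, 1.0)   # (t_max,)
        soil = np.where(t <= config.soil_disturbance_years, config.soil_carbon_loss, 0.0)
        g[:, j, :] = area[:, None] * (sp.peak_storage * resp * maturity[None, :] - soil[None, :])

        rot = np.asarray(sp.rotation_grid, dtype=int)
        mean_resp = np.cumsum(resp, axis=1)[:, rot - 1] / rot[None, :]
        volume_per_ha = sp.yield_coef * mean_resp * rot[None, :] * quality[:, j][:, None]
        price_at_harvest = cer.timber_price_path[rot - 1]
        harvest_revenue.append(
            volume_per_ha * price_at_harvest[None, :] * area[:, None] * cer.global_shock
        )
        planting_cost[:, j] = sp.planting_cost_per_ha * area * cer.global_shock

    farm = (
        config.farm_profit_per_ha
        * grid["farm_productivity"].to_numpy()[:, None]
        * area[:, None]
        * cer.farm_price_index_path[None, :horizon]
        * cer.global_shock
    )

    return GrowthRealization(
        cer_id=cer.cer_id,
        species_names=[sp.name for sp in species],
        rotation_grids=[np.asarray(sp.rotation_grid, dtype=int) for sp in species],
        g=g,
        harvest_revenue=harvest_revenue,
        planting_cost=planting_cost,
        farm_profit=farm,
    )


# ---------------------------------------------------------------------------
# ensemble

def generate_ensemble(
    grid: pd.DataFrame,
    S: int,
    seed: int,
    config: CERConfig | None = None,
    species: list[SpeciesConfig] | None = None,
    horizon: int = 30,
) -> tuple[list[CER], list[GrowthRealization], np.ndarray]:
    """Draw ``S`` independent CERs and their growth realizations.

    Returns ``(cers, growths, probs)`` with equal scenario probabilities
    ``probs = 1/S``.
    """
    if S < 1:
        raise ConfigError("ensemble size S must be >= 1")
    config = config or CERConfig()
    species = species or default_species()
    cers = [draw_cer(cer_id, seed, config) for cer_id in range(1, S + 1)]
    growths = [simulate_growth(grid, species, cer, seed, config, horizon) for cer in cers]
    probs = np.full(S, 1.0 / S)
    return cers, growths, probs


# ---------------------------------------------------------------------------
# delimited-text I/O

_FLOAT_FMT = "%.12g"


def write_grid(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_grid(path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    missing = set(GRID_COLUMNS) - set(grid.columns)
    if missing:
        raise ValueError(f"grid file missing columns: {sorted(missing)}")
    return grid


def cer_table(cers: list[CER]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cer_id": [c.cer_id for c in cers],
            "pathway": [c.pathway for c in cers],
            "member": [c.ensemble_member for c in cers],
            "damage_coeff": [c.damage_coeff for c in cers],
            "global_shock": [c.global_shock for c in cers],
            "gradient": [c.gradient for c in cers],
        }
    )


def path_table(cers: list[CER]) -> pd.DataFrame:
    """Long-format (cer_id, year, variable, value) table of all CER paths."""
    frames = []
    variables = {
        "scc": "scc_path",
        "timber_price": "timber_price_path",
        "farm_price_index": "farm_price_index_path",
        "temp_anomaly": "temp_anomaly_path",
        "precip_anomaly": "precip_anomaly_path",
    }
    for cer in cers:
        years = np.arange(1, cer.t_max + 1)
        for var, attr in variables.items():
            frames.append(
                pd.DataFrame(
                    {"cer_id": cer.cer_id, "year": years, "variable": var,
                     "value": getattr(cer, attr)}
                )
            )
    return pd.concat(frames, ignore_index=True)


def growth_table(
    growth: GrowthRealization,
    grid: pd.DataFrame,
    rotations: np.ndarray,
    horizon: int = 30,
) -> pd.DataFrame:
    """Long (cer_id, cell_id, species, year, g, b, c, farm) table.

    ``rotations`` has shape (N, J) and gives the realized rotation per pair;
    rows run to each pair's rotation (farm profits stop at the horizon).
    """
    records = []
    cell_ids = grid["cell_id"].to_numpy()
    for j, name in enumerate(growth.species_names):
        rot_grid = growth.rotation_grids[j]
        for i, cell in enumerate(cell_ids):
            T = int(rotations[i, j])
            k = int(np.searchsorted(rot_grid, T))
            years = np.arange(1, T + 1)
            b = np.zeros(T)
            b[-1] = growth.harvest_revenue[j][i, k]
            c = np.zeros(T)
            c[0] = growth.planting_cost[i, j]
            farm = np.zeros(T)
            n_farm = min(T, horizon, growth.farm_profit.shape[1])
            farm[:n_farm] = growth.farm_profit[i, :n_farm]
            records.append(
                pd.DataFrame(
                    {"cer_id": growth.cer_id, "cell_id": cell, "species": name,
                     "year": years, "g": growth.g[i, j, :T], "b": b, "c": c,
                     "farm": farm}
                )
            )
    return pd.concat(records, ignore_index=True)


def write_ensemble(cers: list[CER], outdir, prefix: str = "ensemble") -> dict:
    """Write the CER parameter table and long path table; returns file paths."""
    import os

    params_path = os.path.join(outdir, f"{prefix}_cers.csv")
    paths_path = os.path.join(outdir, f"{prefix}_paths.csv")
    cer_table(cers).to_csv(params_path, index=False, float_format=_FLOAT_FMT)
    path_table(cers).to_csv(paths_path, index=False, float_format=_FLOAT_FMT)
    return {"cers": params_path, "paths": paths_path}
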