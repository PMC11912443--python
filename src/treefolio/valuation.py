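"""Decision quantities for planting: storage rates, annualized flows, NPV.

For each (cell i, species j, realization s) the analysis needs:

* ``m_ijs``   -- mean annual net carbon storage over one rotation (tCO2e/yr),
* ``r^T_ijs`` -- timber cash flows annualized over the rotation (GBP/yr),
* ``r^C_ijs`` -- carbon-sequestration value annualized likewise (GBP/yr),
* ``R_ijs``   -- the 30-year NPV of planting: annualized timber + carbon
  flows net of foregone farm profits, discounted at rate rho.

Rotations are chosen per (i, j, s) to maximize annualized timber value over
the species' admissible rotation grid (ties break to the shortest).  Pairs
whose ensemble-mean storage is non-positive (net emitters, e.g. through soil
carbon disturbance) are excluded from the candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CER, GrowthRealization

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# scalar building blocks

def mean_annual_storage(g_path, T: int) -> float:
    """(1/T) * sum_{t=1..T} g_t -- mean yearly net storage over a rotation."""
    g = np.asarray(g_path, dtype=float)
    if T < 1:
        raise ValueError("rotation T must be >= 1")
    if len(g) < T:
        raise ValueError(f"rotation T={T} exceeds path length {len(g)}")
    return float(np.mean(g[:T]))


def annuity_factor(rho: float, T: int) -> float:
    """rho / (1 - (1+rho)^-T); the zero-rate limit is 1/T.

    Multiplying a discounted cash-flow sum by this factor converts it into
    the equivalent constant annual flow over T years.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0.0:
        return 1.0 / T
    # -expm1(-T*log1p(rho)) = 1-(1+rho)^-T, stable down to subnormal rates
    return rho / -np.expm1(-T * np.log1p(rho))


def _discounted_sum(flows: np.ndarray, rho: float, T: int) -> float:
    t = np.arange(1, T + 1)
    return float(np.sum(flows[:T] / (1.0 + rho) ** t))


def annualized_timber(b_path, c_path, rho: float, T: int) -> float:
    """Annualized net timber value: discounted (b - c) times the annuity factor."""
    b = np.asarray(b_path, dtype=float)
    c = np.asarray(c_path, dtype=float)
    if len(b) != len(c):
        raise ValueError("timber revenue and cost paths must have equal length")
    if len(b) < T:
        raise ValueError(f"T={T} exceeds path length {len(b)}")
    return _discounted_sum(b - c, rho, T) * annuity_factor(rho, T)


def annualized_carbon(g_path, scc_path, rho: float, T: int) -> float:
    """Annualized carbon value: discounted g_t * SCC_t times the annuity factor."""
    g = np.asarray(g_path, dtype=float)
    scc = np.asarray(scc_path, dtype=float)
    if len(g) < T or len(scc) < T:
        raise ValueError(f"T={T} exceeds a path length ({len(g)}, {len(scc)})")
    return _discounted_sum(g[:T] * scc[:T], rho, T) * annuity_factor(rho, T)


def optimal_rotation(b_path_family, c_path_family, rho: float, rotation_grid) -> int:
    """Rotation in ``rotation_grid`` maximizing annualized timber value.

    ``b_path_family(T)`` / ``c_path_family(T)`` return the cash-flow paths for
    candidate rotation T.  Ties break to the smallest rotation.
    """
    grid = list(rotation_grid)
    if not grid:
        raise ValueError("rotation_grid must be non-empty")
    best_T, best_val = None, -np.inf
    for T in grid:
        val = annualized_timber(b_path_family(T), c_path_family(T), rho, T)
        if val > best_val:  # strict: first (smallest) T wins ties
            best_T, best_val = T, val
    return int(best_T)


def npv_planting(r_timber: float, r_co2: float, farm_path, rho: float, horizon: int) -> float:
    """30-year NPV of planting: sum_t (r_timber + r_co2 - farm_t) / (1+rho)^t."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    farm = np.asarray(farm_path, dtype=float)
    if len(farm) < horizon:
        raise ValueError(f"farm path shorter than horizon {horizon}")
    net = r_timber + r_co2 - farm[:horizon]
    return _discounted_sum(net, rho, horizon)


# ---------------------------------------------------------------------------
# assembled tables

@dataclass
class ValuationTables:
    """Dense (N, J, S) decision tables plus the quantities the optimizer needs.

    Excluded (net-emitting) pairs are masked out via ``retained`` and their
    entries zeroed, so sums over planted pairs are safe.  ``scc_disc`` and
    ``annuity_horizon`` support the value of the alternative technology and
    the cost lens V'.
    """

    cell_ids: np.ndarray                 # (N,)
    species_names: list                  # length J
    cer_ids: np.ndarray                  # (S,)
    area_ha: np.ndarray                  # (N,)
    m: np.ndarray                        # (N, J, S) tCO2e/yr
    rotation: np.ndarray                 # (N, J, S) years
    r_timber: np.ndarray                 # (N, J, S) GBP/yr
    r_co2: np.ndarray                    # (N, J, S) GBP/yr
    R: np.ndarray                        # (N, J, S) GBP (horizon NPV)
    farm_npv: np.ndarray                 # (N, J, S) GBP (discounted foregone farm)
    retained: np.ndarray                 # (N, J) bool
    scc_disc: np.ndarray                 # (S,) sum_t SCC_st/(1+rho)^t over horizon
    probs: np.ndarray                    # (S,)
    rho: float = 0.035
    horizon: int = 30

    def __post_init__(self):
        n, j, s = self.m.shape
        for name in ("rotation", "r_timber", "r_co2", "R", "farm_npv"):
            if getattr(self, name).shape != (n, j, s):
                raise ValueError(f"{name} shape mismatch: expected {(n, j, s)}")
        if self.retained.shape != (n, j):
            raise ValueError("retained mask shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.m.shape

    @property
    def n_cells(self) -> int:
        return self.m.shape[0]

    @property
    def n_cer(self) -> int:
        return self.m.shape[2]

    @property
    def annuity_horizon(self) -> float:
        """sum_{t=1..horizon} (1+rho)^-t (PV of a unit annual flow)."""
        t = np.arange(1, self.horizon + 1)
        return float(np.sum((1.0 + self.rho) ** (-t)))

    @property
    def mean_m(self) -> np.ndarray:
        """Ensemble-mean storage per pair, zero where excluded; (N, J)."""
        return np.where(self.retained, self.m.mean(axis=2), 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long table (cell_id, species, cer_id, T, m, r_timber, r_co2, R, farm_npv)."""
        n, j_count, s_count = self.shape
        rows = []
        for j, name in enumerate(self.species_names):
            for i in range(n):
                if not self.retained[i, j]:
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": self.cell_ids[i],
                            "species": name,
                            "cer_id": self.cer_ids,
                            "T": self.rotation[i, j, :].astype(int),
                            "m": self.m[i, j, :],
                            "r_timber": self.r_timber[i, j, :],
                            "r_co2": self.r_co2[i, j, :],
                            "R": self.R[i, j, :],
                            "farm_npv": self.farm_npv[i, j, :],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def assemble_valuation(
    growths: list[GrowthRealization],
    cers: list[CER],
    grid: pd.DataFrame,
    rho: float = 0.035,
    horizon: int = 30,
    probs: np.ndarray | None = None,
) -> ValuationTables:
    """Build the full (N, J, S) decision tables from an ensemble.

    For every pair and realization the timber-optimal rotation is selected
    over the species rotation grid, then m, annualized flows and the horizon
    NPV are computed.  Pairs with non-positive ensemble-mean storage are
    dropped (logged) per the net-emissions exclusion rule.
    """
    if len(growths) != len(cers) or not growths:
        raise ValueError("growths and cers must be equal-length, non-empty")
    s_count = len(growths)
    n = growths[0].n_cells
    j_count = len(growths[0].species_names)
    if len(grid) != n:
        raise ValueError("grid does not match growth realizations")
    probs = np.full(s_count, 1.0 / s_count) if probs is None else np.asarray(probs)

    m = np.zeros((n, j_count, s_count))
    rotation = np.zeros((n, j_count, s_count))
    r_timber = np.zeros((n, j_count, s_count))
    r_co2 = np.zeros((n, j_count, s_count))
    farm_npv = np.zeros((n, j_count, s_count))

    disc_h = (1.0 + rho) ** (-np.arange(1, horizon + 1))
    scc_disc = np.array([float(np.sum(c.scc_path[:horizon] * disc_h)) for c in cers])

    for s, (growth, cer) in enumerate(zip(growths, cers)):
        t_max = growth.g.shape[2]
        disc_full = (1.0 + rho) ** (-np.arange(1, t_max + 1))
        for j in range(j_count):
            rot = growth.rotation_grids[j]
            af = np.array([annuity_factor(rho, int(T)) for T in rot])      # (K,)
            # annualized timber for every candidate rotation, (N, K)
            ann_t = (
                growth.harvest_revenue[j] * disc_full[rot - 1][None, :]
                - growth.planting_cost[:, j][:, None] * disc_full[0]
            ) * af[None, :]
            best = np.argmax(ann_t, axis=1)                                # first max wins
            T_star = rot[best]
            rotation[:, j, s] = T_star
            r_timber[:, j, s] = ann_t[np.arange(n), best]

            g = growth.g[:, j, :]                                          # (N, t_max)
            g_cum = np.cumsum(g, axis=1)
            m[:, j, s] = g_cum[np.arange(n), T_star - 1] / T_star
            gscc_cum = np.cumsum(g * (cer.scc_path * disc_full)[None, :], axis=1)
            r_co2[:, j, s] = gscc_cum[np.arange(n), T_star - 1] * af[best]

            farm_npv[:, j, s] = growth.farm_profit[:, :horizon] @ disc_h

    annuity_h = float(np.sum(disc_h))
    R = (r_timber + r_co2) * annuity_h - farm_npv

    mean_m = (m * probs[None, None, :]).sum(axis=2)
    retained = mean_m > 0.0
    dropped = np.argwhere(~retained)
    if len(dropped):
        names = growths[0].species_names
        pairs = [(int(grid['cell_id'].iloc[i]), names[j]) for i, j in dropped]
        logger.info("excluded %d net-emitting cell-species pairs: %s",
                    len(pairs), pairs[:20])
    for arr in (m, rotation, r_timber, r_co2, R, farm_npv):
        arr[~retained, :] = 0.0

    return ValuationTables(
        cell_ids=grid["cell_id"].to_numpy(),
        species_names=list(growths[0].species_names),
        cer_ids=np.array([c.cer_id for c in cers]),
        area_ha=grid["area_ha"].to_numpy(),
        m=m,
        rotation=rotation,
        r_timber=r_timber,
        r_co2=r_co2,
        R=R,
        farm_npv=farm_npv,
        retained=retained,
        scc_disc=scc_disc,
        probs=probs,
        rho=rho,
        horizon=horizon,
    )
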