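"""Shared fixtures: a small synthetic ensemble and random optimization instances."""

import numpy as np
import pytest

import treefolio as tf
from treefolio.valuation import ValuationTables


@pytest.fixture(scope="session")
def small_grid():
    return tf.generate_grid(20, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_grid):
    cers, growths, probs = tf.generate_ensemble(small_grid, S=8, seed=7)
    return cers, growths, probs


@pytest.fixture(scope="session")
def small_valuation(small_grid, small_ensemble):
    cers, growths, probs = small_ensemble
    return tf.assemble_valuation(growths, cers, small_grid, probs=probs)


def random_valuation(seed, n_cells=6, n_cer=6, drop_pairs=True):
    """A self-contained random ValuationTables instance for optimizer tests.

    The arrays are synthetic (not derived from a growth simulation): R, m and
    the cost-lens components are drawn directly, scaled so that the
    alternative-technology value term is commensurate with planting values.
    """
    rng = np.random.default_rng(seed)
    shape = (n_cells, 2, n_cer)
    R = rng.normal(0.0, 10.0, shape)
    m = rng.uniform(0.5, 2.0, shape)
    r_timber = rng.normal(0.0, 0.3, shape)
    farm_npv = rng.uniform(0.0, 5.0, shape)
    retained = np.ones((n_cells, 2), dtype=bool)
    if drop_pairs and n_cells > 2:
        drops = rng.integers(0, 2, size=2)
        retained[rng.integers(0, n_cells, size=2), drops] = False
    for arr in (R, m, r_timber, farm_npv):
        arr[~retained, :] = 0.0
    return ValuationTables(
        cell_ids=np.arange(1, n_cells + 1),
        species_names=["conifer", "broadleaf"],
        cer_ids=np.arange(1, n_cer + 1),
        area_ha=rng.uniform(50.0, 300.0, n_cells),
        m=m,
        rotation=np.full(shape, 40.0),
        r_timber=r_timber,
        r_co2=np.zeros(shape),
        R=R,
        farm_npv=farm_npv,
        retained=retained,
        scc_disc=rng.uniform(0.5, 2.0, n_cer),
        probs=np.full(n_cer, 1.0 / n_cer),
        rho=0.035,
        horizon=30,
    )


def random_instance(seed):
    """Random (valuation, spec) pair used by the oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n_cells = int(rng.integers(3, 9))
    n_cer = int(rng.integers(2, 11))
    valuation = random_valuation(seed + 1000, n_cells, n_cer)
    mbar = valuation.mean_m.max(axis=1)
    frac = rng.uniform(0.2, 0.8)
    target_q = float(frac * mbar.sum() / tf.T_PER_MT)
    gamma = float(rng.uniform(0.0, 0.12)) if rng.random() < 0.5 else None
    beta_choices = [b for b in (0.5, 0.75, 0.8, 0.9) if (1 - b) * n_cer >= 1]
    beta = float(rng.choice(beta_choices)) if beta_choices else 0.5
    spec = tf.OptimizationSpec(
        target_q=target_q, beta=beta, gamma=gamma, value_form="V_full", mip_gap=1e-9
    )
    return valuation, spec
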