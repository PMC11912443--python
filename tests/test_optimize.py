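"""MILP portfolio optimizers against hand and enumeration oracles."""

import dataclasses

import numpy as np
import pytest

import treefolio as tf
from treefolio.config import T_PER_MT
from treefolio.valuation import ValuationTables

import _oracle
from conftest import random_instance, random_valuation


def tiny_valuation(R, m, scc_disc=None, n_cer=None):
    """Build a minimal ValuationTables from explicit R (N, J, S) and m arrays."""
    R = np.asarray(R, dtype=float)
    m = np.asarray(m, dtype=float)
    n, j, s = R.shape
    zeros = np.zeros_like(R)
    return ValuationTables(
        cell_ids=np.arange(1, n + 1),
        species_names=["conifer", "broadleaf"][:j],
        cer_ids=np.arange(1, s + 1),
        area_ha=np.full(n, 100.0),
        m=m,
        rotation=np.full_like(R, 40.0),
        r_timber=zeros.copy(),
        r_co2=zeros.copy(),
        R=R,
        farm_npv=zeros.copy(),
        retained=m.mean(axis=2) > 0,
        scc_disc=np.full(s, 1.0) if scc_disc is None else np.asarray(scc_disc, float),
        probs=np.full(s, 1.0 / s),
        rho=0.035,
        horizon=30,
    )


class TestPortfolioValue:
    def test_empty_strategy_is_zero(self):
        val = tiny_valuation(np.ones((2, 2, 3)), np.ones((2, 2, 3)))
        spec = tf.OptimizationSpec(target_q=0.0)
        strategy = tf.PlantingStrategy()
        assert tf.portfolio_value(strategy, val, 0, spec) == 0.0

    def test_single_cell_value(self):
        R = np.zeros((2, 2, 1))
        R[0, 0, 0] = 7.0
        val = tiny_valuation(R, np.ones((2, 2, 1)))
        strategy = tf.PlantingStrategy(assignment={1: "conifer"})
        assert tf.portfolio_value(strategy, val, 0, tf.OptimizationSpec()) == 7.0

    def test_technology_value_closed_form(self):
        """x empty, z=1 Mt, gamma=0, SCC constant 100 GBP/t, rho=0 -> 3.0e9."""
        val = tiny_valuation(np.zeros((2, 2, 1)), np.ones((2, 2, 1)),
                             scc_disc=[100.0 * 30])
        val = dataclasses.replace(val, rho=0.0)
        spec = tf.OptimizationSpec(target_q=1.0, gamma=0.0)
        strategy = tf.PlantingStrategy(z=1.0)
        assert tf.portfolio_value(strategy, val, 0, spec) == pytest.approx(3.0e9)

    def test_excluded_pair_rejected(self):
        R = np.ones((2, 2, 1))
        m = np.ones((2, 2, 1))
        m[1, 1, :] = -1.0
        val = tiny_valuation(R, m)
        strategy = tf.PlantingStrategy(assignment={2: "broadleaf"})
        with pytest.raises(KeyError):
            tf.portfolio_value(strategy, val, 0, tf.OptimizationSpec())


class TestConstraints:
    def test_constraint_counts(self):
        val = tiny_valuation(np.ones((3, 2, 2)), np.ones((3, 2, 2)))
        cs = tf.build_constraints(val, tf.OptimizationSpec(target_q=0.0))
        assert cs.n_assignment_constraints == 3
        assert cs.n_target_constraints == 1

    def test_infeasible_target_reports_maximum(self):
        val = tiny_valuation(np.ones((5, 2, 1)), np.ones((5, 2, 1)))
        spec = tf.OptimizationSpec(target_q=10.0 / T_PER_MT)  # 10 tCO2e/yr from 5 cells
        with pytest.raises(tf.InfeasibleTargetError) as err:
            tf.build_constraints(val, spec)
        assert err.value.max_attainable_mt == pytest.approx(5.0 / T_PER_MT)

    def test_zero_target_with_disabled_tech_is_vacuous(self):
        R = np.array([[[3.0], [-1.0]], [[-2.0], [4.0]]])
        val = tiny_valuation(R, np.ones((2, 2, 1)))
        sol = tf.scenario_optimal(val, 0, tf.OptimizationSpec(target_q=0.0))
        assert sol.strategy.assignment == {1: "conifer", 2: "broadleaf"}
        assert sol.objective_value == pytest.approx(7.0)


class TestScenarioOptimal:
    def _two_cell(self):
        # R(A,con)=5, R(A,bl)=3, R(B,con)=-1, R(B,bl)=2; m == 1 everywhere
        R = np.array([[[5.0], [3.0]], [[-1.0], [2.0]]])
        return tiny_valuation(R, np.ones((2, 2, 1)))

    def test_hand_enumeration(self):
        val = self._two_cell()
        spec = tf.OptimizationSpec(target_q=2.0 / T_PER_MT)
        sol = tf.scenario_optimal(val, 0, spec)
        assert sol.strategy.assignment == {1: "conifer", 2: "broadleaf"}
        assert sol.objective_value == pytest.approx(7.0)

    def test_zero_target_same_answer(self):
        val = self._two_cell()
        sol = tf.scenario_optimal(val, 0, tf.OptimizationSpec(target_q=0.0))
        assert sol.strategy.assignment == {1: "conifer", 2: "broadleaf"}
        assert sol.objective_value == pytest.approx(7.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        val = random_valuation(13, n_cells=8, n_cer=3)
        # force at least 5 cells: Q above the 4 best mean storages
        mbar = np.sort(val.mean_m.max(axis=1))[::-1]
        spec = tf.OptimizationSpec(
            target_q=float(mbar[:5].sum() * 0.999) / T_PER_MT, mip_gap=1e-9
        )
        sol = tf.scenario_optimal(val, 1, spec)
        oracle = _oracle.oracle_scenario(val, spec, 1)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)
        assert sum(val.mean_m[_i(val, c), _j(val, sp)] for c, sp in
                   sol.strategy.assignment.items()) >= spec.target_q * T_PER_MT - 1e-6


def _i(val, cell_id):
    return int(np.where(val.cell_ids == cell_id)[0][0])


def _j(val, species):
    return val.species_names.index(species)


class TestExpectedValueOptimal:
    def test_single_cer_reduces_to_scenario(self):
        val = random_valuation(5, n_cells=6, n_cer=1)
        spec = tf.OptimizationSpec(target_q=0.0, mip_gap=1e-9)
        ev = tf.expected_value_optimal(val, spec)
        sc = tf.scenario_optimal(val, 0, spec)
        assert ev.strategy.assignment == sc.strategy.assignment
        assert ev.objective_value == pytest.approx(sc.objective_value)

    def test_symmetric_cancellation_prefers_empty(self):
        """Antisymmetric values across two CERs: the empty strategy is chosen."""
        rng = np.random.default_rng(2)
        v = rng.normal(0, 5, (4, 2, 1))
        R = np.concatenate([v, -v], axis=2)
        val = tiny_valuation(R, np.ones((4, 2, 2)))
        sol = tf.expected_value_optimal(val, tf.OptimizationSpec(target_q=0.0))
        assert sol.strategy.assignment == {}

    def test_matches_enumeration_oracle(self):
        val, spec = random_instance(17)
        sol = tf.expected_value_optimal(val, spec)
        oracle = _oracle.oracle_expected_value(val, spec)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)


class TestCVaROptimal:
    def test_risk_averse_prefers_stable_site(self):
        """One cell, two species: risky (+14,-10) vs stable (+1.5,+1.5)."""
        R = np.array([[[14.0, -10.0], [1.5, 1.5]]])  # (1 cell, 2 species, 2 CERs)
        val = tiny_valuation(R, np.ones((1, 2, 2)))
        spec = tf.OptimizationSpec(target_q=1.0 / T_PER_MT, beta=0.5, mip_gap=1e-9)
        ra = tf.cvar_optimal(val, spec)
        ev = tf.expected_value_optimal(val, spec)
        assert ra.strategy.assignment == {1: "broadleaf"}
        assert ra.objective_value == pytest.approx(-1.5)
        assert ev.strategy.assignment == {1: "conifer"}
        assert ev.objective_value == pytest.approx(2.0)

    def test_riskless_candidates_reduce_to_ev(self):
        """Identical values across CERs: P-RA and P-EV coincide."""
        rng = np.random.default_rng(3)
        base = rng.normal(0, 5, (5, 2, 1))
        R = np.repeat(base, 4, axis=2)
        val = tiny_valuation(R, np.ones((5, 2, 4)))
        spec = tf.OptimizationSpec(target_q=0.0, beta=0.75, mip_gap=1e-9)
        ra = tf.cvar_optimal(val, spec)
        ev = tf.expected_value_optimal(val, spec)
        assert ra.strategy.assignment == ev.strategy.assignment
        assert ra.objective_value == pytest.approx(-ev.objective_value)

    def test_matches_enumeration_oracle(self):
        val, spec = random_instance(19)
        spec = dataclasses.replace(spec, beta=0.9 if val.n_cer == 10 else spec.beta)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = tf.cvar_optimal(val, spec)
            oracle = _oracle.oracle_cvar(val, spec)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_non_integer_tail_warns(self):
        val = random_valuation(4, n_cells=4, n_cer=3)
        spec = tf.OptimizationSpec(target_q=0.0, beta=0.9)
        with pytest.warns(UserWarning, match="not an integer"):
            tf.cvar_optimal(val, spec)


class TestOrderingInvariants:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_ev_and_cvar_orderings(self, seed):
        import warnings

        val, spec = random_instance(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = tf.expected_value_optimal(val, spec)
            ra = tf.cvar_optimal(val, spec)
        p = val.probs
        assert p @ ev.per_cer_value >= p @ ra.per_cer_value - 1e-7
        assert tf.empirical_cvar(ra.per_cer_value, p, spec.beta) <= (
            tf.empirical_cvar(ev.per_cer_value, p, spec.beta) + 1e-7
        )

    def test_scenario_dominance(self):
        val, spec = random_instance(404)
        sols = [tf.scenario_optimal(val, s, spec) for s in range(val.n_cer)]
        for s, sol in enumerate(sols):
            for other in sols:
                assert sol.per_cer_value[s] >= other.per_cer_value[s] - 1e-7

    def test_relaxation_bound(self):
        val, spec = random_instance(505)
        binary = tf.expected_value_optimal(val, spec)
        relaxed = tf.expected_value_optimal(
            val, dataclasses.replace(spec, relaxation="continuous")
        )
        assert relaxed.objective_value >= binary.objective_value - 1e-6


class TestSweep:
    def _costly_instance(self, seed=23):
        """All pairs have negative expected value; trees only serve the target."""
        rng = np.random.default_rng(seed)
        shape = (6, 2, 4)
        R = rng.uniform(-12.0, -2.0, shape)
        val = tiny_valuation(R, rng.uniform(0.5, 2.0, shape))
        # positive foregone-farm NPV makes every pair a net cost under V_prime
        return dataclasses.replace(
            val, farm_npv=rng.uniform(2.0, 12.0, shape), scc_disc=np.full(4, 1e-6)
        )

    def test_free_technology_displaces_trees(self):
        val = self._costly_instance()
        q = float(0.5 * val.mean_m.max(axis=1).sum()) / T_PER_MT
        spec = tf.OptimizationSpec(target_q=q, beta=0.75, value_form="V_prime")
        table = tf.mixed_technology_sweep(val, spec, [0.0])
        for _, row in table.iterrows():
            assert row["z"] == pytest.approx(q)
            assert row["hectares_conifer"] + row["hectares_broadleaf"] == 0.0

    def test_expensive_technology_unused(self):
        val = self._costly_instance()
        q = float(0.5 * val.mean_m.max(axis=1).sum()) / T_PER_MT
        spec = tf.OptimizationSpec(target_q=q, beta=0.75, value_form="V_prime")
        # costliest tree option: |R| per tCO2e of mean storage, converted per year
        table = tf.mixed_technology_sweep(val, spec, [1e9])
        assert (table["z"] == 0.0).all()
        assert (table["tree_mean_sequestration_MtCO2e"] >= q - 1e-12).all()

    def test_infeasible_gamma_reported(self):
        val = self._costly_instance()
        q = 2.0 * val.mean_m.max(axis=1).sum() / T_PER_MT  # beyond trees; z capped at q
        spec = tf.OptimizationSpec(
            target_q=float(q), beta=0.75, value_form="V_prime", z_max=0.0
        )
        with pytest.raises(tf.InfeasibleTargetError) as err:
            tf.mixed_technology_sweep(val, spec, [0.0, 1.0])
        assert err.value.gamma == 0.0

    def test_bad_grid_rejected(self):
        val = self._costly_instance()
        spec = tf.OptimizationSpec(target_q=0.0, value_form="V_prime")
        with pytest.raises(ValueError):
            tf.mixed_technology_sweep(val, spec, [2.0, 1.0])


class TestStrategyIO:
    def test_round_trip(self, tmp_path):
        strategy = tf.PlantingStrategy(
            assignment={3: "conifer", 1: "broadleaf"}, z=0.25, label="P-EV"
        )
        path = tmp_path / "strategy.csv"
        tf.write_strategy(strategy, path, tf.OptimizationSpec(target_q=1.0))
        loaded = tf.read_strategy(path)
        assert loaded.assignment == strategy.assignment
        assert loaded.z == strategy.z
        assert loaded.label == "P-EV"

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            tf.PlantingStrategy(z=-1.0)
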