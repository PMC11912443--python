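"""Storage rates, annuities, rotations and planting NPV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treefolio as tf
from treefolio.valuation import _discounted_sum


class TestMeanAnnualStorage:
    @pytest.mark.parametrize(
        "g, T, expected",
        [
            ((2, 2, 2), 3, 2.0),
            ((1, 2, 3, 4), 4, 2.5),
            ((-1, 0, 2, 3), 4, 1.0),  # early soil-carbon loss nets out
        ],
    )
    def test_examples(self, g, T, expected):
        assert tf.mean_annual_storage(g, T) == pytest.approx(expected)

    def test_rotation_beyond_path_rejected(self):
        with pytest.raises(ValueError):
            tf.mean_annual_storage([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            tf.mean_annual_storage([1.0], 0)


class TestAnnuityFactor:
    def test_one_year(self):
        assert tf.annuity_factor(0.035, 1) == pytest.approx(1.035, abs=1e-12)

    def test_zero_rate_limit(self):
        assert tf.annuity_factor(0.0, 30) == pytest.approx(1.0 / 30, abs=1e-15)

    def test_thirty_year_value(self):
        # frozen from a 50-digit decimal evaluation of rho/(1-(1+rho)^-T)
        assert tf.annuity_factor(0.035, 30) == pytest.approx(
            0.05437133160742354, abs=1e-6
        )

    @given(
        rho=st.floats(0.0, 0.1),
        T=st.integers(1, 120),
        k=st.floats(-1e6, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_annuity_identity(self, rho, T, k):
        """A constant net flow annualizes to itself for any rate and horizon."""
        flows = np.full(T, k)
        value = tf.annualized_timber(flows, np.zeros(T), rho, T)
        assert value == pytest.approx(k, rel=1e-9, abs=1e-9)


class TestAnnualizedFlows:
    def test_single_harvest(self):
        b = np.zeros(30)
        b[-1] = 1000.0
        assert tf.annualized_timber(b, np.zeros(30), 0.035, 30) == pytest.approx(
            19.3713316, abs=1e-2
        )

    def test_zero_paths(self):
        assert tf.annualized_timber(np.zeros(5), np.zeros(5), 0.05, 5) == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            tf.annualized_timber(np.zeros(5), np.zeros(4), 0.05, 4)

    def test_carbon_constant_annuity(self):
        assert tf.annualized_carbon(
            np.ones(40), np.full(40, 100.0), 0.07, 40
        ) == pytest.approx(100.0, rel=1e-9)

    def test_carbon_two_year_example(self):
        assert tf.annualized_carbon(
            [1.0, 1.0], [100.0, 110.0], 0.035, 2
        ) == pytest.approx(104.914, abs=1e-2)

    def test_carbon_zero_storage(self):
        assert tf.annualized_carbon(np.zeros(10), np.full(10, 80.0), 0.035, 10) == 0.0

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, scale, seed):
        """Doubling all monetary paths doubles the annualized value exactly."""
        rng = np.random.default_rng(seed)
        b, c = rng.uniform(0, 100, 20), rng.uniform(0, 10, 20)
        base = tf.annualized_timber(b, c, 0.035, 20)
        assert tf.annualized_timber(scale * b, scale * c, 0.035, 20) == pytest.approx(
            scale * base, rel=1e-12, abs=1e-12
        )


class TestOptimalRotation:
    def _family(self, table):
        """Cash-flow families realizing given annualized values via constant flows."""

        def b(T):
            return np.full(T, table[T])

        def c(T):
            return np.zeros(T)

        return b, c

    def test_argmax(self):
        b, c = self._family({30: 5.0, 40: 8.0, 50: 7.0})
        assert tf.optimal_rotation(b, c, 0.035, [30, 40, 50]) == 40

    def test_tie_breaks_to_shortest(self):
        # rho=0 keeps both annualized values exactly equal (8*T/T == 8.0)
        b, c = self._family({40: 8.0, 50: 8.0})
        assert tf.optimal_rotation(b, c, 0.0, [40, 50]) == 40

    def test_increasing_values_pick_boundary(self):
        b, c = self._family({20: 1.0, 30: 2.0, 40: 3.0})
        assert tf.optimal_rotation(b, c, 0.035, [20, 30, 40]) == 40

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tf.optimal_rotation(lambda T: np.zeros(T), lambda T: np.zeros(T), 0.035, [])


class TestNpvPlanting:
    def test_zero_net_flow(self):
        assert tf.npv_planting(1.0, 2.0, np.full(30, 3.0), 0.035, 30) == pytest.approx(0.0)

    def test_unit_flow_thirty_years(self):
        assert tf.npv_planting(1.0, 0.0, np.zeros(30), 0.035, 30) == pytest.approx(
            18.392045, abs=1e-3
        )

    def test_undiscounted(self):
        assert tf.npv_planting(1.0, 0.0, np.zeros(30), 0.0, 30) == pytest.approx(30.0)


class TestAssembledTables:
    def test_shapes_and_finiteness(self, small_valuation):
        n, j, s = small_valuation.shape
        assert (n, j, s) == (20, 2, 8)
        for arr in (
            small_valuation.m,
            small_valuation.r_timber,
            small_valuation.r_co2,
            small_valuation.R,
        ):
            assert np.all(np.isfinite(arr))

    def test_exclusion_completeness(self, small_valuation):
        """No retained pair has non-positive ensemble-mean storage."""
        mean_m = small_valuation.m.mean(axis=2)
        assert np.all(mean_m[small_valuation.retained] > 0)

    def test_rotation_is_annualized_timber_argmax(self, small_grid, small_ensemble):
        """Brute-force check of the chosen rotation for a few pairs."""
        cers, growths, probs = small_ensemble
        val = tf.assemble_valuation(growths, cers, small_grid, probs=probs)
        rho = val.rho
        for s in (0, 3):
            growth = growths[s]
            for j in (0, 1):
                rot = growth.rotation_grids[j]
                for i in (0, 5, 11):
                    chosen = int(val.rotation[i, j, s])
                    if not val.retained[i, j]:
                        continue

                    def ann(T):
                        k = int(np.searchsorted(rot, T))
                        b = np.zeros(T)
                        b[-1] = growth.harvest_revenue[j][i, k]
                        c = np.zeros(T)
                        c[0] = growth.planting_cost[i, j]
                        return tf.annualized_timber(b, c, rho, T)

                    values = {int(T): ann(int(T)) for T in rot}
                    assert values[chosen] == pytest.approx(max(values.values()))
                    # tie-break: no strictly shorter rotation attains the max
                    for T, v in values.items():
                        if T < chosen:
                            assert v < values[chosen]

    def test_composition_matches_direct_npv(self, small_grid, small_ensemble):
        """R equals npv_planting applied to the assembled annualized flows."""
        cers, growths, probs = small_ensemble
        val = tf.assemble_valuation(growths, cers, small_grid, probs=probs)
        i, j, s = 2, 0, 1
        if not val.retained[i, j]:
            i = int(np.argwhere(val.retained[:, j])[0])
        direct = tf.npv_planting(
            val.r_timber[i, j, s],
            val.r_co2[i, j, s],
            growths[s].farm_profit[i, :],
            val.rho,
            val.horizon,
        )
        assert val.R[i, j, s] == pytest.approx(direct, rel=1e-10)

    def test_net_emitting_pair_dropped(self, small_grid, small_ensemble):
        cers, growths, probs = small_ensemble
        import copy

        growths = [copy.deepcopy(g) for g in growths]
        for g in growths:
            g.g[0, 0, :] = -1.0  # force one pair to emit in every CER
        val = tf.assemble_valuation(growths, cers, small_grid, probs=probs)
        assert not val.retained[0, 0]
        assert val.R[0, 0, :].sum() == 0.0

    def test_round_trip_twelve_digits(self, small_valuation, tmp_path):
        import pandas as pd

        path = tmp_path / "valuation.csv"
        small_valuation.write(path)
        frame = pd.read_csv(path)
        original = small_valuation.to_frame()
        for col in ("m", "r_timber", "r_co2", "R"):
            np.testing.assert_allclose(frame[col], original[col], rtol=1e-11)


def test_discounted_sum_matches_polynomial():
    flows = np.array([10.0, -5.0, 3.0])
    rho = 0.1
    expected = 10 / 1.1 - 5 / 1.1**2 + 3 / 1.1**3
    assert _discounted_sum(flows, rho, 3) == pytest.approx(expected, rel=1e-12)
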