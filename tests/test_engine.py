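"""Catchment-engine unit and property tests.

The engine is checked against literal double-loop transcriptions of the
supply-demand-ratio and accessibility sums (written first, in
``_oracles.py``), plus the algebraic identities the model family obeys:
conservation of supplied capacity, homogeneity in weights and populations,
and reduction to the classic unweighted 2SFCA.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from _oracles import fca_oracle, random_instance
from conftest import matrix_from
from parkaccess import (
    AccessibilityField,
    DecaySpec,
    DemandSite,
    ModeMix,
    SupplySite,
    accessibility,
    combine_modes,
    gaussian_decay,
    indicator_decay,
    run_scm_g2sfca,
    supply_demand_ratios,
)

# frozen by direct high-precision evaluation of the kernel formula
G_HALF_THRESHOLD = 0.7013665732390044


class TestDecay:
    def test_gaussian_endpoints_and_midpoint(self):
        assert gaussian_decay(0.0, 39.0) == 1.0
        assert gaussian_decay(39.0, 39.0) == 0.0
        assert gaussian_decay(19.5, 39.0) == pytest.approx(G_HALF_THRESHOLD, abs=1e-15)

    def test_gaussian_beyond_threshold_and_unreachable(self):
        assert gaussian_decay(39.0001, 39.0) == 0.0
        assert gaussian_decay(np.inf, 39.0) == 0.0

    def test_gaussian_strictly_decreasing_on_grid(self):
        t = np.linspace(0.0, 39.0, 1000)
        g = gaussian_decay(t, 39.0)
        assert (np.diff(g) < 0).all()
        assert ((g >= 0) & (g <= 1)).all()

    def test_indicator_inclusive_boundary(self):
        assert indicator_decay(39.0, 39.0) == 1.0
        assert indicator_decay(39.0001, 39.0) == 0.0
        assert indicator_decay(0.0, 39.0) == 1.0

    @pytest.mark.parametrize("fn", [gaussian_decay, indicator_decay])
    def test_invalid_inputs_raise(self, fn):
        with pytest.raises(ValueError):
            fn(np.nan, 39.0)
        with pytest.raises(ValueError):
            fn(-1.0, 39.0)
        with pytest.raises(ValueError):
            fn(-np.inf, 39.0)
        with pytest.raises(ValueError):
            fn(1.0, 0.0)

    @given(st.floats(0.1, 200.0), st.floats(1.0, 100.0))
    def test_gaussian_range_and_continuity(self, cost, t0):
        g = gaussian_decay(cost, t0)
        assert 0.0 <= g <= 1.0
        # continuity at the threshold edge
        assert gaussian_decay(t0, t0) == 0.0


def _one_pair(S=10.0, W=2.0, D=100.0, t=0.0):
    demand = [DemandSite("d0", 0, 0, D)]
    supply = [SupplySite("s0", 0, 0, S, W)]
    costs = matrix_from(demand, supply, [[t]])
    return demand, supply, costs


class TestRatios:
    def test_single_pair_hand_value(self, gaussian39):
        demand, supply, costs = _one_pair()
        r = supply_demand_ratios(demand, supply, costs, gaussian39)
        assert r.loc["s0"] == pytest.approx(0.2, abs=1e-15)  # 10*2/100

    def test_empty_catchment_ratio_zero(self, gaussian39, caplog):
        demand, supply, costs = _one_pair(t=50.0)
        with caplog.at_level("WARNING"):
            r = supply_demand_ratios(demand, supply, costs, gaussian39)
        assert r.loc["s0"] == 0.0
        assert any("empty catchment" in m for m in caplog.messages)

    def test_weights_off_reduces_to_unweighted(self, gaussian39):
        rng = np.random.default_rng(3)
        demand, supply, cost = random_instance(rng, 8, 3, 39.0)
        unit = [
            SupplySite(s.site_id, s.x, s.y, s.supply_scale, 1.0) for s in supply
        ]
        costs = matrix_from(demand, supply, cost)
        a = supply_demand_ratios(demand, supply, costs, gaussian39, use_weights=False)
        b = supply_demand_ratios(demand, unit, costs, gaussian39, use_weights=True)
        pd.testing.assert_series_equal(a, b)

    def test_dimension_mismatch_raises(self, gaussian39):
        demand, supply, costs = _one_pair()
        extra = demand + [DemandSite("d1", 1, 1, 5)]
        with pytest.raises(ValueError, match="cost matrix"):
            supply_demand_ratios(extra, supply, costs, gaussian39)


class TestAccessibility:
    def test_single_pair_closed_form(self, gaussian39):
        demand, supply, costs = _one_pair(S=4.0, W=1.0, D=2.0, t=0.0)
        field = accessibility(demand, supply, costs, gaussian39)
        assert field.values.loc["d0"] == pytest.approx(2.0, abs=1e-15)

    def test_additivity_over_duplicated_supply(self, gaussian39):
        demand = [DemandSite("d0", 0, 0, 2.0)]
        supply = [SupplySite("s0", 0, 0, 4.0, 1.0), SupplySite("s1", 0, 0, 4.0, 1.0)]
        costs = matrix_from(demand, supply, [[0.0, 0.0]])
        field = accessibility(demand, supply, costs, gaussian39)
        assert field.values.loc["d0"] == pytest.approx(4.0, abs=1e-14)

    def test_unreachable_site_gets_exact_zero(self, gaussian39):
        demand = [DemandSite("d0", 0, 0, 10.0), DemandSite("d1", 0, 0, 10.0)]
        supply = [SupplySite("s0", 0, 0, 5.0, 1.0)]
        costs = matrix_from(demand, supply, [[10.0], [np.inf]])
        field = accessibility(demand, supply, costs, gaussian39)
        assert field.values.loc["d1"] == 0.0
        assert field.values.loc["d0"] > 0.0

    @pytest.mark.parametrize("kind", ["gaussian", "indicator"])
    @pytest.mark.parametrize("use_weights", [True, False])
    def test_matches_double_loop_oracle(self, kind, use_weights):
        rng = np.random.default_rng(11)
        decay = DecaySpec(kind=kind, threshold=39.0)
        for trial in range(10):
            n_d = int(rng.integers(2, 12))
            n_s = int(rng.integers(1, 5))
            demand, supply, cost = random_instance(rng, n_d, n_s, 39.0, reachable=False)
            costs = matrix_from(demand, supply, cost)
            r_o, a_o = fca_oracle(demand, supply, cost, 39.0, kind, use_weights)
            field = accessibility(demand, supply, costs, decay, use_weights)
            for sid, r in r_o.items():
                assert field.supply_ratios.loc[sid] == pytest.approx(r, abs=1e-12)
            for sid, a in a_o.items():
                assert field.values.loc[sid] == pytest.approx(a, abs=1e-12)

    def test_conservation_of_capacity(self, gaussian39):
        # sum_i D_i A_i == sum_j S_j W_j when every catchment is nonempty
        rng = np.random.default_rng(5)
        demand, supply, cost = random_instance(rng, 50, 10, 39.0, reachable=True)
        costs = matrix_from(demand, supply, cost)
        field = accessibility(demand, supply, costs, gaussian39)
        pop = np.array([s.population for s in demand])
        lhs = pop @ field.values.to_numpy()
        rhs = sum(s.supply_scale * s.weight for s in supply)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @given(st.floats(0.1, 10.0))
    def test_homogeneity_in_weights_and_population(self, c):
        rng = np.random.default_rng(17)
        demand, supply, cost = random_instance(rng, 10, 4, 39.0)
        costs = matrix_from(demand, supply, cost)
        decay = DecaySpec("gaussian", 39.0)
        base = accessibility(demand, supply, costs, decay).values

        scaled_w = [
            SupplySite(s.site_id, s.x, s.y, s.supply_scale, s.weight * c)
            for s in supply
        ]
        a_w = accessibility(demand, scaled_w, costs, decay).values
        np.testing.assert_allclose(a_w.to_numpy(), c * base.to_numpy(), rtol=1e-12)

        scaled_d = [
            DemandSite(s.site_id, s.x, s.y, s.population * c) for s in demand
        ]
        a_d = accessibility(scaled_d, supply, costs, decay).values
        np.testing.assert_allclose(a_d.to_numpy(), base.to_numpy() / c, rtol=1e-12)

    def test_raising_one_weight_raises_accessibility_inside_catchment(self, gaussian39):
        rng = np.random.default_rng(23)
        demand, supply, cost = random_instance(rng, 12, 3, 39.0, reachable=False)
        costs = matrix_from(demand, supply, cost)
        base = accessibility(demand, supply, costs, gaussian39).values
        bumped = [
            SupplySite(s.site_id, s.x, s.y, s.supply_scale,
                       s.weight * (2.0 if k == 0 else 1.0))
            for k, s in enumerate(supply)
        ]
        new = accessibility(demand, bumped, costs, gaussian39).values
        inside = cost[:, 0] < 39.0  # strictly inside: positive kernel value
        assert (new.to_numpy() >= base.to_numpy() - 1e-12).all()
        assert (new.to_numpy()[inside] > base.to_numpy()[inside]).all()
        outside = ~(cost[:, 0] <= 39.0)
        np.testing.assert_allclose(
            new.to_numpy()[outside], base.to_numpy()[outside], rtol=1e-12
        )


def _unit_fields(values_by_mode):
    return {
        m: AccessibilityField(
            mode=m, values=pd.Series({"d0": v}, name="A")
        )
        for m, v in values_by_mode.items()
    }


class TestCombineModes:
    def test_equal_values_are_fixed_point(self):
        mix = ModeMix.default()
        fields = _unit_fields({m: 3.7 for m in mix.modes})
        combined = combine_modes(fields, mix)
        assert combined.values.loc["d0"] == pytest.approx(3.7, abs=1e-15)

    def test_uniform_shares_average(self):
        mix = ModeMix(["a", "b", "c", "d"], [0.25] * 4)
        combined = combine_modes(_unit_fields({"a": 1, "b": 2, "c": 3, "d": 4}), mix)
        assert combined.values.loc["d0"] == pytest.approx(2.5, abs=1e-15)

    def test_unit_driving_field_picks_out_driving_share(self):
        mix = ModeMix.default()
        vals = {m: 0.0 for m in mix.modes}
        vals["driving"] = 1.0
        combined = combine_modes(_unit_fields(vals), mix)
        assert combined.values.loc["d0"] == pytest.approx(0.257, abs=1e-15)

    def test_mode_mismatch_raises(self):
        mix = ModeMix(["a", "b"], [0.5, 0.5])
        with pytest.raises(ValueError, match="mode mismatch"):
            combine_modes(_unit_fields({"a": 1.0, "c": 2.0}), mix)

    def test_combined_bounded_by_mode_extremes(self):
        rng = np.random.default_rng(31)
        mix = ModeMix.default()
        ids = [f"d{i}" for i in range(20)]
        per_mode = {
            m: AccessibilityField(
                mode=m,
                values=pd.Series(rng.uniform(0, 10, 20), index=ids),
            )
            for m in mix.modes
        }
        combined = combine_modes(per_mode, mix).values
        stack = np.vstack([per_mode[m].values.loc[ids].to_numpy() for m in mix.modes])
        assert (combined.loc[ids].to_numpy() >= stack.min(axis=0) - 1e-12).all()
        assert (combined.loc[ids].to_numpy() <= stack.max(axis=0) + 1e-12).all()


class TestFullModel:
    def test_single_mode_share_one_reduces_to_accessibility(self, gaussian39):
        rng = np.random.default_rng(41)
        demand, supply, cost = random_instance(rng, 10, 3, 39.0)
        costs = matrix_from(demand, supply, cost, mode="walking")
        mix = ModeMix(["walking"], [1.0])
        res = run_scm_g2sfca(demand, supply, {"walking": costs}, gaussian39, mix)
        direct = accessibility(demand, supply, costs, gaussian39)
        pd.testing.assert_series_equal(res.combined.values, direct.values)

    def test_identical_matrices_collapse_to_single_mode(self, gaussian39, default_mix):
        rng = np.random.default_rng(43)
        demand, supply, cost = random_instance(rng, 10, 3, 39.0)
        costs = {
            m: matrix_from(demand, supply, cost, mode=m) for m in default_mix.modes
        }
        res = run_scm_g2sfca(demand, supply, costs, gaussian39, default_mix)
        single = accessibility(demand, supply, costs["walking"], gaussian39)
        np.testing.assert_allclose(
            res.combined.values.to_numpy(), single.values.to_numpy(), rtol=1e-12
        )

    def test_missing_mode_matrix_raises(self, gaussian39, default_mix):
        demand, supply, costs = _one_pair()
        with pytest.raises(ValueError, match="no cost matrix"):
            run_scm_g2sfca(demand, supply, {"walking": costs}, gaussian39, default_mix)

    def test_per_mode_ratios_are_retained(self, gaussian39, default_mix):
        rng = np.random.default_rng(47)
        demand, supply, cost = random_instance(rng, 6, 3, 39.0)
        costs = {
            m: matrix_from(demand, supply, cost, mode=m) for m in default_mix.modes
        }
        res = run_scm_g2sfca(demand, supply, costs, gaussian39, default_mix)
        for m in default_mix.modes:
            assert len(res.per_mode[m].supply_ratios) == 3
            assert (res.per_mode[m].supply_ratios > 0).all()


class TestModeMix:
    def test_shares_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalizing"):
            mix = ModeMix(["a", "b"], [2.0, 6.0])
        np.testing.assert_allclose(mix.shares, [0.25, 0.75])

    def test_exact_shares_do_not_warn(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ModeMix.default()

    def test_invalid_shares_raise(self):
        with pytest.raises(ValueError):
            ModeMix(["a", "b"], [0.5, -0.5])
        with pytest.raises(ValueError):
            ModeMix(["a", "a"], [0.5, 0.5])
        with pytest.raises(ValueError):
            ModeMix(["a"], [0.0])
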