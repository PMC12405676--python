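import numpy as np
import pytest

from aocarbon.forcing import AtmosphereCurve
from aocarbon.onepool import (
    LAMBDA_14C,
    OnePoolError,
    OnePoolParams,
    TurnoverLookup,
    build_lookup,
    default_grid,
    invert_f14c,
    normalize_to_2000,
    simulate_f14c,
)


def equilibrium(c, turnover):
    """Closed-form fixed point of the recursion under constant forcing c."""
    k = 1.0 / turnover
    return c * k / (k + LAMBDA_14C)


def recursion_oracle(curve, turnover, target_year, start_year=-53000):
    """Independent brute-force reimplementation of the annual recursion."""
    k = 1.0 / turnover
    f = curve.value_at(start_year) * k / (k + LAMBDA_14C)
    for year in range(start_year + 1, target_year + 1):
        f = curve.value_at(year) * k + f * (1.0 - k - LAMBDA_14C)
    return f


class TestSimulate:
    @pytest.mark.parametrize("turnover", [1, 10, 100, 1000, 10000, 50000])
    def test_constant_forcing_reaches_equilibrium(self, constant_curve, turnover):
        sim = simulate_f14c(constant_curve, turnover, 2000)
        assert sim == pytest.approx(equilibrium(1.0, turnover), abs=1e-6)

    def test_matches_independent_recursion(self, bomb_curve):
        short = AtmosphereCurve(
            "synthetic",
            bomb_curve.years[-150:],
            bomb_curve.f14c[-150:],
        )
        params = OnePoolParams(start_year=int(short.years[0]))
        for turnover in (5.0, 80.0, 2000.0):
            expected = recursion_oracle(short, turnover, 2000, start_year=int(short.years[0]))
            assert simulate_f14c(short, turnover, 2000, params) == pytest.approx(
                expected, rel=1e-12
            )

    def test_fast_pool_tracks_atmosphere(self, bomb_curve):
        for year in (1970, 1990, 2010):
            sim = simulate_f14c(bomb_curve, 1.0, year)
            assert sim == pytest.approx(bomb_curve.value_at(year), rel=0.02)

    def test_subyear_turnover_rejected(self, constant_curve):
        with pytest.raises(OnePoolError):
            simulate_f14c(constant_curve, 0.5, 2000)
        with pytest.raises(OnePoolError):
            simulate_f14c(constant_curve, -1.0, 2000)

    def test_missing_coverage_raises(self, constant_curve):
        with pytest.raises(Exception):
            simulate_f14c(constant_curve, 100, 2050)


class TestLookup:
    def test_constant_curve_values_match_closed_form(self, constant_curve):
        lk = build_lookup(constant_curve, 2000, grid=np.array([100.0, 1000.0]))
        assert lk.f14c_values[0] == pytest.approx(equilibrium(1.0, 100), abs=1e-9)
        assert lk.f14c_values[1] == pytest.approx(equilibrium(1.0, 1000), abs=1e-9)
        # printed to 5 decimals these are 0.98805 and 0.89209
        assert round(lk.f14c_values[0], 5) == 0.98805

    def test_single_point_grid(self, constant_curve):
        lk = build_lookup(constant_curve, 2000, grid=np.array([100.0]))
        assert lk.turnover_grid.size == 1

    @pytest.mark.parametrize("grid", [[0.5, 10.0], [10.0, 60000.0], []])
    def test_grid_outside_1_to_50kyr_rejected(self, constant_curve, grid):
        with pytest.raises(OnePoolError):
            build_lookup(constant_curve, 2000, grid=np.array(grid))

    def test_cache_returns_same_object(self, constant_curve):
        a = build_lookup(constant_curve, 1999)
        b = build_lookup(constant_curve, 1999)
        assert a is b


class TestInvert:
    def test_closed_form_inversion_constant_forcing(self, constant_curve):
        lk = build_lookup(constant_curve, 2000)
        measured = equilibrium(1.0, 100)
        turnover, flags = invert_f14c(lk, measured)
        assert turnover == pytest.approx(100, rel=1e-3)
        assert not flags

    def test_roundtrip_with_simulation(self, bomb_curve):
        lk = build_lookup(bomb_curve, 1995)
        for turnover in (150.0, 1200.0, 9000.0):  # monotone (slow) region
            measured = simulate_f14c(bomb_curve, turnover, 1995)
            inv, _ = invert_f14c(lk, measured)
            assert inv == pytest.approx(turnover, rel=5e-3)

    def test_largest_solution_on_non_monotone_lookup(self):
        lk = TurnoverLookup(2000, np.array([10.0, 20.0, 50.0]), np.array([1.10, 1.20, 1.10]))
        turnover, flags = invert_f14c(lk, 1.10)
        assert turnover == pytest.approx(50.0)
        assert "ambiguous" in flags

    def test_saturation_below_grid_minimum(self, constant_curve):
        lk = build_lookup(constant_curve, 2000)
        turnover, flags = invert_f14c(lk, 1e-6)
        assert turnover == pytest.approx(50000.0)
        assert "saturated" in flags

    def test_super_modern_above_global_maximum(self, constant_curve):
        lk = build_lookup(constant_curve, 2000)
        turnover, flags = invert_f14c(lk, 1.5)
        assert "super_modern" in flags
        assert turnover == pytest.approx(lk.turnover_grid[np.argmax(lk.f14c_values)])

    def test_nonpositive_measurement_rejected(self, constant_curve):
        lk = build_lookup(constant_curve, 2000)
        with pytest.raises(OnePoolError):
            invert_f14c(lk, 0.0)


class TestNormalize:
    def test_cutoff_left_unnormalized(self, bomb_curve):
        value, flags = normalize_to_2000(0.15, 1990, bomb_curve)
        assert value == 0.15
        assert flags == {"unnormalized"}

    def test_identity_under_constant_forcing(self, constant_curve):
        for measured in (0.2, 0.5, 0.9, 0.99):
            value, _ = normalize_to_2000(measured, 1985, constant_curve)
            assert value == pytest.approx(measured, abs=1e-12)

    def test_bomb_roundtrip_by_construction(self, bomb_curve):
        measured = simulate_f14c(bomb_curve, 100.0, 1990)
        value, _ = normalize_to_2000(measured, 1990, bomb_curve)
        assert value == pytest.approx(simulate_f14c(bomb_curve, 100.0, 2000), abs=2e-4)

    def test_monotone_decreasing_beyond_bomb_region(self, bomb_curve):
        lk = build_lookup(bomb_curve, 2000)
        slow = lk.f14c_values[lk.turnover_grid >= 100.0]
        assert np.all(np.diff(slow) < 0)
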