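import numpy as np
import pytest
from hypothesis import given, strategies as st

from meanfield_sca.meanfield import (
    MeanFieldSpec, bifurcation_diagram, classify, critical_point, equilibria,
    grid_critical_point_exact, grid_map, iterate_map, rg_map, sw_map,
)

from math import comb


def oracle_map(rho, p, size, r_min=0):
    """Independent term-by-term summation of the majority-rule mean-field sum."""
    total = 0.0
    for r in range(r_min, size + 1):
        w = p if r <= size / 2 else 1 - p
        total += w * comb(size, r) * rho ** r * (1 - rho) ** (size - r)
    return total


class TestGridMap:
    def test_at_zero_density_returns_p(self):
        for p in (0.0, 0.1, 0.37):
            assert grid_map(0.0, p, 5) == pytest.approx(p, abs=1e-15)

    def test_half_is_fixed_point_for_odd_gamma(self):
        for p in (0.05, 0.2, 0.45):
            assert grid_map(0.5, p, 5) == pytest.approx(0.5, abs=1e-15)

    def test_hand_evaluated_value(self):
        assert grid_map(0.1, 0.1, 5) == pytest.approx(0.106848, abs=1e-6)

    def test_matches_term_by_term_oracle(self):
        for rho in np.linspace(0, 1, 21):
            for p in (0.05, 0.25, 0.5):
                assert grid_map(rho, p, 5) == pytest.approx(
                    oracle_map(rho, p, 5), abs=1e-12)

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            grid_map(1.2, 0.1, 5)


class TestRandomGraphMap:
    def test_nu_is_floor_of_expected_degree(self):
        spec = MeanFieldSpec(kind="random", n=25, p=0.2, p_e=0.1)
        assert spec.nu == 2  # floor(0.1 * 24)

    def test_at_zero_density_returns_p(self):
        assert rg_map(0.0, 0.3, 0.1, 25) == pytest.approx(0.3)

    def test_nu_two_closed_form_and_fixed_point(self):
        # ν=2 collapses to p + (1-2p)ρ²; fixed point at p=0.2 is ≈0.23241
        for rho in np.linspace(0, 1, 11):
            assert rg_map(rho, 0.2, 0.1, 25) == pytest.approx(
                0.2 + 0.6 * rho ** 2, abs=1e-12)
        eq = equilibria(MeanFieldSpec(kind="random", n=25, p=0.2, p_e=0.1))
        assert eq == [pytest.approx(0.2324081, abs=1e-4)]

    def test_degenerate_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            rg_map(0.5, 0.2, 0.01, 25)  # nu = 0


class TestSmallWorldMap:
    def test_empty_random_part_when_nu_at_most_gamma(self):
        # n=16, p_w=0.3 -> nu = 4 <= 5: only the grid part survives
        rho = 0.4
        expected = (5 / 16) * grid_map(rho, 0.1, 5) * (1 - 0.3) ** 11
        assert sw_map(rho, 0.1, 0.3, 16, 5) == pytest.approx(expected, abs=1e-14)

    def test_value_at_zero_density(self):
        p, p_w, n, g = 0.2, 0.5, 16, 5
        assert sw_map(0.0, p, p_w, n, g) == pytest.approx(
            (g / n) * p * (1 - p_w) ** (n - g), abs=1e-14)

    def test_matches_weighted_two_part_oracle(self):
        n, g, p_w, p = 16, 5, 0.4, 0.1
        nu = int(np.floor(p_w * (n - 1)))  # 6 > gamma
        for rho in np.linspace(0, 1, 13):
            expected = ((g / n) * oracle_map(rho, p, g) * (1 - p_w) ** (n - g)
                        + ((n - g) / n) * oracle_map(rho, p, nu, r_min=g + 1))
            assert sw_map(rho, p, p_w, n, g) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_maps_send_unit_interval_into_itself(rho, p):
    for val in (grid_map(rho, p, 5), grid_map(rho, p, 9),
                rg_map(rho, p, 0.3, 25), sw_map(rho, p, 0.5, 16, 5)):
        assert 0.0 <= float(val) <= 1.0


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_grid_map_symmetry_odd_gamma(rho, p):
    # f_p(1-ρ) = 1 - f_p(ρ) for odd |Γ|
    assert float(grid_map(1 - rho, p, 5)) == pytest.approx(
        1 - float(grid_map(rho, p, 5)), abs=1e-12)


class TestIterateAndEquilibria:
    def test_fixed_point_gives_constant_orbit(self):
        spec = MeanFieldSpec(kind="grid", n=100, p=0.2)
        orbit = iterate_map(spec, 0.5, 100)
        assert np.allclose(orbit, 0.5)

    def test_bistable_equilibria_at_p_point_one(self):
        eq = equilibria(MeanFieldSpec(kind="grid", n=100, p=0.1))
        assert len(eq) == 2
        assert eq[0] == pytest.approx(0.1087, abs=1e-3)
        assert eq[1] == pytest.approx(0.8913, abs=1e-3)

    def test_single_equilibrium_at_p_point_three(self):
        assert equilibria(MeanFieldSpec(kind="grid", n=100, p=0.3)) == [
            pytest.approx(0.5, abs=1e-6)]

    def test_constant_map_at_p_half(self):
        eq = equilibria(MeanFieldSpec(kind="grid", n=100, p=0.5),
                        starts=(0.0, 0.3, 1.0))
        assert eq == [pytest.approx(0.5)]

    def test_limit_from_high_start_at_p_point_three(self):
        orbit = iterate_map(MeanFieldSpec(kind="grid", n=100, p=0.3), 0.9, 1000)
        assert round(orbit[-1], 1) == 0.5


class TestCriticalPoint:
    @pytest.mark.parametrize("gamma", [5, 9, 13])
    def test_numerical_matches_pitchfork_closed_form(self, gamma):
        spec = MeanFieldSpec(kind="grid", n=100, p=0.1, gamma_size=gamma)
        assert critical_point(spec) == pytest.approx(
            grid_critical_point_exact(gamma), abs=1e-3)

    def test_gamma_five_closed_form_is_seven_thirtieths(self):
        assert grid_critical_point_exact(5) == pytest.approx(7 / 30, abs=1e-12)


class TestBifurcationDiagram:
    def test_two_branches_below_one_above(self):
        spec = MeanFieldSpec(kind="grid", n=100, p=0.1)
        diagram = bifurcation_diagram(spec, p_values=np.arange(0.02, 0.5, 0.02),
                                      refine=False)
        n_eq = np.array([len(e) for e in diagram.equilibria])
        below = diagram.p_values < 7 / 30 - 0.02
        above = diagram.p_values > 7 / 30 + 0.02
        assert np.all(n_eq[below] == 2)
        assert np.all(n_eq[above] == 1)

    def test_bistable_branches_sum_to_one(self):
        spec = MeanFieldSpec(kind="grid", n=100, p=0.1)
        diagram = bifurcation_diagram(spec, p_values=np.arange(0.02, 0.2, 0.02),
                                      refine=False)
        for eqs in diagram.equilibria:
            assert eqs[0] + eqs[1] == pytest.approx(1.0, abs=1e-8)

    def test_p_grid_outside_half_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_diagram(MeanFieldSpec(kind="grid", n=100),
                                p_values=[0.2, 0.6])


class TestClassify:
    def test_bistable_below_critical(self):
        res = classify(MeanFieldSpec(kind="grid", n=100, p=0.1))
        assert res.verdict == "bistable"
        assert res.transition_expectancy
        assert res.critical_point == pytest.approx(7 / 30, abs=1e-3)

    def test_stable_above_critical(self):
        res = classify(MeanFieldSpec(kind="grid", n=100, p=0.3))
        assert res.verdict == "stable"

    def test_boundary_assigned_stable(self):
        spec = MeanFieldSpec(kind="grid", n=100, p=0.1)
        cp = critical_point(spec)
        assert classify(spec, p_hat=cp).verdict == "stable"

    def test_p_hat_outside_half_rejected(self):
        with pytest.raises(ValueError):
            classify(MeanFieldSpec(kind="grid", n=100, p=0.1), p_hat=0.7)
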