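"""Ternary-complex binding: conversions, mass action, equilibrium, scans."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcesim.binding import (BindingParams, SpeciesState, binding_odes,
                            clamped_equilibrium, concentration_scan,
                            peak_concentration, sites_to_concentration,
                            solve_equilibrium, SPECIES, _STOICH, _rates)
from tcesim.constants import AVOGADRO

from conftest import random_binding_params


def integrate_to_steady_state(total_tce, p, t_end=2e7):
    """Independent oracle: stiff ODE integration of the mass-action network."""
    y0 = np.array([total_tce, p.cea_total_nM, p.cd3_total_nM, 0, 0, 0, 0, 0, 0])
    sol = solve_ivp(lambda t, y: _STOICH @ _rates(y, p), (0.0, t_end), y0,
                    method="LSODA", rtol=1e-12, atol=1e-14)
    return SpeciesState.from_array(sol.y[:, -1])


class TestSitesToConcentration:
    def test_zero_sites_gives_zero(self):
        assert sites_to_concentration(0.0, 1e12) == 0.0

    def test_linearity(self):
        c1 = sites_to_concentration(1e4, 5e11)
        assert sites_to_concentration(2e4, 5e11) == pytest.approx(2 * c1, rel=1e-12)
        assert sites_to_concentration(1e4, 1e12) == pytest.approx(2 * c1, rel=1e-12)

    def test_hand_computed_value(self):
        # 6.1e4 sites/cell at 1e12 cells/L: 6.1e16 sites/L / N_A * 1e9 nM
        expected = 6.1e4 * 1e12 / AVOGADRO * 1e9
        assert expected == pytest.approx(101.2929, abs=1e-3)
        assert sites_to_concentration(6.1e4, 1e12) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sites_to_concentration(-1.0, 1e12)


class TestBindingOdes:
    def test_no_partners_no_flux(self, params):
        state = SpeciesState(T_free=5.0)
        d = binding_odes(state, params)
        assert all(getattr(d, n) == 0.0 for n in SPECIES)

    def test_conserved_totals_have_zero_derivative(self, rng, params):
        for _ in range(20):
            state = SpeciesState(*rng.uniform(0, 10, size=9))
            d = binding_odes(state, params)
            assert d.total_tce == pytest.approx(0.0, abs=1e-12)
            assert d.total_cea == pytest.approx(0.0, abs=1e-12)
            assert d.total_cd3 == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            SpeciesState(T_free=-1.0)


class TestSolveEquilibrium:
    def test_zero_tce_all_complexes_zero(self, params):
        st = solve_equilibrium(0.0, params)
        assert st.T_free == 0.0
        assert st.biTTC == 0.0 and st.moTTC == 0.0 and st.AT == 0.0

    def test_matches_ode_integration(self, params):
        st = solve_equilibrium(10.0, params)
        ode = integrate_to_steady_state(10.0, params)
        assert st.biTTC == pytest.approx(ode.biTTC, rel=1e-6)

    def test_matches_ode_on_random_draws(self, rng):
        """Algebraic equilibrium agrees with long-time integration, 20 draws."""
        for _ in range(20):
            p = random_binding_params(rng)
            total = 10 ** rng.uniform(-2, 2)
            st = solve_equilibrium(total, p)
            ode = integrate_to_steady_state(total, p)
            for name in ("biTTC", "moTTC", "AT", "AAT", "TC"):
                a, b = getattr(st, name), getattr(ode, name)
                assert a == pytest.approx(b, rel=1e-5, abs=1e-10)

    def test_conservation_of_totals(self, params):
        st = solve_equilibrium(3.0, params)
        assert st.total_tce == pytest.approx(3.0, rel=1e-9)
        assert st.total_cea == pytest.approx(params.cea_total_nM, rel=1e-9)
        assert st.total_cd3 == pytest.approx(params.cd3_total_nM, rel=1e-9)

    def test_low_antigen_bittc_increases_with_lambda(self, params):
        p_lo = params.with_(cea_sites=5e3, lambda_crossarm=1.0)
        p_hi = params.with_(cea_sites=5e3, lambda_crossarm=1e4)
        for conc in np.logspace(-2, 2, 7):
            assert solve_equilibrium(conc, p_hi).biTTC > solve_equilibrium(conc, p_lo).biTTC


class TestConcentrationScan:
    def test_single_point_closed_mode_equals_solver(self, params):
        df = concentration_scan([5.0], params, mode="closed")
        st = solve_equilibrium(5.0, params)
        assert df.loc[0, "biTTC"] == pytest.approx(st.biTTC, rel=1e-9)
        assert df.loc[0, "moTTC"] == pytest.approx(st.moTTC, rel=1e-9)

    def test_species_columns_present(self, params):
        df = concentration_scan([1.0, 2.0], params)
        for col in ("T_free", "AT", "AAT", "TC", "moTTC", "biTTC", "sAT"):
            assert col in df.columns

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            concentration_scan([], params)

    def test_unsorted_grid_rejected(self, params):
        with pytest.raises(ValueError):
            concentration_scan([2.0, 1.0], params)

    def test_bell_shape_single_interior_maximum(self, params):
        grid = np.logspace(-3, 4, 141)
        bi = concentration_scan(grid, params)["biTTC"].to_numpy()
        d = np.sign(np.diff(bi))
        maxima = int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
        assert maxima == 1
        peak = peak_concentration(concentration_scan(grid, params))
        assert 0.03 < peak < 0.3

    def test_lambda_monotonicity_at_low_antigen(self, params):
        """biTTC is non-decreasing in lambda at every conc <= 100 nM for
        CEA expression up to 5e4 sites/cell."""
        for cea in (5e3, 5e4):
            grids = {}
            for lam in (1.0, 100.0, 1e4):
                p = params.with_(cea_sites=cea, lambda_crossarm=lam)
                grids[lam] = concentration_scan(
                    np.logspace(-3, 2, 11), p)["biTTC"].to_numpy()
            assert np.all(grids[100.0] >= grids[1.0])
            assert np.all(grids[1e4] >= grids[100.0])

    def test_high_antigen_lambda_insensitivity(self, params):
        """At 5e5 CEA sites/cell the TCE is the limiting reagent and lambda
        has little effect (small factor across four orders of magnitude)."""
        grid = np.logspace(-3, 2, 11)
        vals = {lam: concentration_scan(
            grid, params.with_(cea_sites=5e5, lambda_crossarm=lam))["biTTC"].to_numpy()
            for lam in (1.0, 100.0, 1e4)}
        ratio = np.max(vals[1e4] / vals[1.0])
        assert ratio < 2.0


class TestClampedEquilibrium:
    def test_conserves_receptor_totals(self, rng):
        for _ in range(10):
            p = random_binding_params(rng)
            st = clamped_equilibrium(10 ** rng.uniform(-2, 2), p)
            assert st.total_cea == pytest.approx(p.cea_total_nM, rel=1e-8)
            assert st.total_cd3 == pytest.approx(p.cd3_total_nM, rel=1e-8)

    def test_extreme_avidity_falls_back_robustly(self, params):
        p = params.with_(lambda_crossarm=1e7, koff_cd3tce=1e-6)
        st = clamped_equilibrium(1.0, p)
        assert st.total_cea == pytest.approx(p.cea_total_nM, rel=1e-6)


class TestBindingParamsValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(koff_ceatce=-1.0)

    def test_zero_kon_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(kon_ceatce=0.0)

    def test_derived_kds(self, params):
        assert params.kd_cea == pytest.approx(130.0)
        assert math.isfinite(params.kd_cd3) and params.kd_cd3 > 0
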