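import numpy as np
import pytest

from mushdry.config import default_config
from mushdry.solver import AmbientSchedule, DryingModel, build_grid


class TestBuildGrid:
    def test_solid_mass_bookkeeping(self):
        cfg = default_config()
        cfg.solver.n_cap = 8
        cfg.solver.n_lam = 2
        cfg.solver.fresh_mass = 25e-3
        cfg.solver.x_m0 = 9.0
        grid = build_grid(cfg)
        assert grid.total_solid == pytest.approx(25e-3 / 10.0, rel=1e-12)
        assert grid.n == 10
        assert grid.n_lam == 2

    def test_refinement_leaves_totals_unchanged(self):
        cfg = default_config()
        g1 = build_grid(cfg)
        cfg.solver.n_cap *= 2
        g2 = build_grid(cfg)
        assert g1.total_solid == pytest.approx(g2.total_solid, rel=1e-12)

    def test_initial_radius_consistent_with_mass(self, default_model):
        """Outer radius closes with the cap volume implied by composition,
        shrinkage law, fresh mass and initial moisture (about 3 cm)."""
        d = default_model.derive(default_model.initial_state())
        cap = ~default_model.grid.is_lamella
        v_cap = d.V_bulk[cap].sum()
        r_expected = (3.0 * v_cap / (2.0 * np.pi)) ** (1.0 / 3.0)
        assert d.radius == pytest.approx(r_expected, rel=1e-10)
        assert 0.02 < d.radius < 0.04

    def test_rejects_too_few_cells(self):
        cfg = default_config()
        cfg.solver.n_cap = 1
        cfg.solver.n_lam = 0
        with pytest.raises(ValueError):
            build_grid(cfg)


class TestSplitState:
    def test_round_trip_identity(self, default_model):
        c_w, T = 500.0, 305.0
        phi_air, phi_s = 0.5, 0.1
        c_m, q = default_model.compose_state(c_w, T, phi_air, phi_s)
        c_w2, c_v2, T2, aw2 = default_model.split_state(c_m, q, phi_air, phi_s)
        assert c_w2 == pytest.approx(c_w, rel=1e-6)
        assert T2 == pytest.approx(T, rel=1e-6)
        assert 0 < aw2 <= 1
        assert c_m == pytest.approx((1 - phi_air) * c_w2 + phi_air * c_v2, rel=1e-9)

    def test_zero_porosity_drops_vapor(self, default_model):
        c_m, q = default_model.compose_state(400.0, 300.0, 0.0, 0.2)
        c_w2, c_v2, T2, _ = default_model.split_state(c_m, q, 0.0, 0.2)
        assert c_w2 == pytest.approx(c_m, rel=1e-12)
        assert T2 == pytest.approx(300.0, rel=1e-9)

    def test_vapor_is_minor_when_wet(self, default_model):
        """Vapor holds well below 1 % of the moisture in any wet state."""
        d = default_model.derive(default_model.initial_state())
        assert np.all(d.m_vap / d.M < 0.01)

    def test_rejects_unphysical_input(self, default_model):
        with pytest.raises(ValueError):
            default_model.split_state(-1.0, 1e5, 0.5, 0.1)


class TestExplicitStepConservation:
    def test_closed_box_conserves_mass_and_energy(self, default_model):
        """Zero-exchange stepping keeps totals to round-off over many steps."""
        model = default_model
        amb = AmbientSchedule.constant(308.15, 0.3, 0.3, 1e9)
        y = model.initial_state()
        m0 = model.unpack(y)[0].sum()
        q0 = model.unpack(y)[1].sum()
        for _ in range(2000):
            y = model.step(y, 0.0, amb, 1.0, exchange=False)
        m1 = model.unpack(y)[0].sum()
        q1 = model.unpack(y)[1].sum()
        assert abs(m1 - m0) / m0 < 1e-10
        assert abs(q1 - q0) / abs(q0) < 1e-10

    def test_equilibrated_state_is_stationary(self, default_model):
        """All fluxes vanish when tissue is equilibrated with the air."""
        model = default_model
        T_air = 308.15
        rh = model.derive(model.initial_state()).a_w[0]  # match initial a_w
        amb = AmbientSchedule.constant(T_air, float(rh), 0.3, 1e9)
        cfg_t = model.config.solver.t_init
        try:
            model.config.solver.t_init = T_air
            y = model.initial_state()
            rate = model.rhs(0.0, y, amb)
            dM, dQ, _, _, _ = model.unpack(rate)
            M, Q = model.unpack(y)[:2]
            assert np.max(np.abs(dM)) * 3600.0 < 1e-6 * M.max()
            assert np.max(np.abs(dQ)) * 3600.0 < 1e-5 * np.abs(Q).max()
        finally:
            model.config.solver.t_init = cfg_t

    def test_saturated_air_no_evaporation(self, default_model):
        model = default_model
        cfg_t = model.config.solver.t_init
        try:
            model.config.solver.t_init = 308.15
            y = model.initial_state()
            amb_dry = AmbientSchedule.constant(308.15, 0.3, 0.3, 1e9)
            amb_sat = AmbientSchedule.constant(308.15, 0.999, 0.3, 1e9)
            loss_dry = -model.unpack(model.rhs(0.0, y, amb_dry))[0].sum()
            loss_sat = -model.unpack(model.rhs(0.0, y, amb_sat))[0].sum()
            assert loss_sat < 0.02 * loss_dry
        finally:
            model.config.solver.t_init = cfg_t


class TestSimulate:
    def test_moisture_monotone_under_dry_air(self, short_drying_result):
        assert np.all(np.diff(short_drying_result.y_w) < 1e-10)
        np.testing.assert_allclose(
            short_drying_result.y_w,
            short_drying_result.x_m / (1.0 + short_drying_result.x_m),
            rtol=1e-12,
        )

    def test_surface_dries_before_center(self, short_drying_result):
        r = short_drying_result
        assert np.all(r.aw_surface <= r.aw_center + 1e-6)
        # and strictly so while drying is under way
        mid = len(r.t) // 2
        assert r.aw_surface[mid] < r.aw_center[mid] - 0.05

    def test_temperatures_bounded(self, short_drying_result, default_model):
        from mushdry.transport import wet_bulb_temperature

        t_wb = wet_bulb_temperature(308.15, 0.3, 0.3, default_model.config.transport)
        assert np.all(short_drying_result.T_center >= t_wb - 1.0)
        assert np.all(short_drying_result.T_center <= 308.15 + 0.1)
        assert np.all(short_drying_result.T_surface <= 308.15 + 0.1)

    def test_global_balance_closure(self, short_drying_result):
        b = short_drying_result.balances
        assert abs(b["moisture_closure_rel"]) < 1e-6
        assert abs(b["energy_closure_rel"]) < 1e-6

    def test_deterministic(self, default_model, ha35_schedule):
        t_eval = np.linspace(0.0, 4 * 3600.0, 9)
        r1 = default_model.simulate(ha35_schedule, 4 * 3600.0, t_eval=t_eval)
        r2 = default_model.simulate(ha35_schedule, 4 * 3600.0, t_eval=t_eval)
        np.testing.assert_array_equal(r1.y_w, r2.y_w)
        np.testing.assert_array_equal(r1.T_center, r2.T_center)


class TestGridConvergence:
    def test_average_moisture_insensitive_to_refinement(self):
        """Doubling the cap resolution changes the drying curve by < 1 %."""
        t_eval = np.linspace(0.0, 10 * 3600.0, 21)
        curves = []
        for n_cap in (10, 20):
            cfg = default_config()
            cfg.solver.n_cap = n_cap
            cfg.solver.rtol = 1e-5
            model = DryingModel(cfg)
            amb = AmbientSchedule.constant(308.15, 0.3, 0.3, 1e7)
            curves.append(model.simulate(amb, 10 * 3600.0, t_eval=t_eval).y_w)
        assert np.max(np.abs(curves[0] - curves[1])) < 0.01


class TestAmbientSchedule:
    def test_interpolation_and_csv_round_trip(self, tmp_path):
        sched = AmbientSchedule(
            np.array([0.0, 3600.0, 7200.0]),
            np.array([300.0, 310.0, 305.0]),
            np.array([0.3, 0.5, 0.4]),
            np.array([0.2, 0.2, 0.3]),
        )
        T, rh, u = sched(1800.0)
        assert T == pytest.approx(305.0)
        assert rh == pytest.approx(0.4)
        path = tmp_path / "amb.csv"
        sched.to_csv(path)
        back = AmbientSchedule.from_csv(path)
        np.testing.assert_allclose(back.T_air, sched.T_air, atol=1e-9)
        np.testing.assert_allclose(back.rh, sched.rh, atol=1e-12)

    def test_rejects_bad_rh(self):
        with pytest.raises(ValueError):
            AmbientSchedule(
                np.array([0.0, 1.0]), np.array([300.0, 300.0]),
                np.array([0.3, 1.2]), np.array([0.3, 0.3]),
            )
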