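import math

import numpy as np
import pytest

from mushdry.calibration import (
    DvsProtocol,
    ExperimentRecord,
    fit_stats,
    objective_lse,
    sequential_search,
    simulate_dvs,
)
from mushdry.config import default_config
from mushdry.solver import DryingResult


def make_result(t, yw, tc):
    """Minimal DryingResult carrying just the curves the objective reads."""
    import pandas as pd

    t = np.asarray(t, dtype=float)
    return DryingResult(
        t, np.asarray(yw, float), np.zeros_like(t), np.asarray(tc, float),
        np.zeros_like(t), np.zeros_like(t), np.zeros_like(t), pd.DataFrame(),
    )


def make_record(t, yw, tp, T_init=298.15, T_air=308.15):
    return ExperimentRecord(np.asarray(t, float), np.asarray(yw, float),
                            np.asarray(tp, float), T_init, T_air)


class TestObjectiveLse:
    def test_perfect_prediction_is_zero(self):
        rec = make_record([0, 3600, 7200], [0.9, 0.8, 0.7],
                          [298.15, 300.15, 302.15])
        sim = make_result(rec.t, rec.y_w, rec.T_p)
        assert objective_lse([rec], [sim]) == 0.0

    def test_hand_computed_value(self):
        """Two Theta residuals of 0.1 and one moisture residual of 0.1 give
        2*0.01/2 + 10*0.01/1 = 0.11 with a single-point moisture record."""
        T_init, T_air = 298.15, 308.15
        scale = T_air - T_init
        rec_t = ExperimentRecord(
            np.array([0.0, 3600.0]), np.array([0.5, 0.5]),
            np.array([T_init + 0.2 * scale, T_init + 0.5 * scale]),
            T_init, T_air,
        )
        sim = make_result(
            rec_t.t,
            [0.5, 0.5],
            [T_init + 0.3 * scale, T_init + 0.6 * scale],  # Theta off by 0.1
        )
        theta_term = objective_lse([rec_t], [sim])
        assert theta_term == pytest.approx(2 * 0.01 / 2, abs=1e-12)

        rec_y = ExperimentRecord(
            np.array([0.0, 3600.0]), np.array([0.5, 0.6]),
            np.array([T_init + 0.2 * scale, T_init + 0.5 * scale]),
            T_init, T_air,
        )
        sim_y = make_result(rec_y.t, [0.6, 0.7],
                            [T_init + 0.2 * scale, T_init + 0.5 * scale])
        moist_term = objective_lse([rec_y], [sim_y])
        assert moist_term == pytest.approx(10 * (2 * 0.01) / 2, abs=1e-12)

    def test_quadratic_scaling_of_moisture_residuals(self):
        rec = make_record([0, 3600], [0.5, 0.6], [298.15, 298.15], T_air=318.15)
        sim1 = make_result(rec.t, [0.51, 0.61], rec.T_p)
        sim3 = make_result(rec.t, [0.53, 0.63], rec.T_p)
        assert objective_lse([rec], [sim3]) == pytest.approx(
            9 * objective_lse([rec], [sim1]), rel=1e-9
        )

    def test_invariant_to_experiment_order(self):
        rec_a = make_record([0, 3600], [0.8, 0.7], [299.0, 301.0])
        rec_b = make_record([0, 3600], [0.9, 0.6], [300.0, 305.0], T_air=324.15)
        sim_a = make_result(rec_a.t, [0.81, 0.69], [299.5, 301.5])
        sim_b = make_result(rec_b.t, [0.88, 0.62], [300.5, 304.0])
        assert objective_lse([rec_a, rec_b], [sim_a, sim_b]) == pytest.approx(
            objective_lse([rec_b, rec_a], [sim_b, sim_a]), rel=1e-12
        )

    def test_theta_undefined_when_isothermal(self):
        rec = make_record([0, 3600], [0.8, 0.7], [298.15, 298.15],
                          T_init=308.15, T_air=308.15)
        sim = make_result(rec.t, rec.y_w, rec.T_p)
        with pytest.raises(ValueError):
            objective_lse([rec], [sim])


class TestFitStats:
    def test_perfect_fit(self):
        r2, rmse, mae = fit_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r2, rmse, mae) == (1.0, 0.0, 0.0)

    def test_hand_values(self):
        r2, rmse, mae = fit_stats([0.0, 1.0], [0.1, 0.9])
        assert r2 == pytest.approx(0.96)
        assert rmse == pytest.approx(0.1)
        assert mae == pytest.approx(0.1)

    def test_null_model_baseline(self):
        y = [1.0, 2.0, 3.0]
        r2, _, _ = fit_stats(y, [2.0, 2.0, 2.0])
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_reported_as_nan(self):
        r2, _, _ = fit_stats([1.0, 1.0], [1.0, 1.1])
        assert math.isnan(r2)


class TestSequentialSearch:
    def test_separable_quadratic_found_quickly(self):
        evals = []

        def obj(p):
            evals.append(1)
            return (p["x"] - 3.0) ** 2 + (p["y"] + 2.0) ** 2

        grids = {"x": [0.0, 1.0, 2.0, 3.0, 4.0], "y": [-3.0, -2.0, -1.0, 0.0]}
        res = sequential_search(obj, grids, {"x": 0.0, "y": 0.0})
        assert res.params == {"x": 3.0, "y": -2.0}
        assert res.objective == 0.0
        # budget bound: at most cycles * total grid size evaluations
        assert res.n_eval <= 12 * (5 + 4)

    def test_incumbent_monotone_along_trace(self):
        def obj(p):
            return (p["x"] - 1.0) ** 2 + 0.5 * (p["y"] - 2.0) ** 2 + 0.01

        grids = {"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]}
        res = sequential_search(obj, grids, {"x": 0.0, "y": 0.0})
        assert res.params == {"x": 1.0, "y": 2.0}

    def test_failed_points_skipped_with_warning(self):
        def obj(p):
            if p["x"] == 2.0:
                raise RuntimeError("boom")
            return (p["x"] - 1.0) ** 2 + 0.5  # nonzero floor: no early exit

        with pytest.warns(UserWarning):
            res = sequential_search(obj, {"x": [0.0, 1.0, 2.0]}, {"x": 0.0})
        assert res.params["x"] == 1.0


class TestSimulateDvs:
    def test_sealed_sample_constant(self):
        proto = DvsProtocol.cycle(k_exchange=0.0)
        res = simulate_dvs(proto)
        np.testing.assert_allclose(res.x_end, res.x_start, rtol=1e-12)

    def test_full_equilibrium_limit(self, default_model):
        """Fast exchange and instant relaxation: each step lands on the
        relaxed isotherm and the two branches coincide."""
        cfg = default_config()
        cfg.viscoelastic.slow.f_tau = 1e-8
        cfg.viscoelastic.fast.f_tau = 1e-8
        proto = DvsProtocol.cycle(k_exchange=3e-3)
        res = simulate_dvs(proto, cfg)
        ts = default_model.tissue
        for rh, x in zip(res.rh, res.x_end):
            assert ts.water_activity(float(x), proto.T) == pytest.approx(
                rh, abs=1e-4
            )
        des = {round(r, 2): x for r, x, b in
               zip(res.rh, res.x_end, res.branch) if b == "desorption"}
        ads = {round(r, 2): x for r, x, b in
               zip(res.rh, res.x_end, res.branch) if b == "adsorption"}
        for rh in set(des) & set(ads):
            assert des[rh] == pytest.approx(ads[rh], abs=2e-4)

    def test_hysteresis_direction_with_slow_relaxation(self):
        """Frozen wall stress keeps the desorption branch above the
        adsorption branch at every shared humidity."""
        cfg = default_config()
        cfg.viscoelastic.slow.f_g = 0.1
        cfg.viscoelastic.fast.f_g = 3.0
        cfg.viscoelastic.slow.f_tau = 10.0
        cfg.viscoelastic.fast.f_tau = 100.0
        res = simulate_dvs(DvsProtocol.cycle(), cfg)
        des = {round(r, 2): x for r, x, b in
               zip(res.rh, res.x_end, res.branch) if b == "desorption"}
        ads = {round(r, 2): x for r, x, b in
               zip(res.rh, res.x_end, res.branch) if b == "adsorption"}
        shared = sorted(set(des) & set(ads))
        assert len(shared) >= 7
        assert all(des[r] >= ads[r] - 1e-12 for r in shared)
        # visibly open loop at the wet end
        assert des[0.8] - ads[0.8] > 0.01

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            DvsProtocol(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            DvsProtocol(np.array([0.5, 0.4]), dwell=-1.0)
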