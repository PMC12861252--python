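import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mushdry.config import ComponentSpec, ThermoConfig
from mushdry.thermo import (
    PhaseCoeffs,
    PhaseComposition,
    TissueSorption,
    mu_mix_water,
    partition_scalar,
    partition_vectorized,
    partition_water,
    water_activity_phase,
)

from oracles import brute_force_split

RT25 = 8.314462618 * 298.15


def comp(name="s", mass=1.0, density=1000.0, n=1.0, chi=0.0):
    return ComponentSpec(name, mass, density, n, chi)


class TestMuMixWater:
    @pytest.mark.parametrize(
        "water,components,expected_ln_aw",
        [
            # pure solvent limit
            (1.0, [comp(mass=0.0)], 0.0),
            # ideal athermal mixture: a_w = phi_w
            (1.0, [comp(mass=1.0)], math.log(0.5)),
            # polymer, 1/N = 0, chi = 0.5, phi_w = 0.8
            (0.8, [comp(mass=0.2, n=math.inf, chi=0.5)],
             math.log(0.8) + 0.2 + 0.5 * 0.04),
        ],
    )
    def test_closed_form_values(self, water, components, expected_ln_aw):
        phase = PhaseComposition(water, components, water_density=1000.0)
        mu = mu_mix_water(phase)
        assert mu == pytest.approx(RT25 * expected_ln_aw, abs=1e-9)

    def test_rejects_nonpositive_water(self):
        with pytest.raises(ValueError):
            mu_mix_water(PhaseComposition(0.0, [comp()]))

    def test_rejects_negative_mass(self):
        with pytest.raises(ValueError):
            PhaseComposition(1.0, [comp(mass=-0.1)])

    @given(
        phi_w=st.floats(0.05, 0.95),
        chi=st.floats(0.0, 0.5),
        n=st.floats(1.0, 50.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_nonpositive_for_moderate_chi(self, phi_w, chi, n):
        """RT ln a_w,mix <= 0 whenever chi <= 0.5 (activity below unity)."""
        phase = PhaseComposition(
            phi_w, [comp(mass=1.0 - phi_w, n=n, chi=chi)], water_density=1000.0
        )
        assert mu_mix_water(phase) <= 1e-12


class TestWaterActivityPhase:
    def test_zero_pressure_identity(self):
        phase = PhaseComposition(0.6, [comp(mass=0.4, n=5.0, chi=0.3)])
        aw0 = water_activity_phase(phase, 0.0)
        assert aw0 == pytest.approx(
            math.exp(mu_mix_water(phase) / (8.314462618 * phase.T))
        )

    def test_pressure_term_on_pure_water(self):
        # v_w p / RT = 1.8e-5 * 1e6 / (8.314*298.15)
        phase = PhaseComposition(1.0, [comp(mass=0.0)], T=298.15)
        aw = water_activity_phase(phase, 1.0e6)
        assert aw == pytest.approx(1.00729, abs=2e-5)

    def test_monotone_in_pressure(self):
        phase = PhaseComposition(0.7, [comp(mass=0.3, n=3.0, chi=0.2)])
        pressures = np.linspace(-5e6, 5e6, 7)
        aws = [water_activity_phase(phase, p) for p in pressures]
        assert np.all(np.diff(aws) > 0)

    def test_rejects_nonfinite_pressure(self):
        phase = PhaseComposition(0.7, [comp(mass=0.3)])
        with pytest.raises(ValueError):
            water_activity_phase(phase, math.nan)


class TestPartitionWater:
    def test_symmetric_phases_split_evenly(self):
        comps = [comp(mass=0.5, density=1500.0, n=5.0, chi=0.3)]
        split = partition_water(1.0, comps, comps, T=308.0)
        assert split.water1 == pytest.approx(split.water2, rel=1e-9)
        assert split.total_water == pytest.approx(1.0, rel=1e-12)
        assert split.residual <= 1e-9

    def test_empty_phase_gets_nothing(self):
        solutes = [comp(mass=0.5, density=1500.0, n=5.0, chi=0.3)]
        empty = [comp(mass=0.0, density=1500.0, n=math.inf, chi=0.5)]
        split = partition_water(1.0, solutes, empty, T=308.0)
        assert split.water1 == pytest.approx(1.0)
        assert split.water2 == 0.0
        assert split.residual == 0.0

    def test_matches_brute_force_free_energy_minimum(self):
        """Equal-activity bisection equals the 1e5-point free-energy argmin,
        including a chi = 0.8 polymer where several roots can exist."""
        solutes = [comp("mannitol", 0.5, 1500.0, 5.0, 0.3)]
        polymer = [comp("matrix", 0.5, 1500.0, math.inf, 0.8)]
        total_water = 1.0
        split = partition_water(total_water, solutes, polymer, T=308.0,
                                water_density=1000.0)
        f_model = split.water1 / total_water

        u_tot = total_water / 1000.0
        f_oracle = brute_force_split(
            u_tot,
            ([0.5 / 1500.0], [5.0], [0.3]),
            ([0.5 / 1500.0], [math.inf], [0.8]),
        )
        assert abs(f_model - f_oracle) <= 1.0 / 100_000 + 1e-9

    def test_mass_conservation_exact(self):
        solutes = [comp(mass=0.25, density=1500.0, n=5.0, chi=0.3)]
        polymer = [comp(mass=0.75, density=1500.0, n=math.inf, chi=0.5)]
        for w in (0.05, 0.4, 2.0, 9.0):
            split = partition_water(w, solutes, polymer, T=308.0)
            assert split.water1 + split.water2 == pytest.approx(w, rel=1e-12)
            assert split.water1 >= 0 and split.water2 >= 0

    def test_rejects_zero_water(self):
        with pytest.raises(ValueError):
            partition_water(0.0, [comp()], [comp()])


class TestVectorizedAndScalarPaths:
    """The fast paths must agree with the reference scalar route."""

    def test_vectorized_matches_partition_water(self):
        cfg = ThermoConfig()
        c1 = PhaseCoeffs.from_components(cfg.phase1, cfg.water_density)
        c2 = PhaseCoeffs.from_components(cfg.phase2, cfg.water_density)
        x = np.array([0.02, 0.1, 0.5, 2.0, 9.0])
        aw_vec, f_vec, _ = partition_vectorized(x, c1, c2, 308.15)
        for xi, awi, fi in zip(x, aw_vec, f_vec):
            split = partition_water(
                float(xi), cfg.phase1, cfg.phase2, T=308.15,
                water_density=cfg.water_density,
            )
            assert awi == pytest.approx(split.a_w, abs=1e-8)
            assert fi == pytest.approx(split.water1 / xi, abs=1e-7)

    def test_scalar_matches_vectorized(self):
        cfg = ThermoConfig()
        c1 = PhaseCoeffs.from_components(cfg.phase1, cfg.water_density)
        c2 = PhaseCoeffs.from_components(cfg.phase2, cfg.water_density)
        for xi in (0.03, 0.4, 3.0):
            aw_s, f_s, _ = partition_scalar(xi, c1, c2, 308.15,
                                            water_density=cfg.water_density)
            aw_v, f_v, _ = partition_vectorized(
                np.array([xi]), c1, c2, 308.15, water_density=cfg.water_density
            )
            assert aw_s == pytest.approx(float(aw_v[0]), abs=1e-9)
            assert f_s == pytest.approx(float(f_v[0]), abs=1e-8)


class TestSorptionIsotherm:
    def test_dilute_limit(self, default_model):
        aw = default_model.tissue.water_activity(50.0, 308.15)
        assert aw > 1.0 - 1e-3

    def test_round_trip_inversion(self, default_model):
        ts = default_model.tissue
        aw = ts.water_activity(1.0, 308.15)
        x_back = ts.moisture(aw, 308.15)
        assert x_back == pytest.approx(1.0, rel=1e-6)

    def test_strictly_increasing(self, default_model):
        ts = default_model.tissue
        xs = np.geomspace(0.02, 9.0, 10)
        aws = [ts.water_activity(float(x), 308.15) for x in xs]
        assert np.all(np.diff(aws) > 0)
        assert all(0.0 < a <= 1.0 for a in aws)

    def test_inverse_rejects_saturation(self, default_model):
        with pytest.raises(ValueError):
            default_model.tissue.moisture(1.0, 308.15)

    def test_compression_lowers_activity(self, default_model):
        """A negative (compressive) phase-2 stress shifts a_w down, which is
        the desorption side of the hysteresis loop."""
        ts = default_model.tissue
        aw_rel = ts.water_activity(0.3, 298.15)
        aw_cmp = ts.water_activity(0.3, 298.15, elastic_state=-2e7)
        assert aw_cmp < aw_rel
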