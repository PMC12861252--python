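"""Moving-grid finite-volume integration of the coupled drying balances.

The mushroom (hemispherical cap plus a dual-porosity lamella layer at its
base) is discretized into control volumes of fixed solid mass; volumes,
porosities and positions are recomputed every evaluation from the local
moisture content through the shrinkage law (Lagrangian, "ideal shrinkage"
coordinates).  Conserved variables per control volume are the total moisture
mass and the total energy (enthalpy referenced to 0 degC); liquid/vapor
split, temperature and water activity follow algebraically from local vapor
equilibrium.  Interior transport is diffusive (liquid in the matrix, vapor in
the pores) plus conduction and the sensible/latent enthalpy carried by the
mass fluxes; both the outer cap surface and the exposed lamella face exchange
with ambient air through convective/radiative heat transfer and a
Lewis-relation mass-transfer coefficient.

The semi-discrete system is in flux form, so interior mass and energy are
conserved to round-off by the explicit stepper and to solver tolerance by the
adaptive BDF integrator used in :func:`DryingModel.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .config import GAS_CONSTANT, ModelConfig, default_config
from .structure import ShrinkageModel
from .thermo import PhaseCoeffs, TissueSorption, partition_vectorized
from .transport import (
    exchange_coefficients,
    mutual_diffusivity_theory,
    thermodynamic_factor,
)
from .viscoelastic import material_functions

__all__ = ["Grid", "AmbientSchedule", "DryingResult", "DryingModel", "build_grid"]


# ---------------------------------------------------------------------------
# ambient schedule
# ---------------------------------------------------------------------------


@dataclass
class AmbientSchedule:
    """Piecewise-linear time series of air temperature, RH and velocity."""

    t: np.ndarray  # s
    T_air: np.ndarray  # K
    rh: np.ndarray  # [0, 1]
    u_air: np.ndarray  # m/s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.T_air = np.asarray(self.T_air, dtype=float)
        self.rh = np.asarray(self.rh, dtype=float)
        self.u_air = np.asarray(self.u_air, dtype=float)
        if np.any(self.rh < 0) or np.any(self.rh > 1):
            raise ValueError("RH must lie in [0, 1]")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("times must be non-decreasing")

    @classmethod
    def constant(
        cls, T_air: float, rh: float, u_air: float, t_end: float
    ) -> "AmbientSchedule":
        t = np.array([0.0, t_end])
        return cls(t, np.full(2, T_air), np.full(2, rh), np.full(2, u_air))

    def __call__(self, t: float) -> tuple[float, float, float]:
        return (
            float(np.interp(t, self.t, self.T_air)),
            float(np.interp(t, self.t, self.rh)),
            float(np.interp(t, self.t, self.u_air)),
        )

    @property
    def nominal_T_air(self) -> float:
        return float(np.median(self.T_air))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t / 3600.0,
                "T_air_C": self.T_air - 273.15,
                "RH": self.rh,
                "u_air_m_s": self.u_air,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "AmbientSchedule":
        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy() * 3600.0,
            df["T_air_C"].to_numpy() + 273.15,
            df["RH"].to_numpy(),
            df["u_air_m_s"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass
class Grid:
    """Lagrangian control volumes: fixed solid mass, moving geometry."""

    solid_mass: np.ndarray  # kg per CV, constant in time
    is_lamella: np.ndarray  # bool per CV; lamella CVs sit at the r=0 end
    hyphae_fraction_lamella: float = 0.5

    @property
    def n(self) -> int:
        return len(self.solid_mass)

    @property
    def n_lam(self) -> int:
        return int(self.is_lamella.sum())

    @property
    def total_solid(self) -> float:
        return float(self.solid_mass.sum())


def build_grid(config: ModelConfig) -> Grid:
    """Discretize the fresh mushroom into equal-solid-mass control volumes.

    The chain runs lamella face -> lamella CVs -> cap shells (inner to outer)
    -> cap surface; both chain ends exchange with the ambient air.
    """
    sc = config.solver
    if sc.n_cap < 2 or sc.n_lam < 0 or sc.n_cap + sc.n_lam < 4:
        raise ValueError("need at least 4 control volumes (n_cap >= 2)")
    m_solid = sc.fresh_mass / (1.0 + sc.x_m0)
    m_lam = sc.lamella_solid_fraction * m_solid if sc.n_lam > 0 else 0.0
    m_cap = m_solid - m_lam
    masses = np.concatenate(
        [
            np.full(sc.n_lam, m_lam / max(sc.n_lam, 1)),
            np.full(sc.n_cap, m_cap / sc.n_cap),
        ]
    )
    if np.any(masses <= 0):
        raise ValueError("infeasible geometry: non-positive solid mass per CV")
    is_lam = np.zeros(len(masses), dtype=bool)
    is_lam[: sc.n_lam] = True
    return Grid(masses, is_lam, sc.lamella_hyphae_fraction)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class DryingResult:
    """Time series and radial profiles produced by a drying simulation."""

    t: np.ndarray  # s
    y_w: np.ndarray  # average moisture, wet basis
    x_m: np.ndarray  # average moisture, dry basis
    T_center: np.ndarray  # K
    T_surface: np.ndarray  # K
    aw_center: np.ndarray
    aw_surface: np.ndarray
    profiles: pd.DataFrame  # long format: time_h, r_m, aw, T_C, phi_air
    balances: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t / 3600.0,
                "yw_wb": self.y_w,
                "Xm_db": self.x_m,
                "T_center_C": self.T_center - 273.15,
                "T_surface_C": self.T_surface - 273.15,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class DryingModel:
    """Couples thermodynamics, viscoelasticity, shrinkage and transport.

    The object precomputes composition coefficients and a spline of the
    relaxed-state thermodynamic factor; the fitted factors (emissivity,
    F_w,conv, F_w,diff, F_G,i, F_tau,i) may be mutated on ``config`` between
    simulations, which the calibration module exploits.
    """

    T_MIN, T_MAX = 252.0, 398.0  # clip range for property evaluations, K

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or default_config()
        tc = self.config.thermo
        self.tissue = TissueSorption(tc)
        self.coeffs1: PhaseCoeffs = self.tissue.coeffs1
        self.coeffs2: PhaseCoeffs = self.tissue.coeffs2
        self.shrink = ShrinkageModel(self.config.structure)
        self.grid = build_grid(self.config)
        self._gamma_spline = self._build_gamma_spline()
        self._f0_spline = self._build_split_spline()
        self._center_index: int | None = None

    # -- precomputation ----------------------------------------------------

    def _build_gamma_spline(self) -> CubicSpline:
        """Relaxed-state thermodynamic factor vs log10 X_m.

        The viscoelastic contribution to Gamma is secondary and would make
        the factor state-dependent; the relaxed curve is used for transport.
        """
        logx = np.linspace(-4.0, 1.5, 140)
        gam = thermodynamic_factor(10.0**logx, self.tissue, 308.15)
        gam = np.maximum(gam, self.config.transport.gamma_floor)
        return CubicSpline(logx, gam)

    def _build_split_spline(self) -> CubicSpline:
        """Relaxed-state phase-1 water fraction vs log10 X_m.

        Serves as the warm start for the Newton partition solve inside the
        right-hand side; the viscoelastic shift of the root is small.
        """
        logx = np.linspace(-4.0, 1.5, 140)
        _, f_rel, _ = partition_vectorized(
            10.0**logx,
            self.coeffs1,
            self.coeffs2,
            308.15,
            None,
            v_w=self.config.thermo.v_w,
            water_density=self.config.thermo.water_density,
        )
        return CubicSpline(logx, f_rel)

    def gamma(self, x_m: np.ndarray) -> np.ndarray:
        logx = np.clip(np.log10(np.maximum(x_m, 1e-12)), -4.0, 1.5)
        return np.maximum(
            self._gamma_spline(logx), self.config.transport.gamma_floor
        )

    # -- thermophysical helpers (clipped, vector-safe) ---------------------

    def _p_sat(self, T: np.ndarray) -> np.ndarray:
        T = np.clip(T, self.T_MIN, self.T_MAX)
        return 133.322387415 * 10.0 ** (8.07131 - 1730.63 / (233.426 + T - 273.15))

    def _c_sat(self, T: np.ndarray) -> np.ndarray:
        return self.config.transport.m_v * self._p_sat(T) / (
            GAS_CONSTANT * np.clip(T, self.T_MIN, self.T_MAX)
        )

    # -- state layout ------------------------------------------------------
    # y = [M (N), Q (N), phi_ref_slow (N), phi_ref_fast (N), cum_mass_out,
    #      cum_energy_in]

    def pack(self, M, Q, phi1, phi2, cum=(0.0, 0.0)) -> np.ndarray:
        return np.concatenate([M, Q, phi1, phi2, np.asarray(cum, dtype=float)])

    def unpack(self, y: np.ndarray):
        n = self.grid.n
        return (
            y[:n],
            y[n : 2 * n],
            y[2 * n : 3 * n],
            y[3 * n : 4 * n],
            y[4 * n :],
        )

    # -- derived quantities -------------------------------------------------

    def derive(self, y: np.ndarray) -> SimpleNamespace:
        """Algebraic closure: geometry, split, temperature, activity, stress."""
        cfg = self.config
        tp = cfg.transport
        sc = cfg.solver
        g = self.grid
        M, Q, phi1, phi2, cum = self.unpack(y)
        M = np.maximum(M, 1e-15)
        phi1 = np.clip(phi1, 1e-6, 1.0)
        phi2 = np.clip(phi2, 1e-6, 1.0)
        ms = g.solid_mass

        m_vap = np.zeros_like(M)
        T = np.full_like(M, sc.t_init)
        for _ in range(2):
            m_liq = np.maximum(M - m_vap, 1e-3 * M)
            x_m = m_liq / ms
            v_ratio, phi_air, phi_w, phi_s = self.shrink.volumes(x_m)
            V = v_ratio * ms / cfg.structure.rho_solid  # hyphal tissue volume
            c_vol = (
                phi_s * cfg.structure.rho_solid * tp.cp_solid
                + phi_w * cfg.structure.rho_water * tp.cp_water
            )
            # first temperature estimate without the (tiny) vapor terms
            T = sc.t_ref + Q / (V * c_vol)
            T = np.clip(T, self.T_MIN, self.T_MAX)

            # viscoelastic stress closure for the activity partition
            g1, g2, tau1, tau2 = material_functions(
                np.maximum(x_m, 1e-9), T, cfg.viscoelastic
            )

            def pressure2(phi_s2, _g1=g1, _g2=g2, _p1=phi1, _p2=phi2):
                pt1 = phi_s2 / _p1
                pt2 = phi_s2 / _p2
                sigma = _g1 * (np.cbrt(pt1) - pt1) + _g2 * (np.cbrt(pt2) - pt2)
                return cfg.thermo.elastic_sign * sigma

            def dpressure2(phi_s2, _g1=g1, _g2=g2, _p1=phi1, _p2=phi2):
                dsig = _g1 * (np.cbrt(phi_s2 / _p1) ** -2 / (3.0 * _p1) - 1.0 / _p1)
                dsig += _g2 * (np.cbrt(phi_s2 / _p2) ** -2 / (3.0 * _p2) - 1.0 / _p2)
                return cfg.thermo.elastic_sign * dsig

            x_safe = np.maximum(x_m, 1e-9)
            f_guess = self._f0_spline(np.clip(np.log10(x_safe), -4.0, 1.5))
            a_w, f1, phi_s2 = partition_vectorized(
                x_safe,
                self.coeffs1,
                self.coeffs2,
                T,
                pressure2,
                v_w=cfg.thermo.v_w,
                water_density=cfg.thermo.water_density,
                f0=f_guess,
                dpressure2=dpressure2,
            )
            # refine temperature including vapor enthalpy, then update vapor
            for _ in range(2):
                c_v = a_w * self._c_sat(T)
                T = sc.t_ref + (Q / V - phi_air * c_v * tp.h_evap) / (
                    c_vol + phi_air * c_v * tp.cp_vapor
                )
                T = np.clip(T, self.T_MIN, self.T_MAX)
            c_v = a_w * self._c_sat(T)
            m_vap = phi_air * c_v * V

        c_w = np.where(phi_air < 1.0, phi_w * cfg.structure.rho_water / (1.0 - phi_air), 0.0)

        # geometry of the chain
        V_bulk = V.copy()
        lam = g.is_lamella
        if lam.any():
            V_bulk[lam] = V[lam] / g.hyphae_fraction_lamella
        v_cap = V_bulk[~lam]
        edges = np.concatenate(([0.0], np.cumsum(v_cap)))
        r_edges = (3.0 * edges / (2.0 * math.pi)) ** (1.0 / 3.0)
        radius = r_edges[-1]
        a_base = math.pi * radius**2
        # node coordinates along the chain (0 at lamella ambient face)
        n_lam = g.n_lam
        if n_lam > 0:
            thick = V_bulk[lam] / a_base
            lam_nodes = np.cumsum(thick) - 0.5 * thick
            lam_depth = thick.sum()
        else:
            lam_nodes = np.zeros(0)
            lam_depth = 0.0
        r_nodes_cap = (0.5 * (r_edges[:-1] ** 3 + r_edges[1:] ** 3)) ** (1.0 / 3.0)
        x_nodes = np.concatenate([lam_nodes, lam_depth + r_nodes_cap])

        # face areas: face i sits between CV i-1 and CV i; face 0 and face N
        # are the ambient faces (lamella and cap surface respectively)
        areas = np.empty(g.n + 1)
        f_h = g.hyphae_fraction_lamella
        areas[: n_lam + 1] = f_h * a_base  # lamella faces incl. junction
        areas[n_lam + 1 :] = 2.0 * math.pi * r_edges[1:] ** 2
        if n_lam == 0:
            areas[0] = 0.0  # hemisphere centre: no exchange face

        dist = np.empty(g.n + 1)
        dist[1:-1] = np.diff(x_nodes)
        dist[0] = x_nodes[0] if n_lam > 0 else 1.0
        dist[-1] = max(radius - r_nodes_cap[-1], 1e-6) + lam_depth * 0.0

        return SimpleNamespace(
            M=M, Q=Q, phi_ref=(phi1, phi2), x_m=x_m, m_liq=m_liq, m_vap=m_vap,
            V=V, V_bulk=V_bulk, phi_air=phi_air, phi_w=phi_w, phi_s=phi_s,
            T=T, a_w=a_w, c_w=c_w, c_v=c_v, phi_s2=phi_s2, f1=f1,
            tau=(tau1, tau2), radius=radius, areas=areas, dist=dist,
            x_nodes=x_nodes, cum=cum,
        )

    # -- fluxes -------------------------------------------------------------

    def _fluxes(self, d: SimpleNamespace, T_air: float, rh: float, u_air: float):
        """Per-face mass and energy fluxes (kg/s and W), positive outward
        (toward increasing chain coordinate)."""
        cfg = self.config
        tp = cfg.transport
        g = self.grid
        t0 = cfg.solver.t_ref

        # interior transport coefficients per CV
        gam = self.gamma(d.x_m)
        phi_wh = self._phi_w_hyphal(d.x_m)
        d_theory = mutual_diffusivity_theory(phi_wh, d.T, gam, tp)
        k_w = tp.f_w_diff * (1.0 - d.phi_air) * d_theory
        d_gas = tp.vapor_d0 * (d.T / 298.15) ** 1.75
        k_v = d.phi_air * d_gas
        lam_eff = (
            d.phi_s * tp.lambda_solid
            + d.phi_w * tp.lambda_water
            + d.phi_air * tp.lambda_air
        )

        n = g.n
        j_w = np.zeros(n + 1)  # kg/m2/s, positive outward along the chain
        j_v = np.zeros(n + 1)
        q_f = np.zeros(n + 1)  # W/m2 into the face direction (outward)

        # interior faces 1..n-1
        i = np.arange(n - 1)
        dx = d.dist[1:-1]
        kwf = 0.5 * (k_w[i] + k_w[i + 1])
        kvf = 0.5 * (k_v[i] + k_v[i + 1])
        lamf = 0.5 * (lam_eff[i] + lam_eff[i + 1])
        j_w[1:-1] = -kwf * (d.c_w[i + 1] - d.c_w[i]) / dx
        j_v[1:-1] = -kvf * (d.c_v[i + 1] - d.c_v[i]) / dx
        # upwind sensible/latent advection
        t_up_w = np.where(j_w[1:-1] >= 0, d.T[i], d.T[i + 1])
        t_up_v = np.where(j_v[1:-1] >= 0, d.T[i], d.T[i + 1])
        q_f[1:-1] = (
            j_w[1:-1] * tp.cp_water * (t_up_w - t0)
            + j_v[1:-1] * (tp.cp_vapor * (t_up_v - t0) + tp.h_evap)
            - lamf * (d.T[i + 1] - d.T[i]) / dx
        )

        # ambient faces: face 0 leaves through the lamella (toward -x, i.e.
        # outward means negative chain direction there), face n at the cap.
        ex = exchange_coefficients(tp, T_air, u_air)
        c_air = rh * self._c_sat(np.asarray(T_air))

        out0 = 0.0
        q0 = 0.0
        if g.n_lam > 0:
            cs0 = d.a_w[0] * self._c_sat(d.T[0])
            out0 = ex.beta_ext * (cs0 - c_air)  # kg/m2/s leaving CV 0
            q0 = ex.h_ext * (T_air - d.T[0]) - tp.h_evap * out0  # W/m2 into CV 0
        csn = d.a_w[-1] * self._c_sat(d.T[-1])
        outn = ex.beta_ext * (csn - c_air)
        qn = ex.h_ext * (T_air - d.T[-1]) - tp.h_evap * outn

        return SimpleNamespace(
            j_w=j_w, j_v=j_v, q_f=q_f, out0=out0, q0=q0, outn=outn, qn=qn
        )

    def _phi_w_hyphal(self, x_m: np.ndarray) -> np.ndarray:
        u = x_m / self.config.thermo.water_density
        v_dry = self.coeffs1.v_dry + self.coeffs2.v_dry
        return u / (u + v_dry)

    # -- right-hand side ----------------------------------------------------

    def rhs(
        self, t: float, y: np.ndarray, ambient: AmbientSchedule, exchange: bool = True
    ) -> np.ndarray:
        T_air, rh, u_air = ambient(t)
        d = self.derive(y)
        fl = self._fluxes(d, T_air, rh, u_air)
        g = self.grid
        n = g.n
        A = d.areas

        flow_m = (fl.j_w + fl.j_v) * A  # kg/s through each face, outward
        flow_q = fl.q_f * A  # W through each face, outward

        dM = np.zeros(n)
        dQ = np.zeros(n)
        # interior faces: flux leaves CV i through face i+1 into CV i+1
        dM[:-1] -= flow_m[1:-1]
        dM[1:] += flow_m[1:-1]
        dQ[:-1] -= flow_q[1:-1]
        dQ[1:] += flow_q[1:-1]

        mass_out = 0.0
        energy_in = 0.0
        if exchange:
            dM[0] -= fl.out0 * A[0]
            dQ[0] += fl.q0 * A[0]
            dM[-1] -= fl.outn * A[-1]
            dQ[-1] += fl.qn * A[-1]
            mass_out = fl.out0 * A[0] + fl.outn * A[-1]
            energy_in = fl.q0 * A[0] + fl.qn * A[-1]

        tau1, tau2 = d.tau
        dphi1 = (d.phi_s2 - d.phi_ref[0]) / tau1
        dphi2 = (d.phi_s2 - d.phi_ref[1]) / tau2

        return np.concatenate([dM, dQ, dphi1, dphi2, [mass_out, energy_in]])

    # -- public operations --------------------------------------------------

    def split_state(
        self,
        c_moisture: float,
        q: float,
        phi_air: float,
        phi_s: float,
        phi_ref: tuple[float, float] | None = None,
        tol: float = 1e-9,
    ) -> tuple[float, float, float, float]:
        """Recover (c_w, c_v, T, a_w) from conserved densities in one CV.

        Solves the algebraic pair {total-moisture closure, energy closure}
        with local vapor equilibrium by fixed-point iteration; the vapor
        holds far below a percent of the moisture so convergence is fast.
        """
        if c_moisture <= 0 or not math.isfinite(q):
            raise ValueError("need positive moisture and finite energy density")
        cfg = self.config
        tp = cfg.transport
        c_vol = (
            phi_s * cfg.structure.rho_solid * tp.cp_solid
        )
        c_v = 0.0
        c_w = c_moisture / max(1.0 - phi_air, 1e-12)
        T = cfg.solver.t_init
        for _ in range(100):
            c_w_new = (c_moisture - phi_air * c_v) / max(1.0 - phi_air, 1e-12)
            x_m = c_w_new * (1.0 - phi_air) / max(phi_s * cfg.structure.rho_solid, 1e-12)
            phi_w = c_w_new * (1.0 - phi_air) / cfg.structure.rho_water
            heat = c_vol + phi_w * cfg.structure.rho_water * tp.cp_water
            if phi_ref is None:
                a_w = self.tissue.water_activity(max(x_m, 1e-9), max(T, 260.0))
            else:
                g1, g2, _, _ = material_functions(max(x_m, 1e-9), T, cfg.viscoelastic)
                pr = np.array([[phi_ref[0]], [phi_ref[1]]])
                a_w, _, _ = partition_vectorized(
                    np.array([max(x_m, 1e-9)]), self.coeffs1, self.coeffs2, T,
                    lambda ps2: cfg.thermo.elastic_sign
                    * (g1 * (np.cbrt(ps2 / pr[0]) - ps2 / pr[0])
                       + g2 * (np.cbrt(ps2 / pr[1]) - ps2 / pr[1])),
                )
                a_w = float(a_w[0])
            T_new = cfg.solver.t_ref + (q - phi_air * c_v * tp.h_evap) / (
                heat + phi_air * c_v * tp.cp_vapor
            )
            c_v_new = a_w * float(self._c_sat(np.asarray(T_new)))
            if (
                abs(c_w_new - c_w) <= tol * max(abs(c_w_new), 1.0)
                and abs(T_new - T) <= tol * T_new
            ):
                c_w, T, c_v = c_w_new, T_new, c_v_new
                break
            c_w, T, c_v = c_w_new, T_new, c_v_new
        return c_w, c_v, T, a_w

    def compose_state(
        self, c_w: float, T: float, phi_air: float, phi_s: float,
        phi_ref: tuple[float, float] | None = None,
    ) -> tuple[float, float]:
        """Inverse of :meth:`split_state`: (c_moisture, q) from (c_w, T)."""
        cfg = self.config
        tp = cfg.transport
        x_m = c_w * (1.0 - phi_air) / (phi_s * cfg.structure.rho_solid)
        if phi_ref is None:
            a_w = self.tissue.water_activity(max(x_m, 1e-9), T)
        else:
            g1, g2, _, _ = material_functions(max(x_m, 1e-9), T, cfg.viscoelastic)
            pr = phi_ref
            a_w_arr, _, _ = partition_vectorized(
                np.array([max(x_m, 1e-9)]), self.coeffs1, self.coeffs2, T,
                lambda ps2: cfg.thermo.elastic_sign
                * (g1 * (np.cbrt(ps2 / pr[0]) - ps2 / pr[0])
                   + g2 * (np.cbrt(ps2 / pr[1]) - ps2 / pr[1])),
            )
            a_w = float(a_w_arr[0])
        c_v = a_w * float(self._c_sat(np.asarray(T)))
        c_moisture = (1.0 - phi_air) * c_w + phi_air * c_v
        phi_w = c_w * (1.0 - phi_air) / cfg.structure.rho_water
        heat = (
            phi_s * cfg.structure.rho_solid * tp.cp_solid
            + phi_w * cfg.structure.rho_water * tp.cp_water
            + phi_air * c_v * tp.cp_vapor
        )
        q = heat * (T - cfg.solver.t_ref) + phi_air * c_v * tp.h_evap
        return c_moisture, q

    def initial_state(self) -> np.ndarray:
        """Uniform fresh state: X_m0, T_init, fully relaxed cell walls."""
        sc = self.config.solver
        g = self.grid
        ms = g.solid_mass
        x0 = np.full(g.n, sc.x_m0)
        v_ratio, phi_air, phi_w, phi_s = self.shrink.volumes(x0)
        V = v_ratio * ms / self.config.structure.rho_solid
        tp = self.config.transport
        aw0, _, phi_s2 = partition_vectorized(
            x0, self.coeffs1, self.coeffs2, sc.t_init, None,
            v_w=self.config.thermo.v_w,
            water_density=self.config.thermo.water_density,
        )
        c_v = aw0 * self._c_sat(np.full(g.n, sc.t_init))
        c_vol = (
            phi_s * self.config.structure.rho_solid * tp.cp_solid
            + phi_w * self.config.structure.rho_water * tp.cp_water
        )
        Q = V * (
            (c_vol + phi_air * c_v * tp.cp_vapor) * (sc.t_init - sc.t_ref)
            + phi_air * c_v * tp.h_evap
        )
        M = ms * x0 + phi_air * c_v * V
        return self.pack(M, Q, phi_s2, phi_s2.copy())

    def step(
        self,
        y: np.ndarray,
        t: float,
        ambient: AmbientSchedule,
        dt: float,
        exchange: bool = True,
    ) -> np.ndarray:
        """One explicit flux-form step of size dt.

        Mass and energy are updated in conservative flux form (interior
        telescoping is exact to round-off); the viscoelastic internal
        variables advance with the exact exponential integrator.
        """
        if dt < 0:
            raise ValueError("dt must be non-negative")
        rate = self.rhs(t, y, ambient, exchange=exchange)
        M, Q, phi1, phi2, cum = self.unpack(y)
        dM, dQ, dphi1, dphi2, dcum = self.unpack(rate)
        d = self.derive(y)
        tau1, tau2 = d.tau
        e1 = np.exp(-dt / tau1)
        e2 = np.exp(-dt / tau2)
        return self.pack(
            M + dt * dM,
            Q + dt * dQ,
            d.phi_s2 + (phi1 - d.phi_s2) * e1,
            d.phi_s2 + (phi2 - d.phi_s2) * e2,
            cum + dt * dcum,
        )

    def _jac_sparsity(self):
        n = self.grid.n
        m = 4 * n + 2
        s = np.zeros((m, m), dtype=bool)
        for b_row in range(4):
            for b_col in range(4):
                rows = np.arange(n) + b_row * n
                cols = np.arange(n) + b_col * n
                s[rows, cols] = True
                s[rows[:-1], cols[1:]] = True
                s[rows[1:], cols[:-1]] = True
        # boundary quadratures depend only on the two ambient-facing CVs
        for b_col in range(4):
            s[4 * n :, b_col * n] = True
            s[4 * n :, b_col * n + n - 1] = True
        s[4 * n, 4 * n] = True
        s[4 * n + 1, 4 * n + 1] = True
        return s

    def center_index(self) -> int:
        """CV reported as 'center': farthest along the chain from both
        ambient faces on the initial geometry."""
        if self._center_index is None:
            d = self.derive(self.initial_state())
            x = d.x_nodes
            total = d.x_nodes[-1] + d.dist[-1]
            score = np.minimum(x, total - x)
            if self.grid.n_lam == 0:
                score = total - x
            self._center_index = int(np.argmax(score))
        return self._center_index

    def simulate(
        self,
        ambient: AmbientSchedule,
        t_end: float,
        t_eval: np.ndarray | None = None,
        profile_times: np.ndarray | None = None,
    ) -> DryingResult:
        """Integrate the drying run with adaptive implicit (BDF) stepping."""
        sc = self.config.solver
        g = self.grid
        y0 = self.initial_state()
        if t_eval is None:
            t_eval = np.linspace(0.0, t_end, 121)
        t_eval = np.asarray(t_eval, dtype=float)
        atol = self.pack(
            np.full(g.n, sc.atol_moisture),
            np.full(g.n, sc.atol_energy),
            np.full(g.n, sc.atol_phiref),
            np.full(g.n, sc.atol_phiref),
            (1e-9, 1e-3),
        )
        sol = solve_ivp(
            lambda t, y: self.rhs(t, y, ambient),
            (0.0, t_end),
            y0,
            method="BDF",
            t_eval=t_eval,
            rtol=sc.rtol,
            atol=atol,
            jac_sparsity=self._jac_sparsity(),
            max_step=sc.max_step,
        )
        if not sol.success:
            raise RuntimeError(f"drying integration failed: {sol.message}")

        ic = self.center_index()
        n_t = sol.y.shape[1]
        y_w = np.empty(n_t)
        x_m = np.empty(n_t)
        t_c = np.empty(n_t)
        t_s = np.empty(n_t)
        aw_c = np.empty(n_t)
        aw_s = np.empty(n_t)
        prof_rows = []
        profile_times = (
            np.asarray(profile_times, dtype=float)
            if profile_times is not None
            else np.array([])
        )
        for k in range(n_t):
            d = self.derive(sol.y[:, k])
            m_total = float(d.M.sum())
            y_w[k] = m_total / (m_total + g.total_solid)
            x_m[k] = m_total / g.total_solid
            t_c[k] = d.T[ic]
            t_s[k] = d.T[-1]
            aw_c[k] = d.a_w[ic]
            aw_s[k] = d.a_w[-1]
            if profile_times.size and np.any(
                np.isclose(sol.t[k], profile_times, rtol=0, atol=1.0)
            ):
                for j in range(g.n):
                    prof_rows.append(
                        (
                            sol.t[k] / 3600.0,
                            d.x_nodes[j],
                            d.a_w[j],
                            d.T[j] - 273.15,
                            d.phi_air[j],
                        )
                    )
        profiles = pd.DataFrame(
            prof_rows, columns=["time_h", "r_m", "aw", "T_C", "phi_air"]
        )

        d0 = self.derive(y0)
        d_end = self.derive(sol.y[:, -1])
        cum = self.unpack(sol.y[:, -1])[4]
        m0, m_end = float(d0.M.sum()), float(d_end.M.sum())
        balances = {
            "moisture_initial_kg": m0,
            "moisture_final_kg": m_end,
            "boundary_outflow_kg": float(cum[0]),
            "moisture_closure_rel": (m_end - m0 + float(cum[0])) / m0,
            "energy_initial_J": float(d0.Q.sum()),
            "energy_final_J": float(d_end.Q.sum()),
            "boundary_energy_in_J": float(cum[1]),
            "energy_closure_rel": (
                float(d_end.Q.sum()) - float(d0.Q.sum()) - float(cum[1])
            )
            / max(abs(float(d0.Q.sum())), 1.0),
        }
        return DryingResult(
            sol.t, y_w, x_m, t_c, t_s, aw_c, aw_s, profiles, balances
        )
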