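"""Constitutive transport properties and external exchange coefficients.

Saturation vapor pressure (Antoine correlation for water, 1-100 degC),
equilibrium vapor concentration, free-volume moisture diffusivity with a
Darken-type thermodynamic factor, binary vapor-in-air diffusivity (T^1.75
scaling), composition-weighted effective thermal conductivity, and the
boundary-layer heat/mass exchange coefficients (linearized radiation, a
flat-surface convection rule of thumb, and the Lewis relation for mass
transfer).  The fitted corrections F_w,diff and F_w,conv and the oven-wall
emissivity e enter here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import GAS_CONSTANT, TransportConfig
from .thermo import TissueSorption

__all__ = [
    "p_sat",
    "c_sat",
    "vapor_concentration",
    "moisture_diffusivity",
    "thermodynamic_factor",
    "vapor_diffusivity",
    "thermal_conductivity",
    "exchange_coefficients",
    "ExchangeCoefficients",
    "wet_bulb_temperature",
]

# Antoine constants for water, p in mmHg and T in degC, valid 1-100 degC
_ANTOINE_A = 8.07131
_ANTOINE_B = 1730.63
_ANTOINE_C = 233.426
_MMHG = 133.322387415


def p_sat(T):
    """Saturation vapor pressure of water (Pa) at temperature T (K)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 250.0) or np.any(T >= 400.0):
        raise ValueError("temperature outside the 250-400 K validity range")
    t_c = T - 273.15
    p = _MMHG * 10.0 ** (_ANTOINE_A - _ANTOINE_B / (_ANTOINE_C + t_c))
    if p.ndim == 0:
        return float(p)
    return p


def c_sat(T, m_v: float = 0.018):
    """Saturated vapor concentration (kg/m3) from the ideal-gas law."""
    return m_v * p_sat(T) / (GAS_CONSTANT * np.asarray(T, dtype=float))


def vapor_concentration(a_w, T, m_v: float = 0.018):
    """Equilibrium vapor concentration c_v = a_w M_v p_sat / (R T), kg/m3."""
    a_w = np.asarray(a_w, dtype=float)
    if np.any(a_w < 0) or np.any(a_w > 1.0 + 1e-12):
        raise ValueError("a_w must lie in [0, 1]")
    return a_w * c_sat(T, m_v)


def thermodynamic_factor(
    x_m, tissue: TissueSorption, T: float = 298.15, rel_step: float = 1e-4
):
    """Gamma = d ln a_w / d ln phi_w of the relaxed tissue isotherm.

    Evaluated by central finite differences in log-moisture; phi_w is the
    water volume fraction of the hyphal material.
    """
    x = np.asarray(x_m, dtype=float)

    def one(xv: float) -> float:
        lo, hi = xv * (1.0 - rel_step), xv * (1.0 + rel_step)
        d_ln_aw = math.log(tissue.water_activity(hi, T)) - math.log(
            tissue.water_activity(lo, T)
        )
        d_ln_phi = math.log(tissue.phi_w_tissue(hi)) - math.log(
            tissue.phi_w_tissue(lo)
        )
        return d_ln_aw / d_ln_phi

    if x.ndim == 0:
        return one(float(x))
    return np.array([one(v) for v in x])


def mutual_diffusivity_theory(phi_w_hyphal, T, gamma, params: TransportConfig):
    """Darken-type mutual moisture diffusivity of the hyphal material (m2/s).

    D = (phi_s D_w,self + phi_w D_s,self) * Gamma with free-volume
    self-diffusivities D_self = d_dilute (T/298.15) 10^(fv_slope phi_s^2);
    the quadratic exponent keeps the wet regime near the dilute limit while
    collapsing the glassy-dry mobility by many decades.  Gamma is floored:
    the theta-solvent vanishing of the osmotic modulus at high hydration is
    an artifact of the continuum picture for cellular tissue.
    """
    phi_w = np.asarray(phi_w_hyphal, dtype=float)
    phi_s = 1.0 - phi_w
    d_w_self = params.d_dilute * (np.asarray(T, float) / 298.15) * 10.0 ** (
        params.fv_slope * phi_s**2
    )
    gamma = np.maximum(np.asarray(gamma, dtype=float), params.gamma_floor)
    return (phi_s * d_w_self + phi_w * params.solute_self_ratio * d_w_self) * gamma


def moisture_diffusivity(
    x_m,
    T,
    params: TransportConfig,
    tissue: TissueSorption | None = None,
    gamma=None,
):
    """Effective liquid-moisture diffusivity F_w,diff * D_theory (m2/s).

    ``gamma`` may be supplied precomputed (the solver passes a spline of the
    relaxed-state thermodynamic factor); otherwise it is evaluated from
    ``tissue`` by finite differences.
    """
    x = np.asarray(x_m, dtype=float)
    if np.any(x <= 0):
        raise ValueError("moisture content must be positive")
    if tissue is None:
        tissue = TissueSorption()
    u = x / tissue.config.water_density
    v_dry = tissue.coeffs1.v_dry + tissue.coeffs2.v_dry
    phi_w = u / (u + v_dry)
    if gamma is None:
        gamma = thermodynamic_factor(x, tissue, T if np.ndim(T) == 0 else 298.15)
    out = params.f_w_diff * mutual_diffusivity_theory(phi_w, T, gamma, params)
    if out.ndim == 0:
        return float(out)
    return out


def vapor_diffusivity(T, P: float = 101325.0, params: TransportConfig | None = None):
    """Binary diffusivity of water vapor in air (m2/s), T^1.75 scaling."""
    d0 = (params or TransportConfig()).vapor_d0
    out = d0 * (np.asarray(T, dtype=float) / 298.15) ** 1.75 * (101325.0 / P)
    if out.ndim == 0:
        return float(out)
    return out


def thermal_conductivity(phi_s, phi_w, phi_air, params: TransportConfig):
    """Volume-weighted parallel effective conductivity (W/m/K)."""
    total = np.asarray(phi_s) + np.asarray(phi_w) + np.asarray(phi_air)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("volume fractions must sum to one")
    out = (
        np.asarray(phi_s) * params.lambda_solid
        + np.asarray(phi_w) * params.lambda_water
        + np.asarray(phi_air) * params.lambda_air
    )
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class ExchangeCoefficients:
    """External heat/mass exchange: h_ext = h_rad + h_conv; beta by Lewis."""

    h_rad: float
    h_conv: float
    h_ext: float
    beta_ext: float


def exchange_coefficients(
    params: TransportConfig, T_wall: float, u_air: float
) -> ExchangeCoefficients:
    """Boundary-layer exchange coefficients.

    h_rad = e 4 sigma T_wall^3 (linearized radiation), h_conv = 6 + 10 u_air
    (flat-surface rule of thumb), and beta_ext = F_w,conv h_conv / (rho_air
    c_p,air) via the Lewis relation.  beta uses h_conv, not h_ext: radiation
    transfers heat but no mass.
    """
    if u_air < 0:
        raise ValueError("air velocity must be non-negative")
    h_rad = params.emissivity * 4.0 * params.sigma_sb * T_wall**3
    h_conv = 6.0 + 10.0 * u_air
    beta = params.f_w_conv * h_conv / (params.rho_air * params.cp_air)
    return ExchangeCoefficients(h_rad, h_conv, h_rad + h_conv, beta)


def wet_bulb_temperature(
    T_air: float,
    rh: float,
    u_air: float,
    params: TransportConfig | None = None,
    include_radiation: bool = True,
) -> float:
    """Steady temperature of a freely evaporating saturated surface (K).

    Solves h_ext (T_air - T) = dH_evap beta_ext (c_sat(T) - RH c_sat(T_air))
    with the model's own exchange coefficients.  With ``include_radiation``
    False and F_w,conv = 1 this reduces to the classical psychrometric
    wet-bulb balance.
    """
    params = params or TransportConfig()
    c_air = rh * c_sat(T_air, params.m_v)
    ex = exchange_coefficients(params, T_air, u_air)
    h = ex.h_ext if include_radiation else ex.h_conv
    beta = ex.beta_ext

    def balance(T):
        return h * (T_air - T) - params.h_evap * beta * (c_sat(T, params.m_v) - c_air)

    return float(brentq(balance, 255.0, T_air, xtol=1e-8))
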