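"""Structured configuration for the drying model.

Every physical constant, regression coefficient and fitting factor used by the
package lives in one dataclass tree so that a run is fully described by a single
YAML file.  Units are SI throughout (kg, m, s, K, J, Pa); temperatures are kelvin
internally and converted to/from Celsius only at the I/O surface.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

GAS_CONSTANT = 8.314462618  # J/mol/K
T_REF_CELSIUS = 273.15  # enthalpy reference (0 degC), K


@dataclass
class ComponentSpec:
    """One dry-matter component of a thermodynamic phase.

    mass is kg per kg of *total* dry matter; size_ratio is the molar-volume
    ratio N_i relative to water (math.inf for crosslinked biopolymers, for
    which 1/N = 0); chi is the water-component Flory interaction parameter.
    """

    name: str
    mass: float
    density: float
    size_ratio: float
    chi: float


@dataclass
class ThermoConfig:
    """Two-phase composition (vacuole solutes vs. biopolymer matrix).

    The component inventory is a representative shiitake dry-matter breakdown:
    vacuolar solutes (mannitol, trehalose, ions) are phase 1, biopolymers
    (protein, cell-wall material) are phase 2.  The N/chi defaults are
    configurable placeholders, not measured values.
    """

    phase1: list[ComponentSpec] = field(
        default_factory=lambda: [
            ComponentSpec("mannitol", 0.12, 1500.0, 5.0, 0.3),
            ComponentSpec("trehalose", 0.08, 1500.0, 9.0, 0.4),
            ComponentSpec("ions", 0.05, 2000.0, 1.0, 0.0),
        ]
    )
    phase2: list[ComponentSpec] = field(
        default_factory=lambda: [
            ComponentSpec("protein", 0.20, 1350.0, math.inf, 0.5),
            ComponentSpec("cell_wall_material", 0.55, 1500.0, math.inf, 0.5),
        ]
    )
    v_w: float = 1.8e-5  # molar volume of water, m3/mol
    water_density: float = 998.0  # kg/m3
    # Sign convention for the phase-2 pressure term: p = elastic_sign * sigma.
    # +1 means compressive (negative) viscoelastic stress lowers a_w on drying.
    elastic_sign: float = 1.0
    partition_tol: float = 1e-9  # absolute tolerance on |a_w1 - a_w2|


@dataclass
class MaxwellModeConfig:
    """Coefficients of one Maxwell relaxation mode.

    Base modulus and relaxation time are log10-linear in moisture (dry basis):
      log10 G_base  = g_intercept  + g_slope  * X_m      (Pa, floored)
      log10 tau_base = tau_intercept + tau_slope * X_m   (s, floored)
    with an Arrhenius temperature factor exp(Ea/R (1/T - 1/T_ref)) on tau.
    The fitted scaling factors F_G and F_tau multiply these base values.
    """

    g_intercept: float = 8.0
    g_slope: float = -0.5
    log10_g_min: float = 3.0
    # steep moisture dependence: relaxation within minutes when wet but
    # effectively frozen (months to years) once the matrix turns glassy-dry
    tau_intercept: float = 7.5
    tau_slope: float = -5.0
    log10_tau_min: float = 1.0  # 10 s: effectively instant on drying scales
    ea: float = 6.0e4  # J/mol
    t_ref: float = 298.15
    f_g: float = 1.0
    f_tau: float = 1.0


@dataclass
class ViscoelasticConfig:
    # the fast mode softens and accelerates more steeply with moisture than
    # the slow one, so the two relaxation modes stay distinguishable
    slow: MaxwellModeConfig = field(default_factory=MaxwellModeConfig)
    fast: MaxwellModeConfig = field(
        default_factory=lambda: MaxwellModeConfig(
            g_intercept=7.0, g_slope=-1.3, tau_intercept=6.3, tau_slope=-5.5
        )
    )


@dataclass
class StructureConfig:
    """Empirical gas/solid volume-ratio law (shrinkage and porosity)."""

    exp_a: float = 8.637
    exp_b: float = 4.034
    exp_c: float = 6.674
    lin_m: float = 2.467
    lin_k: float = 4.33
    x_switch: float = 0.95
    blend: bool = False  # linearly blend the branches over [0.90, 1.00]
    blend_lo: float = 0.90
    blend_hi: float = 1.00
    rho_solid: float = 1500.0  # kg/m3
    rho_water: float = 998.0


@dataclass
class TransportConfig:
    """Constitutive transport properties and external exchange factors."""

    f_w_diff: float = 8.0  # fitted moisture-diffusivity correction
    f_w_conv: float = 5.0  # fitted convective mass-transfer correction
    emissivity: float = 0.9  # fitted oven-wall emissivity
    sigma_sb: float = 5.70e-8  # Stefan constant as used by the model, W/m2/K4
    m_v: float = 0.018  # kg/mol
    cp_solid: float = 1500.0  # J/kg/K
    cp_water: float = 4186.0
    cp_vapor: float = 1900.0
    cp_air: float = 1005.0
    rho_air: float = 1.2
    h_evap: float = 2.45e6  # J/kg
    lambda_solid: float = 0.2  # W/m/K
    lambda_water: float = 0.6
    lambda_air: float = 0.026
    # free-volume self-diffusivity of water:
    #   D_self = d_dilute * (T/298.15) * 10^(fv_slope * phi_s^2)
    d_dilute: float = 3.0e-9  # m2/s at 298.15 K, dilute limit
    fv_slope: float = -7.5
    solute_self_ratio: float = 0.3  # D_s,self / D_w,self
    gamma_floor: float = 0.5  # floor on the thermodynamic factor
    vapor_d0: float = 2.5e-5  # water vapor in air at 298.15 K, 1 atm, m2/s


@dataclass
class SolverConfig:
    n_cap: int = 18  # hemispherical-shell control volumes in the cap
    n_lam: int = 2  # dual-porosity lamella control volumes
    lamella_solid_fraction: float = 0.15  # share of total dry matter in the lamella
    lamella_hyphae_fraction: float = 0.5  # hyphal (non-gap) volume share of the lamella
    fresh_mass: float = 25e-3  # kg
    x_m0: float = 9.0  # initial moisture, dry basis
    t_init: float = 298.15  # K
    t_ref: float = T_REF_CELSIUS  # enthalpy reference
    rtol: float = 1e-6
    atol_moisture: float = 1e-10  # kg
    atol_energy: float = 1e-4  # J
    atol_phiref: float = 1e-9
    max_step: float = math.inf  # s


@dataclass
class ModelConfig:
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    viscoelastic: ViscoelasticConfig = field(default_factory=ViscoelasticConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)


def default_config() -> ModelConfig:
    cfg = ModelConfig()
    # the drying solver prefers the smooth porosity law; the structure module's
    # own default stays faithful to the printed two-branch form
    cfg.structure.blend = True
    return cfg


def _update_dataclass(obj: Any, data: dict) -> None:
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value)
        elif key in ("phase1", "phase2") and isinstance(value, list):
            setattr(obj, key, [ComponentSpec(**c) for c in value])
        else:
            setattr(obj, key, value)


def load_config(path: str | None = None) -> ModelConfig:
    """Return the default configuration, optionally updated from a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        _update_dataclass(cfg, data)
    return cfg


def config_to_dict(cfg: ModelConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: ModelConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
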