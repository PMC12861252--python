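"""Dual-mode Maxwell relaxation of the cell-wall matrix.

The wall stress that opposes cell shrinkage/swelling is carried by two Maxwell
modes (slow and fast).  Each mode tracks an internal reference polymer volume
fraction phi_ref,i that relaxes toward the current phase-2 polymer fraction
phi_s,

    d phi_ref,i / dt = (phi_s - phi_ref,i) / tau_0,i ,

and contributes an isotropic finite-strain stress

    sigma = sum_i G_i (phitilde_i^{1/3} - phitilde_i),   phitilde_i = phi_s / phi_ref,i.

Moduli and relaxation times are moisture-dependent (log-linear regressions,
shipped as configurable coefficients) with an Arrhenius temperature factor on
tau; fitted scaling factors F_G,i and F_tau,i multiply the base functions.
Temperature dependence of the modulus itself is neglected: the tissue glass
transition lies far below drying temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GAS_CONSTANT, MaxwellModeConfig, ViscoelasticConfig

__all__ = [
    "MaxwellState",
    "material_functions",
    "advance_state",
    "stress",
    "delta_mu_elastic",
]


@dataclass
class MaxwellState:
    """Internal reference volume fractions of the two relaxation modes.

    Fully relaxed means phi_ref,i equals the current phi_s (zero stress).
    Arrays are allowed so one state object can carry a whole grid.
    """

    phi_ref: np.ndarray  # shape (2,) or (2, n_cells)

    def __post_init__(self) -> None:
        self.phi_ref = np.asarray(self.phi_ref, dtype=float)
        if self.phi_ref.shape[0] != 2:
            raise ValueError("phi_ref must have leading dimension 2 (slow, fast)")
        if np.any(self.phi_ref <= 0) or np.any(self.phi_ref > 1):
            raise ValueError("phi_ref components must lie in (0, 1]")

    @classmethod
    def relaxed(cls, phi_s) -> "MaxwellState":
        phi_s = np.asarray(phi_s, dtype=float)
        return cls(np.stack([phi_s, phi_s.copy()]))


def _mode_g(mode: MaxwellModeConfig, x_m):
    log_g = np.maximum(mode.g_intercept + mode.g_slope * np.asarray(x_m, float),
                       mode.log10_g_min)
    return mode.f_g * 10.0 ** log_g


def _mode_tau(mode: MaxwellModeConfig, x_m, T):
    log_tau = np.maximum(mode.tau_intercept + mode.tau_slope * np.asarray(x_m, float),
                         mode.log10_tau_min)
    arrh = np.exp(mode.ea / GAS_CONSTANT * (1.0 / np.asarray(T, float) - 1.0 / mode.t_ref))
    return mode.f_tau * 10.0 ** log_tau * arrh


def material_functions(x_m, T, params: ViscoelasticConfig):
    """Moduli and relaxation times of both modes at (X_m, T).

    Returns (G_slow, G_fast, tau_slow, tau_fast); each is scalar or an array
    matching ``x_m``.  The scaling factors F_G,i / F_tau,i are applied here.
    """
    if np.any(np.asarray(x_m) <= 0):
        raise ValueError("moisture content must be positive")
    g1 = _mode_g(params.slow, x_m)
    g2 = _mode_g(params.fast, x_m)
    t1 = _mode_tau(params.slow, x_m, T)
    t2 = _mode_tau(params.fast, x_m, T)
    return g1, g2, t1, t2


def advance_state(state: MaxwellState, phi_s, taus, dt: float) -> MaxwellState:
    """Advance the internal variables over dt with phi_s held constant.

    The relaxation ODE is linear for frozen phi_s, so the exact exponential
    update phi_ref <- phi_s + (phi_ref - phi_s) exp(-dt/tau) is used; it is
    unconditionally stable and exact regardless of step size.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    taus = np.asarray(taus, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("relaxation times must be positive")
    phi_s = np.asarray(phi_s, dtype=float)
    decay = np.exp(-dt / taus)
    new = phi_s + (state.phi_ref - phi_s) * decay
    return MaxwellState(new)


def stress(state: MaxwellState, phi_s, g_modes) -> np.ndarray | float:
    """Total viscoelastic stress sigma (Pa) of both modes.

    sigma = sum_i G_i (phitilde^{1/3} - phitilde); zero at full relaxation,
    negative under compression (phi_s > phi_ref, i.e. drying).
    """
    phi_s = np.asarray(phi_s, dtype=float)
    g_modes = np.asarray(g_modes, dtype=float)
    if np.any(state.phi_ref <= 0):
        raise ValueError("phi_ref must be positive")
    phitilde = phi_s / state.phi_ref
    sig = (g_modes * (np.cbrt(phitilde) - phitilde)).sum(axis=0)
    if sig.ndim == 0:
        return float(sig)
    return sig


def delta_mu_elastic(sigma, v_w: float = 1.8e-5):
    """Elastic chemical-potential change, J/mol.

    With isotropic stress sigma = -Pi_elastic, delta_mu_elastic = v_w
    Pi_elastic = -v_w sigma.  The biopolymer-phase activity correction is
    v_w p = -delta_mu_elastic = +v_w sigma.
    """
    return -v_w * np.asarray(sigma, dtype=float)
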