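"""Independent reference computations used by the test suite.

These deliberately avoid the package's own code paths: brute-force free
energy minimization on a dense grid, explicit-Euler relaxation stepping, a
Magnus-formula psychrometric wet-bulb balance, and direct summation
formulas.  They exist so model results can be checked against a second,
structurally different route.
"""

from __future__ import annotations

import math

import numpy as np

R_GAS = 8.314462618


def fh_free_energy(u_w: float, v_i, n_i, chi_i) -> float:
    """Flory-Huggins mixing free energy of one phase, in units of RT/v_w.

    Direct evaluation of n_w ln phi_w + sum n_i ln phi_i + n_w sum chi phi_i
    with volumes instead of moles (common factor 1/v_w dropped).
    """
    v_i = np.asarray(v_i, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    chi_i = np.asarray(chi_i, dtype=float)
    v_tot = u_w + v_i.sum()
    g = 0.0
    if u_w > 0:
        phi_w = u_w / v_tot
        g += u_w * math.log(phi_w)
        g += u_w * float((chi_i * (v_i / v_tot)).sum())
    for v, n in zip(v_i, n_i):
        if math.isfinite(n) and v > 0:
            g += (v / n) * math.log(v / v_tot)
    return g


def brute_force_split(
    total_water_vol: float, phase1, phase2, n_grid: int = 100_000
) -> float:
    """Brute-force equal-activity split: argmin of total free energy.

    ``phase1``/``phase2`` are (v_i, n_i, chi_i) triples; returns the optimal
    phase-1 water volume fraction on an ``n_grid``-point scan.
    """
    f = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = np.empty(n_grid)
    for k, fk in enumerate(f):
        g[k] = fh_free_energy(fk * total_water_vol, *phase1) + fh_free_energy(
            (1 - fk) * total_water_vol, *phase2
        )
    return float(f[np.argmin(g)])


def euler_relaxation(phi_ref0: float, phi_s: float, tau: float, dt: float,
                     n_sub: int = 20000) -> float:
    """Fine-step explicit Euler integration of dphi_ref/dt=(phi_s-phi_ref)/tau."""
    h = dt / n_sub
    p = phi_ref0
    for _ in range(n_sub):
        p += h * (phi_s - p) / tau
    return p


def euler_richardson(phi_ref0: float, phi_s: float, tau: float, dt: float,
                     n_sub: int = 20000) -> float:
    """Richardson-extrapolated explicit Euler (error O(h^2)) for the
    relaxation ODE; an accurate independent reference at modest cost."""
    coarse = euler_relaxation(phi_ref0, phi_s, tau, dt, n_sub)
    fine = euler_relaxation(phi_ref0, phi_s, tau, dt, 2 * n_sub)
    return 2.0 * fine - coarse


def magnus_p_sat(T: float) -> float:
    """Magnus-formula saturation pressure of water (Pa), T in kelvin."""
    t_c = T - 273.15
    return 610.94 * math.exp(17.625 * t_c / (t_c + 243.04))


def magnus_c_sat(T: float, m_v: float = 0.018) -> float:
    return m_v * magnus_p_sat(T) / (R_GAS * T)


def psychrometric_wet_bulb(
    T_air: float,
    rh: float,
    h_ext: float,
    beta: float,
    h_evap: float = 2.45e6,
) -> float:
    """Wet-bulb balance h_ext (T_air - T) = dH beta (c_sat(T) - rh c_sat(T_air)).

    Solved by bisection with the Magnus saturation formula, independent of
    the package's Antoine correlation and solver.
    """
    c_air = rh * magnus_c_sat(T_air)

    def bal(T):
        return h_ext * (T_air - T) - h_evap * beta * (magnus_c_sat(T) - c_air)

    lo, hi = 255.0, T_air
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if bal(mid) * bal(lo) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
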