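"""Composition-based water activity of the two-phase hyphal system.

A mushroom hypha is approximated as two coexisting thermodynamic phases: the
vacuole holding all small solutes (phase 1) and the biopolymer matrix of
cytoplasm plus cell wall (phase 2).  The cell membrane between them passes
water but not solutes, so at local equilibrium water partitions such that both
phases have the same water activity.  Each phase follows multicomponent
Flory-Huggins mixing,

    ln a_w,mix = ln phi_w + sum_i (1 - 1/N_i) phi_i
                 + (sum_i chi_wi phi_i) (1 - phi_w),

with an optional pressure term v_w p on the chemical potential; for the
biopolymer phase this term carries the viscoelastic cell-wall stress, which is
how sorption hysteresis enters the isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import GAS_CONSTANT, ComponentSpec, ThermoConfig

__all__ = [
    "PhaseComposition",
    "PhaseSplit",
    "mu_mix_water",
    "water_activity_phase",
    "partition_water",
    "sorption_isotherm",
    "aw_to_moisture",
    "TissueSorption",
]


@dataclass
class PhaseComposition:
    """Component inventory of one thermodynamic phase.

    ``water`` and component masses share an arbitrary but common basis
    (conventionally kg per kg of total dry matter).  ``size_ratio`` N_i is the
    molar volume of component i relative to water (``math.inf`` for
    crosslinked polymers); ``chi`` is the pairwise water interaction
    parameter.
    """

    water: float
    components: Sequence[ComponentSpec]
    T: float = 298.15
    v_w: float = 1.8e-5
    water_density: float = 998.0

    def __post_init__(self) -> None:
        if self.water < 0:
            raise ValueError("water mass must be non-negative")
        for c in self.components:
            if c.mass < 0:
                raise ValueError(f"negative mass for component {c.name!r}")
            if c.size_ratio < 1:
                raise ValueError(f"size ratio N must be >= 1 for {c.name!r}")
            if c.density <= 0:
                raise ValueError(f"non-positive density for {c.name!r}")

    @property
    def dry_mass(self) -> float:
        return float(sum(c.mass for c in self.components))

    def volume_fractions(self) -> tuple[float, np.ndarray]:
        """Water and per-component volume fractions (they sum to one)."""
        v_w = self.water / self.water_density
        v_i = np.array([c.mass / c.density for c in self.components])
        total = v_w + v_i.sum()
        if total <= 0:
            raise ValueError("phase has zero volume")
        return v_w / total, v_i / total


def mu_mix_water(phase: PhaseComposition) -> float:
    """Flory-Huggins chemical potential of mixing per mole of water, J/mol.

    Returns RT ln a_w,mix; zero for pure water.
    """
    phi_w, phi_i = phase.volume_fractions()
    if phi_w <= 0:
        raise ValueError("water volume fraction must be positive")
    n = np.array([c.size_ratio for c in phase.components])
    chi = np.array([c.chi for c in phase.components])
    ln_aw = (
        math.log(phi_w)
        + float(((1.0 - 1.0 / n) * phi_i).sum())
        + float((chi * phi_i).sum()) * (1.0 - phi_w)
    )
    return GAS_CONSTANT * phase.T * ln_aw


def water_activity_phase(phase: PhaseComposition, pressure_term: float = 0.0) -> float:
    """Water activity of a single phase under pressure p (J/m3).

    a_w = exp[(mu_mix + v_w p) / (R T)].  For the biopolymer phase the caller
    passes the viscoelastic stress contribution v_w p = -delta_mu_elastic.
    """
    if not math.isfinite(pressure_term):
        raise ValueError("pressure term must be finite")
    mu = mu_mix_water(phase) + phase.v_w * pressure_term
    return math.exp(mu / (GAS_CONSTANT * phase.T))


# ---------------------------------------------------------------------------
# fast phase representation used by partitioning and by the drying solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseCoeffs:
    """Precomputed per-phase constants for fast ln a_w evaluation.

    With u the water volume (per kg dry matter) and V = v_dry + u,
    ln a_w,mix(u) = ln(u/V) + s_size/V + s_chi (1 - u/V)/V, where
    s_size = sum (1-1/N_i) v_i and s_chi = sum chi_i v_i.
    """

    v_dry: float  # m3 of dry components per basis mass
    s_size: float
    s_chi: float
    v_i: tuple[float, ...] = ()  # per-component volumes (for free energy)
    n_i: tuple[float, ...] = ()
    water_density: float = 998.0

    @classmethod
    def from_components(
        cls, components: Sequence[ComponentSpec], water_density: float = 998.0
    ) -> "PhaseCoeffs":
        v_i = np.array([c.mass / c.density for c in components], dtype=float)
        n = np.array([c.size_ratio for c in components], dtype=float)
        chi = np.array([c.chi for c in components], dtype=float)
        return cls(
            v_dry=float(v_i.sum()),
            s_size=float(((1.0 - 1.0 / n) * v_i).sum()),
            s_chi=float((chi * v_i).sum()),
            v_i=tuple(v_i),
            n_i=tuple(n),
            water_density=water_density,
        )

    def ln_aw_mix(self, u):
        """ln a_w,mix for water volume u (scalar or array, same basis)."""
        v = self.v_dry + u
        phi_w = u / v
        return np.log(phi_w) + self.s_size / v + self.s_chi * (1.0 - phi_w) / v

    def free_energy(self, u):
        """Flory-Huggins mixing free energy over (R T / v_w), same basis as u.

        g(u) = u ln phi_w + sum_i (v_i/N_i) ln phi_i + u s_chi / V.  Its
        derivative with respect to u is ln a_w,mix, so equal-activity splits
        are stationary points of the two-phase total.
        """
        u = np.asarray(u, dtype=float)
        v = self.v_dry + u
        out = np.where(u > 0, u * (np.log(np.maximum(u, 1e-300)) - np.log(v)), 0.0)
        for v_i, n_i in zip(self.v_i, self.n_i):
            if math.isfinite(n_i) and v_i > 0:
                out = out + (v_i / n_i) * (math.log(v_i) - np.log(v))
        out = out + u * self.s_chi / v
        return out


@dataclass
class PhaseSplit:
    """Result of equilibrating a fixed amount of water over the two phases."""

    water1: float
    water2: float
    a_w: float
    residual: float
    converged: bool = True

    @property
    def total_water(self) -> float:
        return self.water1 + self.water2


def _pressure_fn(elastic_state, coeffs2: PhaseCoeffs) -> Callable:
    """Normalize the elastic-state argument to a callable p(u2) in J/m3."""
    if elastic_state is None:
        return lambda u2: 0.0
    if callable(elastic_state):
        return elastic_state
    p_const = float(elastic_state)
    return lambda u2: p_const


def partition_water(
    total_water: float,
    phase1_dry: PhaseComposition | Sequence[ComponentSpec],
    phase2_dry: PhaseComposition | Sequence[ComponentSpec],
    elastic_state: float | Callable | None = None,
    T: float = 298.15,
    v_w: float = 1.8e-5,
    water_density: float = 998.0,
    tol: float = 1e-9,
    scan_points: int = 256,
) -> PhaseSplit:
    """Split ``total_water`` so that both phases have equal water activity.

    ``elastic_state`` is either a constant pressure p (J/m3) applied to phase
    2 or a callable ``p(phi_s2)`` evaluated self-consistently during the
    solve.  The residual ln a_w1 - ln a_w2 is monotone in the phase-1 water
    fraction for chi <= 0.5; for stronger interactions several equal-activity
    roots can exist and the one minimizing total free energy is returned.
    """
    if total_water <= 0:
        raise ValueError("total water must be positive")
    comps1 = phase1_dry.components if isinstance(phase1_dry, PhaseComposition) else phase1_dry
    comps2 = phase2_dry.components if isinstance(phase2_dry, PhaseComposition) else phase2_dry
    c1 = PhaseCoeffs.from_components(comps1, water_density)
    c2 = PhaseCoeffs.from_components(comps2, water_density)
    u_tot = total_water / water_density
    rt = GAS_CONSTANT * T

    if c1.v_dry <= 0 and c2.v_dry <= 0:
        raise ValueError("at least one phase needs dry matter")
    if c2.v_dry <= 0:
        aw = float(np.exp(c1.ln_aw_mix(u_tot)))
        return PhaseSplit(total_water, 0.0, aw, 0.0)
    if c1.v_dry <= 0:
        pfn = _pressure_fn(elastic_state, c2)
        phi_s2 = c2.v_dry / (c2.v_dry + u_tot)
        ln_aw = float(c2.ln_aw_mix(u_tot)) + v_w * _as_pressure(pfn, phi_s2) / rt
        return PhaseSplit(0.0, total_water, math.exp(ln_aw), 0.0)

    pfn = _pressure_fn(elastic_state, c2)

    def residual(f: np.ndarray) -> np.ndarray:
        u1 = f * u_tot
        u2 = u_tot - u1
        phi_s2 = c2.v_dry / (c2.v_dry + u2)
        p = np.asarray([_as_pressure(pfn, s) for s in np.atleast_1d(phi_s2)])
        if np.isscalar(phi_s2) or phi_s2.ndim == 0:
            p = p[0]
        return c1.ln_aw_mix(u1) - (c2.ln_aw_mix(u2) + v_w * p / rt)

    # coarse scan: locate sign changes and rank them by total free energy,
    # integrating the residual (= d g_total / d f up to a positive factor)
    eps = 1e-12
    f_grid = np.linspace(eps, 1.0 - eps, scan_points)
    r_grid = residual(f_grid)
    # cumulative trapezoid of the residual = free-energy profile up to a constant
    g_prof = np.concatenate(
        ([0.0], np.cumsum(0.5 * (r_grid[1:] + r_grid[:-1]) * np.diff(f_grid)))
    )
    sign = np.sign(r_grid)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        # no interior root: the optimum is at a boundary (all water one phase)
        k = int(np.argmin(g_prof))
        f_best = float(f_grid[k])
        converged = False
    else:
        candidates = []
        for i in idx:
            lo, hi = f_grid[i], f_grid[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if residual(np.array(mid)) * residual(np.array(lo)) <= 0:
                    hi = mid
                else:
                    lo = mid
            froot = 0.5 * (lo + hi)
            # free energy at the root, interpolated from the profile
            g_root = float(np.interp(froot, f_grid, g_prof))
            candidates.append((g_root, froot))
        candidates.sort()
        f_best = candidates[0][1]
        converged = True

    u1 = f_best * u_tot
    u2 = u_tot - u1
    phi_s2 = c2.v_dry / (c2.v_dry + u2)
    ln_a1 = float(c1.ln_aw_mix(np.array(u1)))
    ln_a2 = float(c2.ln_aw_mix(np.array(u2))) + v_w * _as_pressure(pfn, phi_s2) / rt
    a_w = math.exp(0.5 * (ln_a1 + ln_a2))
    res = abs(math.exp(ln_a1) - math.exp(ln_a2))
    converged = converged and res <= max(tol, 1e-12)
    return PhaseSplit(
        u1 * water_density, u2 * water_density, a_w, res, converged=converged
    )


def _as_pressure(pfn: Callable, phi_s2: float) -> float:
    try:
        return float(pfn(phi_s2))
    except TypeError:
        return float(pfn)


# ---------------------------------------------------------------------------
# vectorized partition used inside the drying solver
# ---------------------------------------------------------------------------


def _dln_aw_mix_du(coeffs: PhaseCoeffs, u):
    """Analytic derivative of ln a_w,mix with respect to water volume."""
    v = coeffs.v_dry + u
    return coeffs.v_dry / (u * v) - coeffs.s_size / v**2 - 2.0 * coeffs.s_chi * coeffs.v_dry / v**3


def partition_vectorized(
    x_m: np.ndarray,
    c1: PhaseCoeffs,
    c2: PhaseCoeffs,
    T: np.ndarray | float,
    pressure2: Callable[[np.ndarray], np.ndarray] | None = None,
    v_w: float = 1.8e-5,
    water_density: float = 998.0,
    f0: np.ndarray | None = None,
    dpressure2: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-activity split for arrays of moisture contents.

    ``pressure2(phi_s2)`` returns the phase-2 pressure term (J/m3) per cell;
    it may depend on the cell's viscoelastic state through a closure, with
    ``dpressure2`` its derivative with respect to phi_s2 (finite-differenced
    when omitted).  The monotone residual (guaranteed for chi <= 0.5 in the
    biopolymer phase) is solved by safeguarded Newton iteration, warm-started
    from ``f0`` when the caller has one (the solver keeps a relaxed-state
    spline); otherwise a short bisection localizes the root first.  Returns
    (a_w, f_phase1, phi_s2).
    """
    x_m = np.asarray(x_m, dtype=float)
    u_tot = x_m / water_density
    rt = GAS_CONSTANT * np.asarray(T, dtype=float)
    if pressure2 is None:
        pressure2 = lambda phi_s2: np.zeros_like(phi_s2)
        dpressure2 = lambda phi_s2: np.zeros_like(phi_s2)
    elif dpressure2 is None:
        def dpressure2(phi_s2, _p=pressure2):
            h = 1e-6
            return (_p(phi_s2 + h) - _p(phi_s2 - h)) / (2.0 * h)

    def resid_and_slope(f):
        u1 = np.maximum(f * u_tot, 1e-300)
        u2 = np.maximum(u_tot - u1, 1e-300)
        phi_s2 = c2.v_dry / (c2.v_dry + u2)
        p = pressure2(phi_s2)
        r = c1.ln_aw_mix(u1) - (c2.ln_aw_mix(u2) + v_w * p / rt)
        dphi_df = u_tot * phi_s2**2 / c2.v_dry
        dr = u_tot * (
            _dln_aw_mix_du(c1, u1) + _dln_aw_mix_du(c2, u2)
        ) - v_w * dpressure2(phi_s2) * dphi_df / rt
        return r, dr, phi_s2, p

    if f0 is None:
        lo = np.full_like(u_tot, 1e-12)
        hi = np.full_like(u_tot, 1.0 - 1e-12)
        r_lo, _, _, _ = resid_and_slope(lo)
        for _ in range(14):
            mid = 0.5 * (lo + hi)
            r_mid, _, _, _ = resid_and_slope(mid)
            take_lo = r_lo * r_mid <= 0
            hi = np.where(take_lo, mid, hi)
            lo = np.where(take_lo, lo, mid)
            r_lo = np.where(take_lo, r_lo, r_mid)
        f = 0.5 * (lo + hi)
    else:
        f = np.clip(np.broadcast_to(np.asarray(f0, float), u_tot.shape).copy(),
                    1e-9, 1.0 - 1e-9)

    for _ in range(7):
        r, dr, _, _ = resid_and_slope(f)
        stepped = f - r / np.maximum(dr, 1e-300)
        f = np.clip(stepped, 1e-12, 1.0 - 1e-12)
    r, dr, phi_s2, p = resid_and_slope(f)
    # rare safeguard: fall back to bisection where Newton failed to converge
    bad = ~(np.abs(r) < 1e-8)
    if np.any(bad):
        lo = np.full_like(u_tot, 1e-12)
        hi = np.full_like(u_tot, 1.0 - 1e-12)
        r_lo, _, _, _ = resid_and_slope(lo)
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            r_mid, _, _, _ = resid_and_slope(mid)
            take_lo = r_lo * r_mid <= 0
            hi = np.where(take_lo, mid, hi)
            lo = np.where(take_lo, lo, mid)
            r_lo = np.where(take_lo, r_lo, r_mid)
        f = np.where(bad, 0.5 * (lo + hi), f)
        r2, dr, phi_s2, p = resid_and_slope(f)

    u2 = (1.0 - f) * u_tot
    ln_a2 = c2.ln_aw_mix(np.maximum(u2, 1e-300)) + v_w * p / rt
    return np.exp(ln_a2), f, phi_s2


def partition_scalar(
    x_m: float,
    c1: PhaseCoeffs,
    c2: PhaseCoeffs,
    T: float,
    pressure2: Callable[[float], float] | None = None,
    dpressure2: Callable[[float], float] | None = None,
    v_w: float = 1.8e-5,
    water_density: float = 998.0,
    f0: float = 0.5,
) -> tuple[float, float, float]:
    """Scalar float fast path of :func:`partition_vectorized`.

    Same safeguarded-Newton scheme on plain floats; used in inner loops
    (the lumped sorption simulator) where array overhead dominates.
    Returns (a_w, f_phase1, phi_s2).
    """
    u_tot = x_m / water_density
    rt = GAS_CONSTANT * T

    def ln_aw(c: PhaseCoeffs, u: float) -> float:
        v = c.v_dry + u
        return math.log(u / v) + c.s_size / v + c.s_chi * (1.0 - u / v) / v

    def dln_aw(c: PhaseCoeffs, u: float) -> float:
        v = c.v_dry + u
        return c.v_dry / (u * v) - c.s_size / v**2 - 2.0 * c.s_chi * c.v_dry / v**3

    f = min(max(f0, 1e-9), 1.0 - 1e-9)
    lo, hi = 1e-12, 1.0 - 1e-12
    for it in range(60):
        u1 = max(f * u_tot, 1e-300)
        u2 = max(u_tot - u1, 1e-300)
        phi_s2 = c2.v_dry / (c2.v_dry + u2)
        p = pressure2(phi_s2) if pressure2 is not None else 0.0
        r = ln_aw(c1, u1) - ln_aw(c2, u2) - v_w * p / rt
        if r > 0:
            hi = f
        else:
            lo = f
        if abs(r) < 1e-12 and it >= 3:
            break
        dp = 0.0
        if pressure2 is not None:
            if dpressure2 is not None:
                dp = dpressure2(phi_s2)
            else:
                h = 1e-6
                dp = (pressure2(phi_s2 + h) - pressure2(phi_s2 - h)) / (2.0 * h)
        dr = u_tot * (dln_aw(c1, u1) + dln_aw(c2, u2)) - (
            v_w * dp / rt
        ) * (u_tot * phi_s2**2 / c2.v_dry)
        step = f - r / dr if dr > 0 else 0.5 * (lo + hi)
        f = step if lo < step < hi else 0.5 * (lo + hi)
    u2 = max(u_tot - f * u_tot, 1e-300)
    phi_s2 = c2.v_dry / (c2.v_dry + u2)
    p = pressure2(phi_s2) if pressure2 is not None else 0.0
    a_w = math.exp(ln_aw(c2, u2) + v_w * p / rt)
    return a_w, f, phi_s2


# ---------------------------------------------------------------------------
# tissue-level sorption isotherm
# ---------------------------------------------------------------------------


@dataclass
class TissueSorption:
    """Sorption isotherm of the whole tissue (both phases at equal activity)."""

    config: ThermoConfig = field(default_factory=ThermoConfig)

    def __post_init__(self) -> None:
        wd = self.config.water_density
        self.coeffs1 = PhaseCoeffs.from_components(self.config.phase1, wd)
        self.coeffs2 = PhaseCoeffs.from_components(self.config.phase2, wd)

    def water_activity(
        self,
        x_m: float,
        T: float = 298.15,
        elastic_state: float | Callable | None = None,
    ) -> float:
        """a_w of tissue at moisture X_m (kg water / kg dry matter)."""
        if x_m <= 0:
            raise ValueError("moisture content must be positive")
        split = partition_water(
            x_m,
            self.config.phase1,
            self.config.phase2,
            elastic_state=elastic_state,
            T=T,
            v_w=self.config.v_w,
            water_density=self.config.water_density,
            tol=self.config.partition_tol,
        )
        return split.a_w

    def moisture(
        self,
        a_w: float,
        T: float = 298.15,
        elastic_state: float | Callable | None = None,
        x_lo: float = 1e-6,
        x_hi: float = 200.0,
        tol: float = 1e-8,
    ) -> float:
        """Numerical inverse of the isotherm: X_m such that a_w(X_m) = a_w."""
        if not 0.0 < a_w < 1.0:
            raise ValueError("a_w must be in (0, 1) for moisture inversion")
        f_hi = self.water_activity(x_hi, T, elastic_state)
        if f_hi < a_w:
            raise ValueError(
                f"requested a_w={a_w} unreachable below X_m={x_hi} (got {f_hi:.6f})"
            )
        lo, hi = x_lo, x_hi
        # bisection on log-moisture: isotherm is monotone at relaxed state
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if self.water_activity(mid, T, elastic_state) < a_w:
                lo = mid
            else:
                hi = mid
            if abs(self.water_activity(mid, T, elastic_state) - a_w) < tol:
                return mid
        return math.sqrt(lo * hi)

    def phi_w_tissue(self, x_m: float) -> float:
        """Water volume fraction of the hyphal material (water + dry matter)."""
        u = x_m / self.config.water_density
        v_dry = self.coeffs1.v_dry + self.coeffs2.v_dry
        return u / (u + v_dry)


def sorption_isotherm(
    x_m: float,
    T: float = 298.15,
    elastic_state: float | Callable | None = None,
    config: ThermoConfig | None = None,
) -> float:
    """Tissue water activity at moisture X_m (dry basis)."""
    return TissueSorption(config or ThermoConfig()).water_activity(x_m, T, elastic_state)


def aw_to_moisture(
    a_w: float,
    T: float = 298.15,
    elastic_state: float | Callable | None = None,
    config: ThermoConfig | None = None,
) -> float:
    """Inverse isotherm: moisture (dry basis) at the given water activity."""
    return TissueSorption(config or ThermoConfig()).moisture(a_w, T, elastic_state)
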