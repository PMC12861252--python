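"""Fitting machinery for the drying model and the sorption factors.

The drying objective sums, over experiments, the mean squared residual of the
rescaled product temperature Theta = (T_p - T_init)/(T_air - T_init) and ten
times the mean squared residual of the wet-basis moisture content; moisture
carries the extra weight because it dominates prediction quality.  The
minimization mirrors the original procedure: a sequential single-factor
(coordinate-descent) search over finite candidate grids, iterated until a
full cycle brings no improvement.

A lumped dynamic-vapor-sorption (DVS) simulator integrates the sample
moisture against stepped relative humidity, coupled to the Maxwell internal
variables; refitting its end-of-step moistures recovers the viscoelastic
scaling factors (F_G,i, F_tau,i).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, default_config
from .solver import AmbientSchedule, DryingModel, DryingResult
from .thermo import partition_scalar

__all__ = [
    "ExperimentRecord",
    "FitResult",
    "DvsProtocol",
    "DvsResult",
    "objective_lse",
    "fit_stats",
    "sequential_search",
    "simulate_dvs",
    "fit_sorption_factors",
    "fit_drying_factors",
]


@dataclass
class ExperimentRecord:
    """A drying experiment: sampled moisture and product temperature."""

    t: np.ndarray  # s, strictly increasing
    y_w: np.ndarray  # wet-basis moisture
    T_p: np.ndarray  # product (center) temperature, K
    T_init: float  # K
    T_air: float  # nominal air setpoint, K
    schedule: AmbientSchedule | None = None
    T_surface: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y_w = np.asarray(self.y_w, dtype=float)
        self.T_p = np.asarray(self.T_p, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any((self.y_w <= 0) | (self.y_w >= 1)):
            raise ValueError("wet-basis moisture must lie in (0, 1)")

    @property
    def n_temperature(self) -> int:
        return len(self.T_p)

    @property
    def n_moisture(self) -> int:
        return len(self.y_w)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.t / 3600.0,
                "yw_wb": self.y_w,
                "T_center_C": self.T_p - 273.15,
            }
        )
        if self.T_surface is not None:
            df["T_surface_C"] = np.asarray(self.T_surface) - 273.15
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str, T_init: float, T_air: float,
        schedule: AmbientSchedule | None = None,
    ) -> "ExperimentRecord":
        df = pd.read_csv(path)
        t_s = (
            df["T_surface_C"].to_numpy() + 273.15
            if "T_surface_C" in df.columns
            else None
        )
        return cls(
            df["time_h"].to_numpy() * 3600.0,
            df["yw_wb"].to_numpy(),
            df["T_center_C"].to_numpy() + 273.15,
            T_init,
            T_air,
            schedule,
            t_s,
        )


@dataclass
class FitResult:
    params: dict
    objective: float
    trace: list = field(default_factory=list)
    n_eval: int = 0
    stats: dict = field(default_factory=dict)


def objective_lse(
    experiments: Sequence[ExperimentRecord],
    simulations: Sequence[DryingResult],
) -> float:
    """Weighted least-squares mismatch between experiments and simulations.

    LSE_sum = sum_i [ mean_j (Theta_exp - Theta_pred)^2
                      + 10 mean_j (y_exp - y_pred)^2 ]
    with simulated curves linearly interpolated onto the sample times.
    """
    total = 0.0
    for rec, sim in zip(experiments, simulations, strict=True):
        if rec.T_air == rec.T_init:
            raise ValueError("Theta undefined: T_air equals T_init")
        scale = rec.T_air - rec.T_init
        th_exp = (rec.T_p - rec.T_init) / scale
        tp_pred = np.interp(rec.t, sim.t, sim.T_center)
        th_pred = (tp_pred - rec.T_init) / scale
        yw_pred = np.interp(rec.t, sim.t, sim.y_w)
        total += float(
            ((th_exp - th_pred) ** 2).sum() / rec.n_temperature
            + 10.0 * ((rec.y_w - yw_pred) ** 2).sum() / rec.n_moisture
        )
    return total


def fit_stats(observed, predicted) -> tuple[float, float, float]:
    """Goodness-of-fit triple (R^2, RMSE, MAE).

    R^2 is reported as NaN when the observations have zero variance.
    """
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("observed/predicted must be equal-length, size >= 2")
    ss_res = float(((y - yh) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(((y - yh) ** 2).mean()))
    mae = float(np.abs(y - yh).mean())
    return r2, rmse, mae


def sequential_search(
    objective: Callable[[dict], float],
    grids: dict[str, Sequence[float]],
    start: dict[str, float],
    max_cycles: int = 12,
    pair_refine: bool = False,
    zero_tol: float = 0.0,
) -> FitResult:
    """Sequential single-factor (coordinate-descent) grid search.

    One parameter is varied at a time over its candidate grid with the others
    held at the incumbent best; the grid argmin becomes the new working
    point.  Cycles repeat until one completes with no strict improvement.
    Failed evaluations are skipped with a warning.

    With ``pair_refine`` the converged point is additionally polished by
    exhaustive two-factor sweeps over every parameter pair (again accepting
    grid argmins), looping back to single-factor cycles after an improvement;
    this escapes the ridge stalls that strictly one-at-a-time moves cannot.
    """
    best = dict(start)
    cache: dict[tuple, float] = {}
    trace: list[tuple[dict, float]] = []
    n_eval = 0

    class _FoundPerfect(Exception):
        pass

    def key(p: dict) -> tuple:
        return tuple(p[k] for k in grids)

    def evaluate(p: dict) -> float:
        nonlocal n_eval, best, best_val
        k = key(p)
        if k not in cache:
            n_eval += 1
            cache[k] = float(objective(p))
            trace.append((dict(p), cache[k]))
            if cache[k] <= zero_tol:
                # a numerically perfect fit cannot be improved: stop searching
                best = dict(p)
                best_val = cache[k]
                raise _FoundPerfect
        return cache[k]

    best_val = float("inf")
    try:
        best_val = evaluate(best)
    except _FoundPerfect:
        return FitResult(best, best_val, trace, n_eval)
    except Exception as err:  # starting point must be evaluable
        raise RuntimeError(f"objective failed at the starting point: {err}")

    def single_factor_cycles() -> None:
        nonlocal best, best_val
        for _ in range(max_cycles):
            improved = False
            for name, grid in grids.items():
                vals = []
                for candidate in grid:
                    trial = dict(best)
                    trial[name] = candidate
                    try:
                        vals.append((evaluate(trial), candidate))
                    except _FoundPerfect:
                        raise
                    except Exception as err:
                        warnings.warn(
                            f"objective failed at {name}={candidate}: {err}; skipped"
                        )
                if not vals:
                    continue
                v_min, c_min = min(vals, key=lambda vc: vc[0])
                if v_min < best_val:
                    best[name] = c_min
                    best_val = v_min
                    improved = True
            if not improved:
                break

    def pair_refine_stage() -> None:
        nonlocal best, best_val
        names = list(grids)
        # sweep the most finely gridded (most informative) pairs first
        pairs = sorted(
            ((names[a], names[b])
             for a in range(len(names)) for b in range(a + 1, len(names))),
            key=lambda p: -(len(grids[p[0]]) * len(grids[p[1]])),
        )
        for _ in range(max_cycles):
            improved = False
            for na, nb in pairs:
                if True:
                    vals = []
                    for ca in grids[na]:
                        for cb in grids[nb]:
                            trial = dict(best)
                            trial[na], trial[nb] = ca, cb
                            try:
                                vals.append((evaluate(trial), ca, cb))
                            except _FoundPerfect:
                                raise
                            except Exception as err:
                                warnings.warn(
                                    f"objective failed at {na}={ca}, {nb}={cb}:"
                                    f" {err}; skipped"
                                )
                    if not vals:
                        continue
                    v_min, ca, cb = min(vals, key=lambda vc: vc[0])
                    if v_min < best_val:
                        best[na], best[nb] = ca, cb
                        best_val = v_min
                        improved = True
            if improved:
                single_factor_cycles()
            else:
                break

    try:
        single_factor_cycles()
        if pair_refine and best_val > zero_tol:
            pair_refine_stage()
    except _FoundPerfect:
        pass
    return FitResult(best, best_val, trace, n_eval)


# ---------------------------------------------------------------------------
# dynamic vapor sorption
# ---------------------------------------------------------------------------


@dataclass
class DvsProtocol:
    """Stepped relative-humidity program for a lumped (gradient-free) sample."""

    rh_steps: np.ndarray  # ordered RH setpoints
    dwell: float = 6.0 * 3600.0  # s per step
    T: float = 298.15  # K
    k_exchange: float = 3e-4  # lumped conductance, 1/s
    relax_start: bool = True  # start at relaxed equilibrium with the first step
    n_substeps: int = 48  # fixed integration substeps per dwell

    def __post_init__(self) -> None:
        self.rh_steps = np.asarray(self.rh_steps, dtype=float)
        if np.any((self.rh_steps <= 0) | (self.rh_steps >= 1)):
            raise ValueError("RH steps must lie in (0, 1)")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")

    @classmethod
    def cycle(
        cls, rh_hi: float = 0.9, rh_lo: float = 0.1, step: float = 0.1, **kw
    ) -> "DvsProtocol":
        """Desorption rh_hi -> rh_lo then adsorption back up, in RH steps."""
        down = np.arange(rh_hi, rh_lo - step / 2, -step)
        up = np.arange(rh_lo + step, rh_hi + step / 2, step)
        return cls(np.concatenate([down, up]), **kw)


@dataclass
class DvsResult:
    rh: np.ndarray  # per step
    x_end: np.ndarray  # end-of-step moisture, dry basis
    branch: np.ndarray  # "desorption" / "adsorption" per step
    x_start: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": np.arange(len(self.rh)),
                "RH": self.rh,
                "Xm_end": self.x_end,
                "branch": self.branch,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_dvs(
    protocol: DvsProtocol,
    config: ModelConfig | None = None,
    model: DryingModel | None = None,
) -> DvsResult:
    """Integrate a lumped stepped-RH sorption run.

    Moisture exchanges with the chamber as dX_m/dt = k (RH - a_w(X_m, state))
    (the vapor-concentration driving force normalized by saturation), coupled
    to the Maxwell internal-variable kinetics.  Integration uses fixed
    operator-splitting substeps: an exponential-Euler update for moisture
    (linearizing a_w around the current state, hence stable however steep
    the isotherm) and the exact exponential update for the internal
    variables.  Descending steps trace the desorption branch, ascending
    steps the adsorption branch; unrelaxed wall stress separates the two.
    """
    cfg = config or default_config()
    if model is None:
        model = DryingModel(cfg)  # supplies composition coefficients and splines
    c1, c2 = model.coeffs1, model.coeffs2
    tc = cfg.thermo
    T = protocol.T
    ve = cfg.viscoelastic
    sign = tc.elastic_sign
    f_warm = [0.5]

    def aw_state(x, p1, p2):
        x = max(x, 1e-9)
        g1 = float(_mode_g_scalar(ve.slow, x))
        g2 = float(_mode_g_scalar(ve.fast, x))
        tau1 = float(_mode_tau_scalar(ve.slow, x, T))
        tau2 = float(_mode_tau_scalar(ve.fast, x, T))

        def pressure2(phi_s2):
            pt1, pt2 = phi_s2 / p1, phi_s2 / p2
            return sign * (
                g1 * (pt1 ** (1.0 / 3.0) - pt1) + g2 * (pt2 ** (1.0 / 3.0) - pt2)
            )

        def dpressure2(phi_s2):
            d1 = (phi_s2 / p1) ** (-2.0 / 3.0) / (3.0 * p1) - 1.0 / p1
            d2 = (phi_s2 / p2) ** (-2.0 / 3.0) / (3.0 * p2) - 1.0 / p2
            return sign * (g1 * d1 + g2 * d2)

        a_w, f, phi_s2 = partition_scalar(
            x, c1, c2, T, pressure2, dpressure2,
            v_w=tc.v_w, water_density=tc.water_density, f0=f_warm[0],
        )
        f_warm[0] = f
        return a_w, phi_s2, tau1, tau2

    # initial state: relaxed equilibrium with the first RH step
    rh0 = protocol.rh_steps[0]
    x0 = model.tissue.moisture(rh0, T) if protocol.relax_start else 1.0
    _, phi_s2_0, _, _ = aw_state(x0, 1.0, 1.0)
    for _ in range(5):  # tiny fixed-point: phi_s2 at zero stress
        _, phi_s2_0, _, _ = aw_state(x0, phi_s2_0, phi_s2_0)
    x, p1, p2 = x0, phi_s2_0, phi_s2_0

    k = protocol.k_exchange
    dt = protocol.dwell / protocol.n_substeps
    x_end = np.empty(len(protocol.rh_steps))
    branch = np.empty(len(protocol.rh_steps), dtype=object)
    prev_rh = rh0
    for i, rh in enumerate(protocol.rh_steps):
        for _ in range(protocol.n_substeps):
            a_w, phi_s2, tau1, tau2 = aw_state(x, p1, p2)
            a_w_eps, _, _, _ = aw_state(x * 1.001, p1, p2)
            slope = (a_w_eps - a_w) / (0.001 * x)
            if slope > 1e-9:
                # exponential Euler on the linearized exchange dynamics
                x = x + (rh - a_w) / slope * (1.0 - math.exp(-k * slope * dt))
            else:
                x = x + dt * k * (rh - a_w)
            x = max(x, 1e-9)
            e1 = math.exp(-dt / tau1)
            e2 = math.exp(-dt / tau2)
            p1 = phi_s2 + (p1 - phi_s2) * e1
            p2 = phi_s2 + (p2 - phi_s2) * e2
        x_end[i] = x
        branch[i] = "desorption" if rh <= prev_rh else "adsorption"
        prev_rh = rh
    return DvsResult(protocol.rh_steps.copy(), x_end, branch, x_start=x0)


def _mode_g_scalar(mode, x: float) -> float:
    return mode.f_g * 10.0 ** max(mode.g_intercept + mode.g_slope * x, mode.log10_g_min)


def _mode_tau_scalar(mode, x: float, T: float) -> float:
    from .config import GAS_CONSTANT

    log_tau = max(mode.tau_intercept + mode.tau_slope * x, mode.log10_tau_min)
    arrh = math.exp(mode.ea / GAS_CONSTANT * (1.0 / T - 1.0 / mode.t_ref))
    return mode.f_tau * 10.0 ** log_tau * arrh


_SORPTION_FACTOR_KEYS = ("f_g0", "f_g1", "f_tau0", "f_tau1")


def _apply_sorption_factors(cfg: ModelConfig, params: dict) -> None:
    cfg.viscoelastic.slow.f_g = params["f_g0"]
    cfg.viscoelastic.fast.f_g = params["f_g1"]
    cfg.viscoelastic.slow.f_tau = params["f_tau0"]
    cfg.viscoelastic.fast.f_tau = params["f_tau1"]


def fit_sorption_factors(
    observed_x_end: np.ndarray,
    protocol: DvsProtocol,
    config: ModelConfig | None = None,
    grid: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
    start: dict | None = None,
) -> FitResult:
    """Recover (F_G0, F_G1, F_tau00, F_tau01) from end-of-step DVS moistures.

    Minimizes the squared end-of-step moisture error by sequential
    single-factor search over a log-spaced grid per factor.
    """
    observed = np.asarray(observed_x_end, dtype=float)
    cfg = config or default_config()
    model = DryingModel(cfg)

    def objective(params: dict) -> float:
        _apply_sorption_factors(cfg, params)
        sim = simulate_dvs(protocol, cfg, model=model)
        return float(((sim.x_end - observed) ** 2).sum())

    grids = {k: list(grid) for k in _SORPTION_FACTOR_KEYS}
    start = start or {k: 1.0 for k in _SORPTION_FACTOR_KEYS}
    result = sequential_search(objective, grids, start, pair_refine=True)
    _apply_sorption_factors(cfg, result.params)
    return result


def fit_drying_factors(
    experiments: Sequence[ExperimentRecord],
    config: ModelConfig | None = None,
    grid_e: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    grid_f: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 8.0, 10.0),
    start: dict | None = None,
) -> FitResult:
    """Fit (e, F_w,conv, F_w,diff) to drying records by coordinate descent.

    Each objective evaluation re-simulates every experiment on its own
    ambient schedule, sampling the model at the experimental times.
    """
    cfg = config or default_config()
    model = DryingModel(cfg)

    def objective(params: dict) -> float:
        cfg.transport.emissivity = params["emissivity"]
        cfg.transport.f_w_conv = params["f_w_conv"]
        cfg.transport.f_w_diff = params["f_w_diff"]
        sims = []
        for rec in experiments:
            if rec.schedule is None:
                raise ValueError("experiment record lacks an ambient schedule")
            sims.append(
                model.simulate(rec.schedule, float(rec.t[-1]), t_eval=rec.t)
            )
        return objective_lse(experiments, sims)

    grids = {
        "emissivity": list(grid_e),
        "f_w_conv": list(grid_f),
        "f_w_diff": list(grid_f),
    }
    start = start or {"emissivity": 0.5, "f_w_conv": 1.0, "f_w_diff": 1.0}
    result = sequential_search(objective, grids, start, pair_refine=True)

    # goodness of fit at the optimum
    cfg.transport.emissivity = result.params["emissivity"]
    cfg.transport.f_w_conv = result.params["f_w_conv"]
    cfg.transport.f_w_diff = result.params["f_w_diff"]
    stats = {}
    for i, rec in enumerate(experiments):
        sim = model.simulate(rec.schedule, float(rec.t[-1]), t_eval=rec.t)
        yw_pred = np.interp(rec.t, sim.t, sim.y_w)
        r2, rmse, mae = fit_stats(rec.y_w, yw_pred)
        stats[f"experiment_{i}"] = {"R2": r2, "RMSE": rmse, "MAE": mae}
    result.stats = stats
    return result
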